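"""Covariate selection and per-ROI model diagnostics.

Covariates are chosen by forward-stepwise search under the Bayesian
information criterion (BIC = k ln n − 2 lnL): starting from the
dose-only model, the candidate whose addition lowers BIC most is added,
until no candidate lowers it.  Diagnostics mirror the usual per-ROI
reporting for multi-ROI toxicity studies: Wald p-values for the dose
and age coefficients, adjusted for multiplicity across ROIs by the
Benjamini–Hochberg false-discovery-rate procedure (one family per
coefficient), plus BIC and ROC AUC per model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .model import (
    ConvergenceError,
    DegenerateOutcomeError,
    NTCPResults,
    SeparationError,
    fit_mle,
)

__all__ = [
    "SelectionResult",
    "bic_score",
    "forward_stepwise",
    "benjamini_hochberg",
    "roc_auc",
    "diagnostics_table",
]


def bic_score(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion, ``k ln(n) - 2 lnL`` (lower is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * np.log(n) - 2 * log_likelihood


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the input order (monotonicity across
    ranks enforced, values capped at 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roc_auc(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """ROC area via the Mann–Whitney statistic.

    Fraction of (positive, negative) pairs with the positive scored
    higher, counting ties 1/2.  Requires both classes present.
    """
    y = np.asarray(outcomes)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcomes must contain both classes")
    return float(roc_auc_score(y, s))


@dataclass
class SelectionResult:
    """Outcome of a forward-stepwise BIC search for one ROI."""

    roi: str
    candidate_covariates: list[str]
    selected: list[str]
    bic_trace: list[float] = field(repr=False)
    final_fit: NTCPResults = field(repr=False)

    def summary(self) -> str:
        steps = " -> ".join(["dose-only"] + self.selected) or "dose-only"
        trace = ", ".join(f"{b:.2f}" for b in self.bic_trace)
        return (
            f"Forward-stepwise BIC selection — ROI {self.roi}\n"
            f"  candidates: {', '.join(self.candidate_covariates)}\n"
            f"  path: {steps}\n"
            f"  BIC trace: {trace}"
        )


def forward_stepwise(
    cohort: pd.DataFrame,
    roi: str,
    candidates: Sequence[str],
    *,
    outcome: str = "outcome",
) -> SelectionResult:
    """Greedy forward BIC selection on top of the dose-only model.

    Dose is always in the model.  At each step every remaining
    candidate is tried; the one giving the lowest BIC is added if it
    improves on the current BIC, with ties broken by candidate-list
    order (the first-listed winner is kept).  Candidates whose fit
    fails (separation, degenerate outcome) are excluded with a warning.
    The search is deterministic given the cohort and candidate order.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    remaining = list(candidates)
    selected: list[str] = []
    current = fit_mle(cohort, roi, selected, outcome=outcome)
    trace = [current.bic]
    while remaining:
        best_name, best_fit, best_bic = None, None, current.bic
        for name in remaining:
            try:
                trial = fit_mle(cohort, roi, selected + [name], outcome=outcome)
            except (SeparationError, ConvergenceError, DegenerateOutcomeError) as exc:
                warnings.warn(
                    f"candidate {name!r} excluded from stepwise search: {exc}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                remaining = [c for c in remaining if c != name]
                continue
            # strict improvement required; the earliest-listed candidate
            # wins exact ties because later ones must beat it strictly
            if trial.bic < best_bic - 1e-12:
                best_name, best_fit, best_bic = name, trial, trial.bic
        if best_name is None:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current = best_fit
        trace.append(best_bic)
    return SelectionResult(
        roi=roi,
        candidate_covariates=list(candidates),
        selected=selected,
        bic_trace=trace,
        final_fit=current,
    )


def diagnostics_table(
    fits: Mapping[str, NTCPResults] | Sequence[NTCPResults],
) -> pd.DataFrame:
    """Per-ROI diagnostics: FDR-adjusted dose/age p-values, BIC, AUC.

    Every fit must contain ``dose`` and ``age`` coefficients.  Raw Wald
    p-values are collected across ROIs and BH-adjusted within two
    families — all dose p-values together, all age p-values together.
    """
    if isinstance(fits, Mapping):
        items = list(fits.values())
    else:
        items = list(fits)
    if not items:
        raise ValueError("no fits supplied")
    rows = []
    for fit in items:
        names = fit.param_names
        if "dose" not in names or "age" not in names:
            raise KeyError(f"fit for ROI {fit.roi!r} lacks dose and/or age coefficient")
        rows.append({
            "muscle": fit.roi,
            "dose_p_raw": float(fit.pvalues["dose"]),
            "age_p_raw": float(fit.pvalues["age"]),
            "bic": float(fit.bic),
            "auc": float(fit.auc),
        })
    df = pd.DataFrame(rows)
    df["dose_fdr_p"] = benjamini_hochberg(df["dose_p_raw"].to_numpy())
    df["age_fdr_p"] = benjamini_hochberg(df["age_p_raw"].to_numpy())
    return df[["muscle", "dose_fdr_p", "age_fdr_p", "bic", "auc",
               "dose_p_raw", "age_p_raw"]]
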