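"""Age-stratified dose constraints and dose–response curve export.

Given a fitted logistic NTCP model with a positive dose coefficient,
the dose that keeps the predicted complication probability at a target
risk (default 5%) follows in closed form:

    D(risk) = (logit(risk) - b0 - sum_j bj x_j) / bD

evaluated per age stratum at the stratum's representative age.  When
the modelled risk at zero dose already exceeds the target, no finite
constraint exists and the cell is flagged (reported as "<floor", with a
10 Gy display floor by convention).  With a positive age coefficient
constraints tighten with age at the exact rate -b_age / bD Gy per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .model import BootstrapEnsemble, NonMonotoneResponseError, NTCPResults

__all__ = [
    "AgeStratum",
    "DEFAULT_AGE_STRATA",
    "BaselineRiskError",
    "ConstraintTable",
    "CurveSet",
    "invert_dose_for_risk",
    "constraint_table",
    "ntcp_curves",
]


class BaselineRiskError(ValueError):
    """Modelled risk at zero dose already exceeds the target: no finite
    dose constraint exists (the cell is below the display floor)."""


@dataclass(frozen=True)
class AgeStratum:
    """A decade-of-age reporting stratum with its representative age.

    The age interval is half-open, ``[lower, upper)``.
    """

    label: str
    representative_age: float
    lower: float
    upper: float

    def contains(self, age) -> np.ndarray:
        a = np.asarray(age, dtype=float)
        return (a >= self.lower) & (a < self.upper)


#: decade strata used for reporting, represented at mid-decade ages
DEFAULT_AGE_STRATA: tuple[AgeStratum, ...] = (
    AgeStratum("<=49", 45.0, 0.0, 50.0),
    AgeStratum("50-59", 55.0, 50.0, 60.0),
    AgeStratum("60-69", 65.0, 60.0, 70.0),
    AgeStratum(">=70", 75.0, 70.0, np.inf),
)


def invert_dose_for_risk(
    fit: NTCPResults,
    covariate_profile: Mapping[str, float] | None = None,
    risk: float = 0.05,
    *,
    verify: bool = True,
) -> float:
    """Dose at which the modelled NTCP equals ``risk`` for a profile.

    Uses the closed-form logistic inversion and, when ``verify`` is on,
    confirms it against a bisection root find to 1e-6 Gy.  Raises
    :class:`BaselineRiskError` when the zero-dose risk already exceeds
    the target and :class:`NonMonotoneResponseError` when the dose
    coefficient is not positive.
    """
    if not 0 < risk < 1:
        raise ValueError("risk must be in (0, 1)")
    bD = fit.beta_dose
    if bD <= 0:
        raise NonMonotoneResponseError(
            f"dose coefficient {bD:.4g} is not positive; cannot invert"
        )
    p0 = float(fit.predict(0.0, covariate_profile))
    if p0 > risk:
        raise BaselineRiskError(
            f"baseline (0 Gy) risk {p0:.4f} exceeds target {risk:.4f}"
        )
    lp0 = float(fit.linear_predictor(0.0, covariate_profile))
    dose = (special.logit(risk) - lp0) / bD
    if verify:
        f = lambda d: float(fit.predict(d, covariate_profile)) - risk
        lo, hi = 0.0, max(2 * dose, dose + 10.0)
        while f(hi) < 0:
            hi *= 2
        root = optimize.brentq(f, lo, hi, xtol=1e-9)
        if abs(root - dose) > 1e-6:
            raise RuntimeError(
                f"closed-form inversion ({dose:.8f}) and bisection ({root:.8f}) disagree"
            )
    return float(dose)


@dataclass
class ConstraintTable:
    """Per-ROI, per-age-stratum mean-dose constraints at a fixed risk.

    ``data`` has one row per (ROI, stratum) with the full-precision
    constraint dose (NaN when below the floor or when the baseline risk
    exceeds the target) and a display string using the "<floor"
    convention with integer-Gy rounding.
    """

    risk_target: float
    floor: float
    data: pd.DataFrame = field(repr=False)

    def pivot(self, display: bool = True) -> pd.DataFrame:
        """Wide layout: ROIs as rows, age strata as columns."""
        col = "display" if display else "dose_gy"
        wide = self.data.pivot(index="muscle", columns="age_stratum", values=col)
        order = list(dict.fromkeys(self.data["age_stratum"]))
        return wide[order]

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()


def constraint_table(
    fits: Mapping[str, NTCPResults],
    age_strata: Sequence[AgeStratum] = DEFAULT_AGE_STRATA,
    risk: float = 0.05,
    *,
    floor: float = 10.0,
    base_profile: Mapping[str, float] | None = None,
) -> ConstraintTable:
    """Build the per-ROI, per-age-stratum constraint table.

    Each fit must carry an ``age`` coefficient; every other covariate
    is held at ``base_profile`` (default 0).  Doses are rounded to the
    nearest integer Gy for display; values below ``floor`` — including
    cells where the baseline risk already exceeds the target — are
    shown as ``"<{floor}"``.
    """
    base = dict(base_profile or {})
    rows = []
    for roi, fit in fits.items():
        if "age" not in fit.param_names:
            raise KeyError(f"fit for ROI {roi!r} has no age coefficient")
        for stratum in age_strata:
            profile = dict(base)
            profile["age"] = stratum.representative_age
            flag = ""
            try:
                dose = invert_dose_for_risk(fit, profile, risk)
            except BaselineRiskError:
                dose, flag = np.nan, "baseline_risk_exceeds_target"
            except NonMonotoneResponseError:
                dose, flag = np.nan, "non_monotone_dose_response"
            if flag or dose < floor:
                display = f"<{floor:g}"
                stored = np.nan if flag else dose
            else:
                display = f"{round(dose):d}"
                stored = dose
            rows.append({
                "muscle": roi,
                "age_stratum": stratum.label,
                "dose_gy": stored,
                "display": display,
                "flag": flag,
            })
    return ConstraintTable(risk_target=risk, floor=floor, data=pd.DataFrame(rows))


@dataclass
class CurveSet:
    """Per-stratum NTCP curves on a dose grid with bootstrap bands.

    ``curves`` maps stratum label -> DataFrame with columns
    ``dose, ntcp`` and, when an ensemble was supplied, ``lower, upper``
    pointwise percentile bands.
    """

    roi: str
    dose_grid: np.ndarray = field(repr=False)
    curves: dict[str, pd.DataFrame] = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, df in self.curves.items():
            d = df.copy()
            d.insert(0, "age_stratum", label)
            frames.append(d)
        out = pd.concat(frames, ignore_index=True)
        out.insert(0, "muscle", self.roi)
        return out


def ntcp_curves(
    fit: NTCPResults,
    ensemble: BootstrapEnsemble | None,
    dose_grid: Sequence[float],
    age_strata: Sequence[AgeStratum] = DEFAULT_AGE_STRATA,
    *,
    base_profile: Mapping[str, float] | None = None,
    level: float = 0.95,
) -> CurveSet:
    """Evaluate per-stratum dose–response curves with percentile bands.

    The central curve comes from the point fit; bands are pointwise
    percentiles over the converged bootstrap replicates.  With no
    ensemble (or an empty one) only central curves are returned, with a
    warning.
    """
    grid = np.asarray(dose_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("dose grid must be non-empty and strictly increasing")
    base = dict(base_profile or {})
    curves: dict[str, pd.DataFrame] = {}
    if ensemble is None:
        import warnings

        warnings.warn("no bootstrap ensemble: central curves only", RuntimeWarning,
                      stacklevel=2)
    for stratum in age_strata:
        profile = dict(base)
        profile["age"] = stratum.representative_age
        central = np.asarray(fit.predict(grid, profile), dtype=float)
        df = pd.DataFrame({"dose": grid, "ntcp": central})
        if ensemble is not None:
            band = ensemble.predict_band(grid, profile, level=level)
            df["lower"] = band["lower"].to_numpy()
            df["upper"] = band["upper"].to_numpy()
        curves[stratum.label] = df
    return CurveSet(roi=fit.roi, dose_grid=grid, curves=curves)
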