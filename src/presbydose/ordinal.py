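"""Proportional-odds (cumulative logit) fit for graded toxicity outcomes.

When the toxicity outcome is recorded on an ordered scale — here the
number of distinct chronic-dysphagia criteria a patient met (0, 1, 2+)
— the binary logistic model generalizes to a proportional-odds model:

    P(Y <= j | dose, x) = logistic(theta_j - (bD * dose + sum bk x_k))

with strictly increasing thresholds theta_0 < ... < theta_{J-1} and a
single slope vector shared across grade boundaries.  With two outcome
levels this is exactly the binary logistic model (b0 = -theta_0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .model import (
    PROB_CLIP,
    ConvergenceError,
    NTCPModel,
    dose_column,
)

__all__ = ["OrdinalNTCPModel", "OrdinalNTCPResults", "ordinal_fit"]


class OrdinalNTCPModel:
    """Proportional-odds dose–response model on an ordinal grade column."""

    def __init__(
        self,
        cohort: pd.DataFrame,
        roi: str,
        covariates: Sequence[str] = (),
        *,
        grade: str = "ordinal_grade",
    ) -> None:
        self.cohort = cohort.reset_index(drop=True)
        self.roi = roi
        self.covariates = list(covariates)
        self.grade_col = grade

        if grade not in cohort.columns:
            raise KeyError(f"grade column {grade!r} not in cohort")
        g = cohort[grade].to_numpy()
        self.levels = np.unique(g)
        if len(self.levels) < 2:
            raise ValueError("ordinal outcome needs at least 2 distinct levels")
        # y as level index 0..J
        self.y = np.searchsorted(self.levels, g)

        dcol = dose_column(roi) if dose_column(roi) in cohort.columns else roi
        if dcol not in cohort.columns:
            raise KeyError(f"no dose column for ROI {roi!r}")
        cols = [dcol] + self.covariates
        for c in self.covariates:
            if c not in cohort.columns:
                raise KeyError(f"covariate column {c!r} not in cohort")
        self.exog = np.column_stack([cohort[c].to_numpy(dtype=float) for c in cols])
        self.slope_names = ["dose"] + self.covariates

    @property
    def n_thresholds(self) -> int:
        return len(self.levels) - 1

    def _unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Free params -> (increasing thresholds, slopes)."""
        J = self.n_thresholds
        raw = theta[:J]
        cuts = np.empty(J)
        cuts[0] = raw[0]
        if J > 1:
            cuts[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
        return cuts, theta[J:]

    def nloglike(self, theta: np.ndarray) -> float:
        cuts, beta = self._unpack(theta)
        eta = self.exog @ beta
        # P(Y <= j) for each boundary, with sentinels 0 and 1
        cum = special.expit(cuts[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        probs = cum[np.arange(len(eta)), self.y + 1] - cum[np.arange(len(eta)), self.y]
        probs = np.clip(probs, PROB_CLIP, 1.0)
        return float(-np.sum(np.log(probs)))

    def fit(self) -> "OrdinalNTCPResults":
        J, p = self.n_thresholds, self.exog.shape[1]
        # start thresholds at empirical cumulative logits, slopes at zero,
        # standardizing the design for a well-scaled search
        mu, sigma = self.exog.mean(axis=0), self.exog.std(axis=0)
        sigma[sigma == 0] = 1.0
        Zmodel = OrdinalNTCPModel.__new__(OrdinalNTCPModel)
        Zmodel.__dict__.update(self.__dict__)
        Zmodel.exog = (self.exog - mu) / sigma

        freqs = np.bincount(self.y, minlength=J + 1) / len(self.y)
        cum = np.clip(np.cumsum(freqs)[:-1], 1e-6, 1 - 1e-6)
        cuts0 = special.logit(cum)
        x0 = np.zeros(J + p)
        x0[0] = cuts0[0]
        if J > 1:
            x0[1:J] = np.log(np.clip(np.diff(cuts0), 1e-6, None))

        res = optimize.minimize(
            Zmodel.nloglike, x0, method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        if not res.success and res.fun > Zmodel.nloglike(x0):
            raise ConvergenceError(f"ordinal fit failed: {res.message}")
        cuts_z, beta_z = Zmodel._unpack(res.x)
        beta = beta_z / sigma
        cuts = cuts_z + np.sum(beta_z * mu / sigma)
        llf = -self.nloglike(np.concatenate([
            [cuts[0]], np.log(np.clip(np.diff(cuts), 1e-300, None)), beta,
        ])) if J > 1 else -self.nloglike(np.concatenate([[cuts[0]], beta]))
        return OrdinalNTCPResults(model=self, thresholds=cuts, slopes=beta, llf=llf)


@dataclass
class OrdinalNTCPResults:
    """Fitted proportional-odds model."""

    model: OrdinalNTCPModel
    thresholds: np.ndarray
    slopes: np.ndarray
    llf: float

    @property
    def n(self) -> int:
        return len(self.model.y)

    @property
    def k(self) -> int:
        return len(self.thresholds) + len(self.slopes)

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2 * self.llf

    @property
    def params(self) -> pd.Series:
        names = [f"threshold_{i}" for i in range(len(self.thresholds))] + \
            self.model.slope_names
        return pd.Series(np.concatenate([self.thresholds, self.slopes]), index=names)

    def prob_exceeds(self, grade_index: int, dose, covariate_profile: Mapping[str, float] | None = None):
        """P(Y > level_j) at a dose and covariate profile."""
        profile = dict(covariate_profile or {})
        eta = self.slopes[0] * np.asarray(dose, dtype=float)
        for i, c in enumerate(self.model.covariates, start=1):
            if c not in profile:
                raise KeyError(f"covariate profile missing {c!r}")
            eta = eta + self.slopes[i] * float(profile[c])
        return special.expit(eta - self.thresholds[grade_index])

    def as_binary_coefficients(self) -> pd.Series:
        """Equivalent binary-logistic coefficients when there are 2 levels."""
        if len(self.thresholds) != 1:
            raise ValueError("binary reduction only defined for 2-level outcomes")
        vals = np.concatenate([[-self.thresholds[0]], self.slopes])
        return pd.Series(vals, index=["intercept"] + self.model.slope_names)


def ordinal_fit(
    cohort: pd.DataFrame,
    roi: str,
    covariate_names: Sequence[str] = (),
    *,
    grade: str = "ordinal_grade",
) -> OrdinalNTCPResults:
    """Fit the proportional-odds model (functional form of :class:`OrdinalNTCPModel`)."""
    return OrdinalNTCPModel(cohort, roi, covariate_names, grade=grade).fit()
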