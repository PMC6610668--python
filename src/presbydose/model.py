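"""Logistic NTCP dose–response models with clinical covariates.

The core model is a logistic regression of a binary late-toxicity
outcome on the summary dose to one region of interest (ROI) plus
clinical covariates — here centrally patient age, which acts as a
dose-response-modifying factor:

    NTCP(D, x) = 1 / (1 + exp(-(b0 + bD * D + sum_j bj * x_j)))

Fitting is by maximum likelihood (Newton iterations with step-halving
and a derivative-free restart fallback).  The fitted model can be
re-expressed in the conventional two-parameter dose–response form
(D50, the dose giving 50% complication probability at a fixed covariate
profile, and gamma50, the normalized slope there), and uncertainty is
quantified by case-resampling bootstrap.

Usage follows the statsmodels convention: build an :class:`NTCPModel`
from a cohort table, call :meth:`~NTCPModel.fit` to obtain an
:class:`NTCPResults`, and hang prediction, inversion and bootstrap off
the results object.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "NTCPModel",
    "NTCPResults",
    "BootstrapEnsemble",
    "DoseResponseParams",
    "SeparationError",
    "ConvergenceError",
    "DegenerateOutcomeError",
    "NonMonotoneResponseError",
    "fit_mle",
    "ntcp_probability",
    "negative_log_likelihood",
    "derive_d50_gamma",
    "bootstrap",
    "dose_column",
]

#: floor used to keep probabilities away from {0, 1} inside likelihoods
PROB_CLIP = 1e-12
#: cap on standardized coefficient magnitude before declaring separation
SEPARATION_CAP = 50.0
GRADIENT_TOL = 1e-8
MAX_NEWTON_ITER = 100


class SeparationError(RuntimeError):
    """The likelihood is unbounded: the data are (quasi-)separated."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to reach the gradient tolerance."""


class DegenerateOutcomeError(ValueError):
    """The cohort contains only one outcome class."""


class NonMonotoneResponseError(ValueError):
    """The fitted dose coefficient is not positive, so the D50/gamma50
    re-parameterization (and risk inversion) is undefined."""


def dose_column(roi: str) -> str:
    """Name of the cohort column holding an ROI's summary dose."""
    return f"dose_{roi}"


def _logistic(lp: np.ndarray | float) -> np.ndarray | float:
    return special.expit(lp)


@dataclass(frozen=True)
class DoseResponseParams:
    """Two-parameter (D50, gamma50) description of a dose–response curve.

    ``d50`` is the dose at which the modelled complication probability
    is 0.5 for the covariate profile it was derived at; ``gamma50`` is
    the normalized slope of the curve there (``bD * d50 / 4`` for the
    logistic link).
    """

    d50: float
    gamma50: float


class NTCPModel:
    """Logistic NTCP model for one ROI on a cohort table.

    Parameters
    ----------
    cohort
        One row per patient.  Must contain the outcome column, the
        ROI's dose column (``dose_<roi>``, or the ROI name itself), and
        every covariate column.
    roi
        ROI label; resolves the dose column.
    covariates
        Clinical covariate column names entering the linear predictor
        in addition to dose (e.g. ``["age"]``).
    outcome
        Name of the binary outcome column (values in {0, 1}).
    include_dose
        If False the model has no dose term (intercept + covariates
        only); used for null/intercept-only fits.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        roi: str,
        covariates: Sequence[str] = (),
        *,
        outcome: str = "outcome",
        include_dose: bool = True,
    ) -> None:
        self.cohort = cohort.reset_index(drop=True)
        self.roi = roi
        self.covariates = list(covariates)
        self.outcome_col = outcome
        self.include_dose = include_dose

        if outcome not in cohort.columns:
            raise KeyError(f"outcome column {outcome!r} not in cohort")
        y = cohort[outcome].to_numpy(dtype=float)
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("outcome must be coded 0/1")
        self.y = y

        cols: list[str] = []
        if include_dose:
            dcol = dose_column(roi) if dose_column(roi) in cohort.columns else roi
            if dcol not in cohort.columns:
                raise KeyError(f"no dose column for ROI {roi!r} (looked for {dose_column(roi)!r})")
            cols.append(dcol)
        for c in self.covariates:
            if c not in cohort.columns:
                raise KeyError(f"covariate column {c!r} not in cohort")
            cols.append(c)
        X = np.column_stack(
            [np.ones(len(cohort))] + [cohort[c].to_numpy(dtype=float) for c in cols]
        )
        self.exog = X
        names = ["intercept"]
        if include_dose:
            names.append("dose")
        names.extend(self.covariates)
        self.param_names = names

    # -- likelihood machinery -------------------------------------------------

    def nloglike(self, params: np.ndarray) -> float:
        p = np.clip(_logistic(self.exog @ params), PROB_CLIP, 1 - PROB_CLIP)
        return float(-np.sum(self.y * np.log(p) + (1 - self.y) * np.log(1 - p)))

    def score(self, params: np.ndarray) -> np.ndarray:
        """Gradient of the *log*-likelihood."""
        p = _logistic(self.exog @ params)
        return self.exog.T @ (self.y - p)

    def hessian(self, params: np.ndarray) -> np.ndarray:
        """Hessian of the log-likelihood (negative definite)."""
        p = _logistic(self.exog @ params)
        w = p * (1 - p)
        return -(self.exog * w[:, None]).T @ self.exog

    # -- fitting --------------------------------------------------------------

    def fit(self) -> "NTCPResults":
        """Maximum-likelihood fit.

        Newton iterations with step-halving on a standardized design;
        if Newton stalls without evidence of separation, a Nelder–Mead
        restart is tried and polished by Newton.  Raises
        :class:`SeparationError` when a standardized coefficient runs
        past the cap of 50 (or the deviance is still falling there) and
        :class:`DegenerateOutcomeError` when only one outcome class is
        present.
        """
        y = self.y
        if y.sum() == 0 or y.sum() == len(y):
            raise DegenerateOutcomeError("cohort has a single outcome class; cannot fit")

        Z, mu, sigma = self._standardized_design()
        b = self._newton(Z, allow_restart=True)
        params = self._destandardize(b, mu, sigma)

        H = self.hessian(params)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        llf = -self.nloglike(params)
        return NTCPResults(model=self, params=params, cov=cov, llf=llf)

    def _standardized_design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X = self.exog
        mu = X.mean(axis=0)
        sigma = X.std(axis=0)
        mu[0], sigma[0] = 0.0, 1.0  # intercept untouched
        sigma[sigma == 0] = 1.0
        Z = (X - mu) / sigma
        return Z, mu, sigma

    @staticmethod
    def _destandardize(b: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        params = b / sigma
        params[0] = b[0] - np.sum(b[1:] * mu[1:] / sigma[1:])
        return params

    def _newton(self, Z: np.ndarray, *, allow_restart: bool) -> np.ndarray:
        y = self.y
        n, k = Z.shape
        b = np.zeros(k)
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        b[0] = special.logit(pbar)

        def nll(bv: np.ndarray) -> float:
            p = np.clip(_logistic(Z @ bv), PROB_CLIP, 1 - PROB_CLIP)
            return float(-np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

        cur = nll(b)
        for _ in range(MAX_NEWTON_ITER):
            p = _logistic(Z @ b)
            g = Z.T @ (y - p)
            if np.max(np.abs(g)) < GRADIENT_TOL:
                if cur < 1e-5:
                    raise SeparationError(
                        "perfect in-sample prediction: data are separated"
                    )
                return b
            w = np.clip(p * (1 - p), 1e-10, None)
            H = (Z * w[:, None]).T @ Z
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            if np.max(np.abs(g)) < 1e-4:
                # near the optimum deviance differences fall below double
                # resolution, so a line search cannot certify descent; the
                # raw Newton step converges quadratically from here
                b = b + step
                cur = nll(b)
                continue
            # step-halving line search on the deviance
            t = 1.0
            for _ in range(40):
                cand = b + t * step
                val = nll(cand)
                if val <= cur + 1e-14:
                    b, cur = cand, val
                    break
                t /= 2
            else:
                break  # no descent found
            if np.max(np.abs(b[1:])) > SEPARATION_CAP or abs(b[0]) > SEPARATION_CAP:
                raise SeparationError(
                    "standardized coefficient exceeded cap 50: data are separated"
                )
        else:
            # hit the iteration cap; if the deviance is still falling the
            # likelihood is effectively unbounded
            raise SeparationError("deviance still decreasing at iteration cap")

        if allow_restart:
            res = optimize.minimize(nll, b, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            b = res.x
            try:
                return self._polish(Z, b)
            except np.linalg.LinAlgError:
                pass
        raise ConvergenceError("Newton iterations stalled before reaching gradient tolerance")

    def _polish(self, Z: np.ndarray, b: np.ndarray) -> np.ndarray:
        y = self.y
        for _ in range(50):
            p = _logistic(Z @ b)
            g = Z.T @ (y - p)
            if np.max(np.abs(g)) < GRADIENT_TOL:
                return b
            w = np.clip(p * (1 - p), 1e-10, None)
            H = (Z * w[:, None]).T @ Z
            b = b + np.linalg.solve(H, g)
            if np.max(np.abs(b)) > SEPARATION_CAP:
                raise SeparationError("separation detected during polish")
        raise ConvergenceError("polish failed to converge")


class NTCPResults:
    """Fitted NTCP model: estimates, uncertainty, diagnostics.

    Attributes
    ----------
    params : pandas.Series
        Coefficients indexed by ``["intercept", "dose", <covariates>]``.
    cov_params : pandas.DataFrame
        Observed-information covariance estimate.
    llf, bic, aic : float
        Log-likelihood and information criteria (``bic = k ln n − 2 llf``).
    pvalues : pandas.Series
        Two-sided Wald p-values (normal reference).
    auc : float
        ROC area of the fitted linear predictor against the outcome.
    """

    def __init__(self, model: NTCPModel, params: np.ndarray, cov: np.ndarray, llf: float):
        self.model = model
        self._params = np.asarray(params, dtype=float)
        self._cov = np.asarray(cov, dtype=float)
        self.llf = float(llf)
        self.n = len(model.y)
        self.k = len(params)

    # -- basic accessors ------------------------------------------------------

    @property
    def roi(self) -> str:
        return self.model.roi

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.param_names, name="coef")

    @property
    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=self.param_names, columns=self.param_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._cov)), index=self.param_names, name="std err")

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        z = self.tvalues.to_numpy()
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.Series(p, index=self.param_names, name="P>|z|")

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2 * self.llf

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.llf

    @property
    def deviance(self) -> float:
        return -2 * self.llf

    @property
    def auc(self) -> float:
        lp = self.model.exog @ self._params
        return float(roc_auc_score(self.model.y, lp))

    # -- prediction -----------------------------------------------------------

    def linear_predictor(self, dose, covariate_profile: Mapping[str, float] | None = None):
        profile = dict(covariate_profile or {})
        lp = np.full_like(np.asarray(dose, dtype=float), self._params[0], dtype=float)
        names = self.param_names
        if "dose" in names:
            lp = lp + self._params[names.index("dose")] * np.asarray(dose, dtype=float)
        for c in self.model.covariates:
            if c not in profile:
                raise KeyError(f"covariate profile missing {c!r}")
            lp = lp + self._params[names.index(c)] * float(profile[c])
        return lp

    def predict(self, dose, covariate_profile: Mapping[str, float] | None = None):
        """NTCP at the given dose(s) and covariate profile."""
        return _logistic(self.linear_predictor(dose, covariate_profile))

    # -- re-parameterization --------------------------------------------------

    @property
    def beta_dose(self) -> float:
        if "dose" not in self.param_names:
            raise KeyError("model was fitted without a dose term")
        return float(self._params[self.param_names.index("dose")])

    def d50_gamma(self, covariate_profile: Mapping[str, float] | None = None) -> DoseResponseParams:
        """D50 and gamma50 at a fixed covariate profile.

        ``d50 = -(b0 + sum_j bj x_j) / bD``; ``gamma50 = bD d50 / 4``.
        Requires a positive dose coefficient.
        """
        bD = self.beta_dose
        if bD <= 0:
            raise NonMonotoneResponseError(
                f"dose coefficient {bD:.4g} is not positive; no rising dose response"
            )
        profile = dict(covariate_profile or {})
        offset = self._params[0]
        for c in self.model.covariates:
            if c not in profile:
                raise KeyError(f"covariate profile missing {c!r}")
            offset += self._params[self.param_names.index(c)] * float(profile[c])
        d50 = -offset / bD
        return DoseResponseParams(d50=float(d50), gamma50=float(bD * d50 / 4))

    # -- bootstrap ------------------------------------------------------------

    def bootstrap(self, B: int = 2000, seed: int = 0) -> "BootstrapEnsemble":
        """Case-resampling bootstrap of the fit (see :func:`bootstrap`)."""
        return bootstrap(self.model.cohort, self.roi, self.model.covariates,
                         B=B, seed=seed, outcome=self.model.outcome_col,
                         include_dose=self.model.include_dose)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            f"NTCP logistic fit — ROI: {self.roi}",
            f"n = {self.n}, events = {int(self.model.y.sum())}, "
            f"logL = {self.llf:.3f}, BIC = {self.bic:.2f}, AUC = {self.auc:.4f}",
            "-" * 64,
            f"{'':<12}{'coef':>12}{'std err':>12}{'z':>10}{'P>|z|':>12}",
        ]
        for name in self.param_names:
            lines.append(
                f"{name:<12}{self.params[name]:>12.5f}{self.bse[name]:>12.5f}"
                f"{self.tvalues[name]:>10.3f}{self.pvalues[name]:>12.4g}"
            )
        lines.append("-" * 64)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "roi": self.roi,
            "param_names": self.param_names,
            "coefficients": self._params.tolist(),
            "covariance": self._cov.tolist(),
            "log_likelihood": self.llf,
            "n": self.n,
            "bic": self.bic,
            "auc": self.auc,
            "wald_p": self.pvalues.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class BootstrapEnsemble:
    """Case-resampled refits of one NTCP model.

    ``params`` is a (B, k) array with NaN rows for replicates whose
    refit failed (separation or non-convergence); ``converged`` flags
    each replicate.  The ensemble is fully determined by the seed and
    the cohort.
    """

    seed: int
    B: int
    param_names: list[str]
    params: np.ndarray = field(repr=False)
    converged: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        frac_failed = 1.0 - self.converged.mean()
        if frac_failed > 0.5:
            raise ConvergenceError(
                f"{frac_failed:.0%} of bootstrap replicates failed to converge"
            )
        if frac_failed > 0:
            warnings.warn(
                f"{int((~self.converged).sum())}/{self.B} bootstrap replicates "
                "failed to converge and are excluded from bands",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def n_converged(self) -> int:
        return int(self.converged.sum())

    @property
    def fits(self) -> pd.DataFrame:
        """Converged replicate coefficients, one row per replicate."""
        return pd.DataFrame(self.params[self.converged], columns=self.param_names)

    def coefficient_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Percentile interval for one coefficient."""
        vals = self.fits[name].to_numpy()
        lo, hi = np.percentile(vals, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
        return float(lo), float(hi)

    def predict_band(
        self,
        dose_grid: np.ndarray,
        covariate_profile: Mapping[str, float] | None = None,
        level: float = 0.95,
    ) -> pd.DataFrame:
        """Pointwise percentile band of NTCP over a dose grid."""
        grid = np.asarray(dose_grid, dtype=float)
        profile = dict(covariate_profile or {})
        names = self.param_names
        ok = self.params[self.converged]
        lp = np.tile(ok[:, [0]], (1, grid.size))
        if "dose" in names:
            lp = lp + ok[:, [names.index("dose")]] * grid[None, :]
        for c in names:
            if c in ("intercept", "dose"):
                continue
            if c not in profile:
                raise KeyError(f"covariate profile missing {c!r}")
            lp = lp + ok[:, [names.index(c)]] * float(profile[c])
        probs = _logistic(lp)
        qlo, qhi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        lo, hi = np.percentile(probs, [qlo, qhi], axis=0)
        return pd.DataFrame({"dose": grid, "lower": lo, "upper": hi})


# ---------------------------------------------------------------------------
# functional surface


def fit_mle(
    cohort: pd.DataFrame,
    roi: str,
    covariate_names: Sequence[str] = (),
    *,
    outcome: str = "outcome",
    include_dose: bool = True,
) -> NTCPResults:
    """Fit a logistic NTCP model by maximum likelihood (see :class:`NTCPModel`)."""
    return NTCPModel(cohort, roi, covariate_names, outcome=outcome,
                     include_dose=include_dose).fit()


def ntcp_probability(
    fit: NTCPResults, dose, covariate_profile: Mapping[str, float] | None = None
):
    """Modelled complication probability at ``dose`` for a covariate profile."""
    return fit.predict(dose, covariate_profile)


def negative_log_likelihood(
    params: Iterable[float],
    cohort: pd.DataFrame,
    roi: str,
    covariate_names: Sequence[str] = (),
    *,
    outcome: str = "outcome",
    include_dose: bool = True,
) -> float:
    """Bernoulli negative log-likelihood of a coefficient vector on a cohort."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    m = NTCPModel(cohort, roi, covariate_names, outcome=outcome, include_dose=include_dose)
    return m.nloglike(np.asarray(list(params), dtype=float))


def derive_d50_gamma(
    fit: NTCPResults, covariate_profile: Mapping[str, float] | None = None
) -> DoseResponseParams:
    """Two-parameter (D50, gamma50) form of a fitted model at a profile."""
    return fit.d50_gamma(covariate_profile)


def bootstrap(
    cohort: pd.DataFrame,
    roi: str,
    covariate_names: Sequence[str] = (),
    *,
    B: int = 2000,
    seed: int = 0,
    outcome: str = "outcome",
    include_dose: bool = True,
) -> BootstrapEnsemble:
    """Case-resampling bootstrap: refit on B resamples of size n.

    Replicates that separate or fail to converge are flagged and
    excluded from percentile bands; more than 50% failures raises a
    diagnostic error.  Identical seed and cohort give an identical
    ensemble.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(cohort)
    rng = np.random.default_rng(seed)
    template = NTCPModel(cohort, roi, covariate_names, outcome=outcome,
                         include_dose=include_dose)
    k = len(template.param_names)
    out = np.full((B, k), np.nan)
    ok = np.zeros(B, dtype=bool)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sample = cohort.iloc[idx]
        try:
            res = fit_mle(sample, roi, covariate_names, outcome=outcome,
                          include_dose=include_dose)
        except (SeparationError, ConvergenceError, DegenerateOutcomeError):
            continue
        out[b] = res._params
        ok[b] = True
    return BootstrapEnsemble(seed=seed, B=B, param_names=template.param_names,
                             params=out, converged=ok)
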