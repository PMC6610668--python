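"""End-to-end analysis orchestration: cohort + DVHs in, report bundle out.

The full chain is: parse cohort table → (optionally) reduce each
patient's per-ROI DVH to an EQD2 generalized mean dose → per-ROI
logistic (dose, age) fits → forward-stepwise covariate selection →
FDR/BIC/AUC diagnostics table → bootstrap ensembles → age-stratified
dose–response curves → age-stratified dose-constraint table, all
serialized as delimited tables plus a versioned JSON report.

A single master seed deterministically derives every per-stage seed,
so a rerun with the same config produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import constraints as _constraints
from . import dvh as _dvh
from . import model as _model
from . import selection as _selection
from . import simulate as _simulate

__all__ = ["RunConfig", "StageError", "run_full_analysis", "load_report",
           "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1"
logger = logging.getLogger("presbydose")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    cohort_path: str | None = None          # delimited cohort table; None -> simulate
    dvh_dir: str | None = None              # directory of <patient>_<roi>.csv DVHs
    output_dir: str = "presbydose_out"
    rois: tuple[str, ...] = _simulate.ROI_NAMES
    candidate_covariates: tuple[str, ...] = (
        "age", "sex_male", "t34", "n2b3", "smoking", "chemo_cisplatin",
    )
    alpha_beta: float = 3.0
    geud_exponents: Mapping[str, float] = field(default_factory=dict)  # default a=1
    default_total_dose: float = 70.0
    default_n_fractions: int = 35
    bootstrap_B: int = 2000
    risk_target: float = 0.05
    floor: float = 10.0
    seed: int = 0
    simulate_n: int = 300                   # used when cohort_path is None
    dose_grid_max: float = 80.0
    dose_grid_step: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.risk_target < 1:
            raise ValueError("risk_target must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rois" in raw:
            raw["rois"] = tuple(raw["rois"])
        if "candidate_covariates" in raw:
            raw["candidate_covariates"] = tuple(raw["candidate_covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rois"] = list(self.rois)
        d["candidate_covariates"] = list(self.candidate_covariates)
        d["geud_exponents"] = dict(self.geud_exponents)
        return d


def _stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Derive a deterministic 31-bit sub-seed for one stage."""
    tag = zlib.crc32(stage.encode("utf-8"))
    h = np.random.SeedSequence([master, tag, index])
    return int(h.generate_state(1)[0] % (2**31))


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns the report dict.  Any stage failure raises
    :class:`StageError` and removes files written so far.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    try:
        return _run(config, outdir, emit)
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # pragma: no cover - safety net
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError("unknown", str(exc)) from exc


def _run(config: RunConfig, outdir: Path, emit) -> dict:
    # -- stage: cohort --------------------------------------------------------
    if config.cohort_path is None:
        seed = _stage_seed(config.seed, "simulate")
        logger.info("stage simulate: n=%d seed=%d", config.simulate_n, seed)
        sim_cfg = _simulate.SimulationConfig(n=config.simulate_n, seed=seed)
        cohort = _simulate.simulate_cohort(sim_cfg)
    else:
        logger.info("stage load_cohort: %s", config.cohort_path)
        try:
            cohort = pd.read_csv(config.cohort_path)
        except Exception as exc:
            raise StageError("load_cohort", str(exc)) from exc
        for col in ("age", "outcome"):
            if col not in cohort.columns:
                raise StageError("load_cohort", f"cohort lacks required column {col!r}")

    # -- stage: DVH reduction -------------------------------------------------
    if config.dvh_dir is not None:
        params = _dvh.RadiobiologyParams(alpha_beta=config.alpha_beta)
        dvh_dir = Path(config.dvh_dir)
        for roi in config.rois:
            a = float(config.geud_exponents.get(roi, 1.0))
            col = []
            for _, row in cohort.iterrows():
                pid = str(row["patient_id"])
                path = dvh_dir / f"{pid}_{roi}.csv"
                if not path.exists():
                    raise StageError("reduce_dvh", f"missing DVH for patient {pid}, ROI {roi}")
                try:
                    with open(path) as fh:
                        cum = _dvh.parse_dvh(fh, roi_name=roi, kind="cumulative")
                    diff = _dvh.cumulative_to_differential(cum)
                    scheme = _dvh.FractionationScheme(
                        float(row.get("prescribed_dose", config.default_total_dose)),
                        int(row.get("n_fractions", config.default_n_fractions)),
                    )
                    eqd2 = _dvh.eqd2_transform(diff, scheme, params)
                    col.append(_dvh.generalized_mean_dose(eqd2, a))
                except (_dvh.DVHParseError, _dvh.DVHValidationError) as exc:
                    raise StageError("reduce_dvh", f"patient {pid}, ROI {roi}: {exc}") from exc
            cohort[_model.dose_column(roi)] = col
            logger.info("stage reduce_dvh: ROI %s a=%g alpha_beta=%g", roi, a, config.alpha_beta)
    missing = [r for r in config.rois if _model.dose_column(r) not in cohort.columns]
    if missing:
        raise StageError("reduce_dvh", f"no dose columns for ROIs {missing}")

    emit("cohort.csv", lambda p: cohort.to_csv(p, index=False))

    # -- stage: prevalence ----------------------------------------------------
    try:
        prevalence = _simulate.prevalence_by_stratum(cohort)
    except Exception as exc:
        raise StageError("prevalence", str(exc)) from exc
    emit("prevalence.csv", lambda p: prevalence.to_csv(p, index=False))

    # -- stage: per-ROI fits --------------------------------------------------
    fits: dict[str, _model.NTCPResults] = {}
    for roi in config.rois:
        try:
            fits[roi] = _model.fit_mle(cohort, roi, ["age"])
        except Exception as exc:
            raise StageError("fit", f"ROI {roi}: {exc}") from exc
        logger.info("stage fit: ROI %s BIC=%.2f AUC=%.3f", roi, fits[roi].bic, fits[roi].auc)

    # -- stage: covariate selection ------------------------------------------
    selections = {}
    for roi in config.rois:
        try:
            sel = _selection.forward_stepwise(cohort, roi, config.candidate_covariates)
        except Exception as exc:
            raise StageError("select", f"ROI {roi}: {exc}") from exc
        selections[roi] = sel
        logger.info("stage select: ROI %s selected=%s", roi, sel.selected)

    # -- stage: diagnostics ---------------------------------------------------
    try:
        diagnostics = _selection.diagnostics_table(fits)
    except Exception as exc:
        raise StageError("diagnostics", str(exc)) from exc
    emit("diagnostics.csv", lambda p: diagnostics.to_csv(p, index=False))

    # -- stage: bootstrap -----------------------------------------------------
    ensembles = {}
    for i, roi in enumerate(config.rois):
        seed = _stage_seed(config.seed, "bootstrap", i)
        try:
            ensembles[roi] = fits[roi].bootstrap(B=config.bootstrap_B, seed=seed)
        except Exception as exc:
            raise StageError("bootstrap", f"ROI {roi}: {exc}") from exc
        logger.info("stage bootstrap: ROI %s B=%d seed=%d converged=%d",
                    roi, config.bootstrap_B, seed, ensembles[roi].n_converged)

    # -- stage: curves --------------------------------------------------------
    grid = np.arange(0.0, config.dose_grid_max + config.dose_grid_step / 2,
                     config.dose_grid_step)
    curve_frames = []
    for roi in config.rois:
        try:
            cs = _constraints.ntcp_curves(fits[roi], ensembles[roi], grid)
        except Exception as exc:
            raise StageError("curves", f"ROI {roi}: {exc}") from exc
        curve_frames.append(cs.to_frame())
    curves_df = pd.concat(curve_frames, ignore_index=True)
    emit("curves.csv", lambda p: curves_df.to_csv(p, index=False))

    # -- stage: constraints ---------------------------------------------------
    try:
        table = _constraints.constraint_table(
            fits, risk=config.risk_target, floor=config.floor)
    except Exception as exc:
        raise StageError("constraints", str(exc)) from exc
    emit("constraints.csv", lambda p: table.data.to_csv(p, index=False))

    # -- stage: report --------------------------------------------------------
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "prevalence": prevalence.to_dict(orient="records"),
        "fits": {roi: fits[roi].to_dict() for roi in config.rois},
        "selection": {
            roi: {
                "candidates": selections[roi].candidate_covariates,
                "selected": selections[roi].selected,
                "bic_trace": selections[roi].bic_trace,
            } for roi in config.rois
        },
        "diagnostics": diagnostics.to_dict(orient="records"),
        "constraints": {
            "risk_target": table.risk_target,
            "floor": table.floor,
            "rows": json.loads(table.data.to_json(orient="records")),
        },
        "bootstrap": {
            roi: {
                "seed": ensembles[roi].seed,
                "B": ensembles[roi].B,
                "n_converged": ensembles[roi].n_converged,
            } for roi in config.rois
        },
    }
    emit("report.json", lambda p: p.write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"))
    return report


def load_report(path: str | Path) -> dict:
    """Read a report bundle back, checking its schema version."""
    with open(path) as fh:
        report = json.load(fh)
    version = report.get("schema_version")
    if version != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema version {version!r}")
    return report
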