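"""Dose–volume histograms and their reduction to summary doses.

A DVH describes, for one region of interest (ROI), how much of the
structure's volume receives each dose level.  Two conventions are
supported:

* *cumulative*: ``volume(D)`` is the fraction of the ROI receiving at
  least ``D`` Gy (non-increasing in dose);
* *differential*: each bin carries the volume fraction receiving a dose
  inside the bin (masses sum to one).

The reduction chain implemented here is the standard radiobiological
one: re-express each dose bin as its isoeffective dose in 2-Gy fractions
(EQD2, linear-quadratic model), then collapse the histogram to a single
generalized mean dose — the power mean ``(sum_i v_i D_i^a)^(1/a)``,
which for ``a = 1`` is the plain mean dose and for large ``a``
approaches the maximum dose (gEUD).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Union

import numpy as np
import pandas as pd

__all__ = [
    "DVH",
    "FractionationScheme",
    "RadiobiologyParams",
    "DVHValidationError",
    "DVHParseError",
    "parse_dvh",
    "write_dvh",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "eqd2_transform",
    "generalized_mean_dose",
]

#: any volume value above this is taken to be on the percent scale
PERCENT_DETECTION_THRESHOLD = 1.5

_DIFFERENTIAL_MASS_TOL = 1e-6


class DVHValidationError(ValueError):
    """A DVH violates a structural invariant."""


class DVHParseError(ValueError):
    """Input text could not be interpreted as a DVH."""


@dataclass(frozen=True)
class FractionationScheme:
    """Prescribed total dose and fraction count of a radiotherapy course."""

    total_dose: float
    n_fractions: int

    def __post_init__(self) -> None:
        if not self.total_dose > 0:
            raise ValueError(f"total_dose must be positive, got {self.total_dose}")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError(f"n_fractions must be a positive integer, got {self.n_fractions}")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


@dataclass(frozen=True)
class RadiobiologyParams:
    """Linear-quadratic parameters for fractionation correction.

    ``alpha_beta`` is the α/β ratio in Gy; late-responding muscle is
    conventionally taken at 3 Gy.  ``reference_dose_per_fraction`` is
    the fraction size the equivalent dose is expressed in (2 Gy).
    """

    alpha_beta: float = 3.0
    reference_dose_per_fraction: float = 2.0

    def __post_init__(self) -> None:
        if not self.alpha_beta > 0:
            raise ValueError(f"alpha_beta must be positive, got {self.alpha_beta}")


@dataclass(frozen=True)
class DVH:
    """A validated dose–volume histogram.

    ``bins`` holds (dose Gy, volume fraction) pairs with strictly
    increasing doses.  Volumes are always fractions in [0, 1].
    """

    roi_name: str
    kind: str  # "cumulative" | "differential"
    doses: np.ndarray = field(repr=False)
    volumes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "volumes", volumes)
        if self.kind not in ("cumulative", "differential"):
            raise DVHValidationError(f"unknown DVH kind {self.kind!r}")
        if doses.ndim != 1 or doses.shape != volumes.shape:
            raise DVHValidationError("doses and volumes must be 1-D arrays of equal length")
        if doses.size == 0:
            raise DVHValidationError("empty DVH")
        if np.any(doses < 0):
            raise DVHValidationError("negative dose bin")
        if np.any(np.diff(doses) <= 0):
            raise DVHValidationError("dose bins must be strictly increasing")
        if np.any(volumes < -1e-12):
            raise DVHValidationError("negative volume")
        if self.kind == "cumulative":
            if volumes[0] > 1 + 1e-9:
                raise DVHValidationError("cumulative DVH starts above volume 1")
            if np.any(np.diff(volumes) > 1e-12):
                raise DVHValidationError("cumulative volumes must be non-increasing")
        else:
            total = volumes.sum()
            if abs(total - 1.0) > _DIFFERENTIAL_MASS_TOL:
                raise DVHValidationError(
                    f"differential volumes must sum to 1 (got {total:.8f})"
                )

    def __len__(self) -> int:
        return int(self.doses.size)

    @property
    def bins(self) -> list[tuple[float, float]]:
        return list(zip(self.doses.tolist(), self.volumes.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.doses, "volume": self.volumes})


def parse_dvh(
    stream: Union[str, IO[str]],
    *,
    roi_name: str = "roi",
    kind: str = "cumulative",
    volume_unit: str = "auto",
    delimiter: str | None = None,
) -> DVH:
    """Parse a two-column delimited text DVH.

    Parameters
    ----------
    stream
        File-like object or string containing the table.  An optional
        single header line is tolerated.
    kind
        ``"cumulative"`` or ``"differential"``.
    volume_unit
        ``"percent"``, ``"fraction"``, or ``"auto"`` (percent is
        inferred when any volume exceeds 1.5).
    delimiter
        Column separator; ``None`` autodetects comma/tab/whitespace.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    if not text.strip():
        raise DVHParseError("empty DVH input")
    sep = delimiter if delimiter is not None else r"[,\t\s]+"
    try:
        df = pd.read_csv(
            io.StringIO(text), sep=sep, engine="python", header=None, comment="#",
            skip_blank_lines=True,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DVHParseError(f"could not read DVH table: {exc}") from exc
    # tolerate a single header line of non-numeric labels
    first = df.iloc[0]
    if not np.all([_is_number(v) for v in first]):
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise DVHParseError(f"expected 2 columns, found {df.shape[1]}")
    try:
        doses = df.iloc[:, 0].astype(float).to_numpy()
        volumes = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise DVHParseError(f"non-numeric DVH values: {exc}") from exc
    if doses.size == 0:
        raise DVHParseError("empty DVH table")
    if np.any(np.diff(doses) <= 0):
        raise DVHParseError("dose column must be strictly increasing")

    if volume_unit == "percent":
        volumes = volumes / 100.0
    elif volume_unit == "auto":
        if np.nanmax(volumes) > PERCENT_DETECTION_THRESHOLD:
            volumes = volumes / 100.0
    elif volume_unit != "fraction":
        raise ValueError(f"unknown volume_unit {volume_unit!r}")
    return DVH(roi_name=roi_name, kind=kind, doses=doses, volumes=volumes)


def write_dvh(dvh: DVH, stream: IO[str], *, delimiter: str = ",") -> None:
    """Write a DVH as two-column delimited text with fractional volumes."""
    stream.write(f"dose_gy{delimiter}volume\n")
    for d, v in zip(dvh.doses, dvh.volumes):
        stream.write(f"{d:.6g}{delimiter}{v:.10g}\n")


def cumulative_to_differential(dvh: DVH) -> DVH:
    """Convert a cumulative DVH to a differential one.

    Each interval between consecutive cumulative bins becomes one
    differential bin: mass = drop in cumulative volume, representative
    dose = interval midpoint.  Masses sum to (first − last) cumulative
    volume, so the input must span volume 1 → 0 (within 1e-6) for the
    result to satisfy the unit-mass invariant of differential DVHs;
    truncated cumulative histograms fail validation rather than being
    silently renormalized.
    """
    if dvh.kind != "cumulative":
        raise ValueError("input must be a cumulative DVH")
    if len(dvh) < 2:
        raise DVHValidationError("cumulative DVH needs at least 2 bins to differentiate")
    mids = 0.5 * (dvh.doses[:-1] + dvh.doses[1:])
    masses = -np.diff(dvh.volumes)
    return DVH(roi_name=dvh.roi_name, kind="differential", doses=mids, volumes=masses)


def differential_to_cumulative(dvh: DVH, *, bin_width: float | None = None) -> DVH:
    """Rebuild a cumulative DVH from a differential one.

    Bin edges are placed half-way between representative doses (bin
    midpoints map back to the edges they came from when the original
    spacing was uniform).
    """
    if dvh.kind != "differential":
        raise ValueError("input must be a differential DVH")
    mids = dvh.doses
    if len(dvh) == 1:
        w = bin_width if bin_width is not None else max(mids[0], 1.0)
        edges = np.array([mids[0] - w / 2, mids[0] + w / 2])
    else:
        inner = 0.5 * (mids[:-1] + mids[1:])
        first = mids[0] - (inner[0] - mids[0])
        last = mids[-1] + (mids[-1] - inner[-1])
        edges = np.concatenate([[max(first, 0.0)], inner, [last]])
    cum = 1.0 - np.concatenate([[0.0], np.cumsum(dvh.volumes)])
    cum = np.clip(cum, 0.0, 1.0)
    return DVH(roi_name=dvh.roi_name, kind="cumulative", doses=edges, volumes=cum)


def eqd2_transform(
    dvh: DVH,
    scheme: FractionationScheme,
    params: RadiobiologyParams = RadiobiologyParams(),
) -> DVH:
    """Re-express every differential dose bin as its 2-Gy-fraction equivalent.

    Under the linear-quadratic model a physical dose ``D`` delivered at
    fraction size ``d`` is isoeffective to ``D (d + α/β) / (2 + α/β)``
    delivered in 2-Gy fractions.  The per-bin fraction size is
    ``d_i = D_i / n_fractions`` (uniform fractionation across bins).
    Volumes are unchanged.  Doses at 2 Gy/fraction map to themselves.
    """
    if dvh.kind != "differential":
        raise ValueError("eqd2_transform expects a differential DVH")
    n = scheme.n_fractions
    if n == 0:
        raise ValueError("n_fractions must be nonzero")
    ab = params.alpha_beta
    ref = params.reference_dose_per_fraction
    d_per_fx = dvh.doses / n
    new_doses = dvh.doses * (d_per_fx + ab) / (ref + ab)
    # zero-dose bins stay at zero; strict monotonicity is preserved because
    # the map D -> D(D/n + ab) is strictly increasing for D >= 0
    return replace(dvh, doses=new_doses)


def generalized_mean_dose(dvh: DVH, a: float = 1.0) -> float:
    """Power-mean (gEUD) reduction of a differential DVH.

    Returns ``(sum_i v_i D_i^a)^(1/a)``.  ``a = 1`` is the mean dose;
    larger ``a`` weights hot spots more and tends to the maximum dose.
    ``a = 0`` (geometric mean) is not supported.
    """
    if dvh.kind != "differential":
        raise ValueError("generalized_mean_dose expects a differential DVH")
    if a == 0:
        raise ValueError("exponent a must be nonzero")
    doses = dvh.doses
    volumes = dvh.volumes
    if a > 0:
        # zero-dose bins contribute 0 mass to the sum
        s = float(np.sum(volumes * np.power(doses, a)))
        return float(s ** (1.0 / a))
    # a < 0: zero-dose bins dominate (limit -> 0) when they carry mass
    if np.any((doses == 0) & (volumes > 0)):
        return 0.0
    mask = volumes > 0
    s = float(np.sum(volumes[mask] * np.power(doses[mask], a)))
    return float(s ** (1.0 / a))


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False
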