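"""Cumulative dose–volume histograms and the named DVH metrics.

Every zone DVH is sampled on one fixed dose axis (0–400 % of prescription in
1 % steps, 401 nodes) so that the curves form fixed-length vectors suitable
for principal-component featurization across patients. Volumes are
fractional (relative to the zone), keeping curves commensurate across
patients and zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosimetry import DoseGrid

__all__ = ["DVH_AXIS", "DVHCurve", "DVHMetrics", "compute_dvh", "dvh_metric"]

#: fixed cumulative-DVH dose axis, % of prescription
DVH_AXIS = np.arange(0.0, 401.0, 1.0)


@dataclass
class DVHCurve:
    """Cumulative DVH of one zone: fraction of zone volume receiving >= d."""

    dose_axis: np.ndarray
    volume_fraction: np.ndarray
    zone_name: str = ""
    patient_id: str = ""
    empty: bool = False

    def __post_init__(self) -> None:
        self.dose_axis = np.asarray(self.dose_axis, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_axis.shape != self.volume_fraction.shape:
            raise ValueError("axis and volume arrays must align")
        if not self.empty:
            v = self.volume_fraction
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError("volume fractions must lie in [0, 1]")
            if np.any(np.diff(v) > 1e-12):
                raise ValueError("cumulative DVH must be non-increasing")


@dataclass(frozen=True)
class DVHMetrics:
    """The whole-organ planning metrics (doses in % of prescription)."""

    prostate_d90: float
    prostate_v100: float
    prostate_v150: float
    urethra_d5: float
    urethra_d30: float
    urethra_v150: float

    def __post_init__(self) -> None:
        if self.prostate_v100 < self.prostate_v150 - 1e-9:
            raise ValueError("V100 must not be below V150")
        if self.urethra_d5 < self.urethra_d30 - 1e-9:
            raise ValueError("D5 must not be below D30")


def compute_dvh(
    dose: DoseGrid,
    mask: np.ndarray,
    zone_name: str = "",
    patient_id: str = "",
    axis: np.ndarray = DVH_AXIS,
) -> DVHCurve:
    """Cumulative DVH of the masked voxels on the fixed axis.

    An empty mask yields an all-zero curve flagged ``empty`` rather than an
    error: tiny composite zones can vanish in small prostates.
    """
    mask = np.asarray(mask)
    doses = dose.dose_pct[mask] if mask.dtype == bool else dose.dose_pct[np.asarray(mask, int)]
    if doses.size == 0:
        return DVHCurve(axis, np.zeros_like(axis), zone_name, patient_id, empty=True)
    sorted_d = np.sort(doses)
    # fraction with dose >= d == (N - # strictly below d) / N
    frac = (doses.size - np.searchsorted(sorted_d, axis, side="left")) / doses.size
    return DVHCurve(axis, frac, zone_name, patient_id)


def dvh_metric(curve: DVHCurve, kind: str) -> float:
    """Evaluate a named metric on a cumulative DVH.

    ``kind`` is ``"D<x>"`` (minimum dose, % of prescription, to the hottest
    x % of the volume — the largest axis node d with V(d) >= x/100) or
    ``"V<y>"`` (fractional volume receiving at least y % of prescription,
    linearly interpolated between axis nodes).

    D_x uses the floor-node convention: the reported dose is the highest
    sampled node still covering the requested volume fraction, which is
    exact for piecewise-constant (voxelized) dose distributions and within
    one axis bin of the continuous quantile otherwise.
    """
    if curve.empty:
        raise ValueError(f"metric {kind!r} undefined on empty zone {curve.zone_name!r}")
    if len(kind) < 2 or kind[0] not in "DV":
        raise ValueError(f"unknown metric kind {kind!r}")
    value = float(kind[1:])
    axis, vol = curve.dose_axis, curve.volume_fraction

    if kind[0] == "V":
        if not 0.0 < value <= axis[-1]:
            raise ValueError(f"V_y dose {value} outside (0, {axis[-1]}]")
        return float(np.interp(value, axis, vol))

    q = value / 100.0
    if not 0.0 < q <= 1.0:
        raise ValueError(f"D_x percentage {value} outside (0, 100]")
    above = np.nonzero(vol >= q)[0]
    if above.size == 0:
        return 0.0
    return float(axis[int(above[-1])])
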