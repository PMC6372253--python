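"""Cumulative dose-volume histograms and scalar plan-quality metrics.

The cumulative DVH V(d) is the fraction of a structure receiving at least
dose d. All plan-quality endpoints used in this package derive from it:
Dv% (dose to the hottest v% of the volume), Vd (volume at dose), the
homogeneity index HI = 100*(D2% - D98%)/D50%, and mean/max dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DVHCurve",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "homogeneity_index",
    "hi_from_doses",
    "mean_dose",
    "max_point_dose",
    "v95_percent",
]

DEFAULT_BIN_GY = 0.05


@dataclass
class DVHCurve:
    """Cumulative DVH sampled at increasing dose edges.

    ``volume_fraction[i]`` is the fraction of the structure receiving at
    least ``dose_edges_Gy[i]``; it is monotone non-increasing, 1 at 0 Gy and
    0 beyond the maximum dose.
    """

    dose_edges_Gy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose_edges_Gy = np.asarray(self.dose_edges_Gy, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_edges_Gy.shape != self.volume_fraction.shape:
            raise ValueError("dose edges and volume fractions must have equal length")
        if np.any(np.diff(self.dose_edges_Gy) <= 0):
            raise ValueError("dose edges must be strictly increasing")

    def mean_dose_Gy(self) -> float:
        """Mean dose integrated from the curve: mean = ∫ V(d) dd."""
        return float(np.trapezoid(self.volume_fraction, self.dose_edges_Gy))


def compute_dvh(dose: np.ndarray, mask: np.ndarray, bin_width_Gy: float = DEFAULT_BIN_GY) -> DVHCurve:
    """Cumulative DVH of ``dose`` over a nonempty binary ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.sort(np.asarray(dose, dtype=float)[mask])
    dmax = vals[-1]
    n_bins = int(np.ceil(max(dmax, bin_width_Gy) / bin_width_Gy)) + 2
    edges = np.arange(n_bins) * bin_width_Gy
    # fraction with dose >= edge
    vf = 1.0 - np.searchsorted(vals, edges, side="left") / vals.size
    return DVHCurve(edges, vf)


def volume_at_dose(dvh: DVHCurve, dose_Gy: float) -> float:
    """Interpolated cumulative volume (percent) at a dose level."""
    if dose_Gy < 0:
        raise ValueError("dose must be nonnegative")
    if dose_Gy >= dvh.dose_edges_Gy[-1]:
        return float(100.0 * dvh.volume_fraction[-1])
    return float(100.0 * np.interp(dose_Gy, dvh.dose_edges_Gy, dvh.volume_fraction))


def dose_at_volume(dvh: DVHCurve, v_percent: float) -> float:
    """Inverse of the cumulative curve with linear interpolation (D2%, D50%, ...)."""
    if not 0 < v_percent <= 100:
        raise ValueError("volume percent must lie in (0, 100]")
    v = v_percent / 100.0
    vf = dvh.volume_fraction
    d = dvh.dose_edges_Gy
    if v <= vf[-1]:
        return float(d[-1])
    hits = np.nonzero(vf >= v)[0]
    if hits.size == 0:
        # band envelopes may start below 1 at zero dose; no dose level
        # reaches this volume fraction
        return float(d[0])
    # sup{d : V(d) >= v}: the last edge still at or above v, interpolated
    # into the following downward step (plateaus resolve to their high-dose
    # end, matching the sort-based definition of Dv%)
    idx = int(hits[-1])
    frac = (vf[idx] - v) / (vf[idx] - vf[idx + 1])
    return float(d[idx] + frac * (d[idx + 1] - d[idx]))


def hi_from_doses(d2_Gy: float, d98_Gy: float, d50_Gy: float) -> float:
    """Homogeneity index 100*(D2% - D98%)/D50% in percent; 0 = homogeneous."""
    if d50_Gy == 0:
        raise ValueError("D50 is zero; homogeneity index undefined")
    return 100.0 * (d2_Gy - d98_Gy) / d50_Gy


def homogeneity_index(dvh: DVHCurve) -> float:
    return hi_from_doses(dose_at_volume(dvh, 2), dose_at_volume(dvh, 98), dose_at_volume(dvh, 50))


def mean_dose(dose: np.ndarray, mask: np.ndarray) -> float:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(np.asarray(dose, dtype=float)[mask].mean())


def max_point_dose(dose: np.ndarray, mask: np.ndarray) -> float:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(np.asarray(dose, dtype=float)[mask].max())


def v95_percent(dose: np.ndarray, mask: np.ndarray, prescription_Gy: float,
                bin_width_Gy: float = DEFAULT_BIN_GY) -> float:
    """Percent of a target receiving at least 95% of its prescription."""
    return volume_at_dose(compute_dvh(dose, mask, bin_width_Gy), 0.95 * prescription_Gy)
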