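"""Cumulative dose-volume histograms and the standard planning endpoints.

A cumulative DVH reports, for each dose level d, the fraction of a
VOI's volume receiving at least d Gy.  The endpoints used throughout
treatment-plan comparison are:

* D_x  -- the minimum dose received by the hottest x% of the VOI
  (D5, D25, D50, D70, D95), computed by a rank rule on the raw voxel
  doses: sort descending and take the voxel at rank ceil(x*N/100),
  with no interpolation, so results are bit-reproducible.
* V_t  -- the percentage of the VOI receiving at least t Gy (V20, V100).
* D_mean -- the arithmetic mean voxel dose in the VOI.

Endpoints are always computed from raw voxel doses, never from the
binned curve; the curve exists for plotting and export.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from math import ceil

import numpy as np

from .voxel import DoseMap

__all__ = [
    "DvhCurve",
    "compute_dvh",
    "d_percent",
    "v_threshold",
    "d_mean_voi",
    "standard_endpoints",
]

#: The D_x percentages reported for every VOI.
STANDARD_D_PERCENTS = (5.0, 25.0, 50.0, 70.0, 95.0)


@dataclass(frozen=True)
class DvhCurve:
    """Cumulative DVH: fraction of volume receiving at least each dose."""

    dose_edges_Gy: np.ndarray
    volume_fraction_at_least: np.ndarray
    voi_name: str
    n_voxels: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges_Gy, dtype=float)
        frac = np.asarray(self.volume_fraction_at_least, dtype=float)
        if edges.shape != frac.shape:
            raise ValueError("edges and fractions must have the same length")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("dose edges must be strictly increasing")
        if np.any(np.diff(frac) > 0):
            raise ValueError("cumulative DVH must be non-increasing")
        object.__setattr__(self, "dose_edges_Gy", edges)
        object.__setattr__(self, "volume_fraction_at_least", frac)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["dose_Gy", "volume_fraction"])
            for d, f in zip(self.dose_edges_Gy, self.volume_fraction_at_least):
                writer.writerow([d, f])


def _voi_doses(dose: DoseMap, voi: np.ndarray) -> np.ndarray:
    voi = np.asarray(voi, dtype=bool)
    if voi.shape != dose.geometry.shape:
        raise ValueError("VOI mask shape does not match dose map")
    if not voi.any():
        raise ValueError("VOI is empty; DVH undefined")
    return dose.values[voi]


def compute_dvh(
    dose: DoseMap,
    voi: np.ndarray,
    bin_width_Gy: float = 0.5,
    voi_name: str = "",
) -> DvhCurve:
    """Cumulative 'volume receiving >= d' curve over the VOI's voxels."""
    if bin_width_Gy <= 0:
        raise ValueError("bin width must be positive")
    doses = _voi_doses(dose, voi)
    top = doses.max()
    n_bins = max(int(ceil(top / bin_width_Gy)), 1) + 1
    edges = np.arange(n_bins + 1) * bin_width_Gy
    # fraction of voxels with dose >= edge for every edge
    frac = 1.0 - np.searchsorted(np.sort(doses), edges, side="left") / doses.size
    return DvhCurve(
        dose_edges_Gy=edges,
        volume_fraction_at_least=frac,
        voi_name=voi_name,
        n_voxels=int(doses.size),
    )


def d_percent(dose: DoseMap, voi: np.ndarray, x: float) -> float:
    """D_x: the largest dose received by at least x% of the VOI, in Gy.

    Rank rule: descending sort, rank ceil(x*N/100), no interpolation.
    """
    if not (0.0 < x <= 100.0):
        raise ValueError("x must lie in (0, 100]")
    doses = np.sort(_voi_doses(dose, voi))[::-1]
    rank = ceil(x * doses.size / 100.0)
    return float(doses[rank - 1])


def v_threshold(dose: DoseMap, voi: np.ndarray, t_Gy: float) -> float:
    """V_t: percentage of VOI voxels receiving at least t Gy."""
    if t_Gy < 0:
        raise ValueError("threshold must be non-negative")
    doses = _voi_doses(dose, voi)
    return 100.0 * float(np.count_nonzero(doses >= t_Gy)) / doses.size


def d_mean_voi(dose: DoseMap, voi: np.ndarray) -> float:
    """Mean absorbed dose over the VOI's voxels, in Gy."""
    return float(_voi_doses(dose, voi).mean())


def standard_endpoints(
    dose: DoseMap,
    voi: np.ndarray,
    v_thresholds_Gy: tuple[float, ...] = (20.0, 100.0),
) -> dict[str, float]:
    """The endpoint set used for method comparison, keyed with units."""
    out: dict[str, float] = {"d_mean_Gy": d_mean_voi(dose, voi)}
    for x in STANDARD_D_PERCENTS:
        out[f"d{x:g}_Gy"] = d_percent(dose, voi, x)
    for t in v_thresholds_Gy:
        out[f"v{t:g}Gy_percent"] = v_threshold(dose, voi, t)
    return out
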