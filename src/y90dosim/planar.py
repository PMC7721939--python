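"""Lung shunt fraction from anterior/posterior planar counts.

The shunt fraction is the percentage of injected activity that bypasses
the liver capillary bed and lodges in the lungs.  It is estimated from a
pair of conjugate planar scintigraphy views as

    LSF(%) = 100 * C_lung / (C_lung + C_WL)

where each C is the geometric mean over the two views of the *total*
counts inside the corresponding ROI (not a pixel-wise geometric mean).
No attenuation or scatter correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CountImage

__all__ = ["PlanarStudy", "geometric_mean_counts", "lsf_percent", "lsf_from_study"]


@dataclass
class PlanarStudy:
    """Conjugate anterior/posterior planar views with 2D ROI masks."""

    anterior: CountImage
    posterior: CountImage
    rois: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anterior.geometry.shape != self.posterior.geometry.shape:
            raise ValueError(
                "anterior and posterior views have different shapes: "
                f"{self.anterior.geometry.shape} vs {self.posterior.geometry.shape}"
            )
        shape = self.anterior.geometry.shape
        checked = {}
        for name, roi in self.rois.items():
            roi = np.asarray(roi, dtype=bool)
            if roi.shape != shape:
                raise ValueError(
                    f"ROI {name!r} shape {roi.shape} does not match views {shape}"
                )
            checked[name] = roi
        self.rois = checked


def geometric_mean_counts(study: PlanarStudy, roi: str) -> float:
    """Geometric mean of the ROI's total counts over the two views."""
    if roi not in study.rois:
        raise KeyError(
            f"ROI {roi!r} not present; available: {sorted(study.rois)}"
        )
    mask = study.rois[roi]
    return float(np.sqrt(study.anterior.total(mask) * study.posterior.total(mask)))


def lsf_percent(c_lung: float, c_wl: float) -> float:
    """Lung shunt fraction in percent from lung and whole-liver counts."""
    if c_lung < 0 or c_wl < 0:
        raise ValueError("counts must be non-negative")
    if c_lung == 0 and c_wl == 0:
        raise ValueError("no counts in lung or liver ROI; LSF undefined")
    return 100.0 * c_lung / (c_lung + c_wl)


def lsf_from_study(
    study: PlanarStudy, lung_roi: str = "lung", liver_roi: str = "liver"
) -> float:
    """LSF in percent from a planar study's lung and whole-liver ROIs."""
    return lsf_percent(
        geometric_mean_counts(study, lung_roi),
        geometric_mean_counts(study, liver_roi),
    )
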