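"""Synthetic SPECT-like liver phantoms with known dosimetric ground truth.

No public MAA SPECT datasets with contoured VOIs exist, so every test
and demo runs on digital phantoms: an ellipsoidal liver on a cubic
voxel grid, spherical tumors with prescribed per-tumor uptake ratios
TNR_i, a uniform normal-liver activity concentration, and an optional
detector PSF (Gaussian blur) followed by Poisson counting noise.  The
planning target volume is either the whole liver or a half-plane cut
through it (emulating a lobar treatment).

The phantom is the inverse of the estimation pipeline: with no blur and
no noise, the pipeline recovers LSF, TNR, TNR_i, and every compartment
dose exactly from the generated images, and the generator's closed-form
doses provide the oracle.  The planar shunt study is synthesized as a
separate anterior/posterior pair (axis projections of the liver counts
plus a lung field holding the prescribed shunt), since shunt fractions
are measured on planar images only.

What the phantom does not emulate: collimator response, attenuation,
scatter, reconstruction artifacts, or intra-tumor uptake texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .compartments import (
    CompartmentDoseReport,
    cov_tnri,
    mtpm_dose_ti,
    pm_dose_nlt,
    pm_dose_tl,
    rescale_nlw,
)
from .core import (
    CountImage,
    GridGeometry,
    PhysicsConstants,
    TreatmentRecord,
    VoiSet,
)
from .planar import PlanarStudy

__all__ = ["TumorSpec", "PhantomSpec", "PhantomTruth", "generate", "cohort"]

DEFAULT_VOXEL_MM = 4.48
DEFAULT_SHAPE = (64, 64, 64)
#: Liver ellipsoid semi-axes giving a ~1.27 L adult liver.
DEFAULT_SEMI_AXES_MM = (85.0, 65.0, 55.0)


@dataclass(frozen=True)
class TumorSpec:
    """A spherical tumor: center and radius in mm, uptake ratio TNR_i."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    tnr_i: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if self.tnr_i < 0:
            raise ValueError("TNR_i must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic patient."""

    geometry: GridGeometry = field(
        default_factory=lambda: GridGeometry(DEFAULT_SHAPE, (DEFAULT_VOXEL_MM,) * 3)
    )
    liver_center_mm: tuple[float, float, float] | None = None
    liver_semi_axes_mm: tuple[float, float, float] = DEFAULT_SEMI_AXES_MM
    ptv: str = "whole"  # "whole" or "half" (half-plane cut along x)
    tumors: tuple[TumorSpec, ...] = ()
    nl_concentration_counts_per_mL: float = 1000.0
    lsf_percent: float = 6.1
    psf_sigma_mm: float = 0.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ptv not in ("whole", "half"):
            raise ValueError("ptv must be 'whole' or 'half'")
        if not self.tumors:
            raise ValueError("at least one tumor is required")
        if self.nl_concentration_counts_per_mL < 0:
            raise ValueError("concentration must be non-negative")
        if not (0.0 <= self.lsf_percent < 100.0):
            raise ValueError("lsf_percent must be in [0, 100)")
        if self.psf_sigma_mm < 0:
            raise ValueError("psf_sigma_mm must be non-negative")

    def center_mm(self) -> np.ndarray:
        if self.liver_center_mm is not None:
            return np.asarray(self.liver_center_mm, dtype=float)
        return (
            np.asarray(self.geometry.shape, dtype=float)
            * np.asarray(self.geometry.spacing_mm)
            / 2.0
        )


@dataclass
class PhantomTruth:
    """Generated images plus the ground truth that produced them."""

    spec: PhantomSpec
    vois: VoiSet
    counts: CountImage
    planar: PlanarStudy
    true_lsf_percent: float
    true_tnr: float
    true_tnr_i: dict[str, float]

    def expected_report(
        self,
        treatment: TreatmentRecord,
        constants: PhysicsConstants | None = None,
        method: str = "MTPM",
    ) -> CompartmentDoseReport:
        """Closed-form compartment doses from the true uptake ratios.

        Uses the voxelized VOI volumes (the same discretization the
        pipeline sees), so on a noiseless, unblurred phantom the
        pipeline must reproduce these values exactly.
        """
        constants = constants or PhysicsConstants()
        v_tl = self.vois.volume_mL("TL")
        v_nlt = self.vois.volume_mL("NLt")
        v_nlw = self.vois.volume_mL("NLw")
        a, lsf = treatment.activity_Y90_GBq, treatment.lsf_percent
        d_tl = pm_dose_tl(a, lsf, self.true_tnr, v_tl, v_nlt, constants)
        d_nlt = pm_dose_nlt(a, lsf, self.true_tnr, v_tl, v_nlt, constants)
        d_nlw = rescale_nlw(d_nlt, v_nlt, v_nlw)
        per_tumor = []
        for name, ti in self.true_tnr_i.items():
            if method == "PM":
                per_tumor.append((name, ti, d_tl))
            else:
                per_tumor.append(
                    (
                        name,
                        ti,
                        mtpm_dose_ti(
                            a, lsf, self.true_tnr, ti, v_tl, v_nlt, constants
                        ),
                    )
                )
        tis = list(self.true_tnr_i.values())
        cov = cov_tnri(tis) if (method == "MTPM" and len(tis) >= 2) else None
        return CompartmentDoseReport(
            method=method,
            d_mean_TL_Gy=d_tl,
            d_mean_NLt_Gy=d_nlt,
            d_mean_NLw_Gy=d_nlw,
            tnr=self.true_tnr,
            per_tumor=per_tumor,
            cov_tnri_percent=cov,
            volumes_mL={"TL": v_tl, "NLt": v_nlt, "NLw": v_nlw},
            constants=constants.describe(),
        )


def _voxel_centers_mm(geometry: GridGeometry) -> tuple[np.ndarray, ...]:
    axes = [
        (np.arange(n) + 0.5) * sp
        for n, sp in zip(geometry.shape, geometry.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def generate(spec: PhantomSpec) -> PhantomTruth:
    """Voxelize a phantom spec into images, masks, and ground truth."""
    geom = spec.geometry
    xx, yy, zz = _voxel_centers_mm(geom)
    cx, cy, cz = spec.center_mm()
    ax, ay, az = spec.liver_semi_axes_mm

    liver = (
        ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2
    ) <= 1.0
    if not liver.any():
        raise ValueError("liver ellipsoid contains no voxels on this grid")

    ptv = liver if spec.ptv == "whole" else (liver & (xx >= cx))

    tumors: dict[str, np.ndarray] = {}
    tnr_map = np.ones(geom.shape)
    for i, t in enumerate(spec.tumors):
        name = t.name or f"T{i + 1}"
        tx, ty, tz = t.center_mm
        mask = (
            (xx - tx) ** 2 + (yy - ty) ** 2 + (zz - tz) ** 2
        ) <= t.radius_mm**2
        if not mask.any():
            raise ValueError(
                f"tumor {name!r} (r={t.radius_mm} mm) contains no voxels"
            )
        n_out = int(np.count_nonzero(mask & ~ptv))
        if n_out:
            raise ValueError(
                f"tumor {name!r} escapes the PTV by {n_out} voxel(s)"
            )
        for other, omask in tumors.items():
            if (mask & omask).any():
                raise ValueError(f"tumors {name!r} and {other!r} overlap")
        tumors[name] = mask
        tnr_map[mask] = t.tnr_i

    vois = VoiSet(geometry=geom, wl=liver, ptv=ptv, tumors=tumors)

    # counts per voxel: concentration x voxel volume, scaled by TNR_i in
    # tumors, 1 in normal liver, 0 outside the liver
    base = spec.nl_concentration_counts_per_mL * geom.voxel_volume_mL
    values = np.where(liver, base * tnr_map, 0.0)

    rng = np.random.default_rng(spec.seed)
    if spec.psf_sigma_mm > 0:
        sigma_vox = [spec.psf_sigma_mm / sp for sp in geom.spacing_mm]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if spec.poisson_noise:
        values = rng.poisson(values).astype(float)
    counts = CountImage(geometry=geom, values=values)

    planar = _synthesize_planar(spec, values, rng)

    # ground-truth ratios from the voxelized masks (uniform per-tumor
    # concentration, so aggregate TNR is the volume-weighted TNR_i mean)
    true_tnr_i = {
        (t.name or f"T{i + 1}"): t.tnr_i for i, t in enumerate(spec.tumors)
    }
    v_tl = sum(int(m.sum()) for m in tumors.values())
    true_tnr = (
        sum(int(tumors[name].sum()) * ti for name, ti in true_tnr_i.items()) / v_tl
    )

    return PhantomTruth(
        spec=spec,
        vois=vois,
        counts=counts,
        planar=planar,
        true_lsf_percent=spec.lsf_percent,
        true_tnr=true_tnr,
        true_tnr_i=true_tnr_i,
    )


def _synthesize_planar(
    spec: PhantomSpec, volume_counts: np.ndarray, rng: np.random.Generator
) -> PlanarStudy:
    """Anterior/posterior views: liver projection plus a lung field.

    The liver field is the y-axis projection of the 3D counts; the lung
    field above it carries exactly the counts that make the geometric-
    mean shunt fraction equal the prescribed value.
    """
    geom = spec.geometry
    nx, _, nz = geom.shape
    lung_rows = max(nz // 4, 4)
    shape2d = (nx, nz + lung_rows)
    sp = geom.spacing_mm
    geom2d = GridGeometry(shape2d, (sp[0], sp[2]))

    canvas = np.zeros(shape2d)
    liver_proj = volume_counts.sum(axis=1)
    canvas[:, :nz] = liver_proj

    liver_roi = np.zeros(shape2d, dtype=bool)
    liver_roi[:, :nz] = liver_proj > 0
    lung_roi = np.zeros(shape2d, dtype=bool)
    lung_roi[nx // 4 : 3 * nx // 4, nz:] = True

    c_liver = float(liver_proj.sum())
    if spec.lsf_percent > 0 and c_liver > 0:
        c_lung = c_liver * spec.lsf_percent / (100.0 - spec.lsf_percent)
        canvas[lung_roi] = c_lung / lung_roi.sum()

    ant = canvas.copy()
    post = canvas.copy()
    if spec.poisson_noise:
        ant = rng.poisson(ant).astype(float)
        post = rng.poisson(post).astype(float)

    return PlanarStudy(
        anterior=CountImage(geometry=geom2d, values=ant),
        posterior=CountImage(geometry=geom2d, values=post),
        rois={"lung": lung_roi, "liver": liver_roi},
    )


# ---------------------------------------------------------------------------
# Randomized cohorts
# ---------------------------------------------------------------------------

def cohort(
    n: int,
    tnr_i_range: tuple[float, float] = (0.5, 3.5),
    tumor_volume_range_mL: tuple[float, float] = (0.6, 351.0),
    lsf_range_percent: tuple[float, float] = (1.4, 10.7),
    tumor_count_range: tuple[int, int] = (1, 15),
    seed: int = 0,
    **spec_overrides,
) -> list[PhantomSpec]:
    """A reproducible randomized cohort of phantom specs.

    Tumor volumes are drawn log-uniformly (small lesions dominate real
    cohorts), per-tumor uptake ratios and shunt fractions uniformly.
    Spheres are placed by rejection sampling inside the PTV with a
    one-voxel margin and no mutual overlap; if a sampled volume cannot
    be placed, it is halved and retried so every phantom keeps its
    sampled tumor count.  Per-phantom seeds derive from the master seed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    for rng_name, rng_range in [
        ("tnr_i_range", tnr_i_range),
        ("tumor_volume_range_mL", tumor_volume_range_mL),
        ("lsf_range_percent", lsf_range_percent),
    ]:
        lo, hi = rng_range
        if not (0 <= lo <= hi) or hi <= 0:
            raise ValueError(f"invalid {rng_name}: {rng_range}")
    lo_k, hi_k = tumor_count_range
    if not (1 <= lo_k <= hi_k):
        raise ValueError(f"invalid tumor_count_range: {tumor_count_range}")

    master = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(n)]
    rng = np.random.default_rng(master.spawn(1)[0])

    base = PhantomSpec(
        tumors=(TumorSpec((0, 0, 0), 1.0, 1.0),), **spec_overrides
    )  # template for geometry/ptv defaults; placeholder tumor replaced below
    geom = base.geometry
    center = base.center_mm()
    semi = np.asarray(base.liver_semi_axes_mm)
    margin = max(geom.spacing_mm)

    specs: list[PhantomSpec] = []
    for k in range(n):
        n_tumors = int(rng.integers(lo_k, hi_k + 1))
        placed: list[TumorSpec] = []
        for j in range(n_tumors):
            lo_v, hi_v = tumor_volume_range_mL
            vol = float(np.exp(rng.uniform(np.log(lo_v), np.log(hi_v))))
            tnr_i = float(rng.uniform(*tnr_i_range))
            while True:
                radius = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
                ok = False
                for _ in range(200):
                    u = rng.uniform(-1.0, 1.0, size=3)
                    pos = center + u * np.maximum(semi - radius - margin, 0.0)
                    inside = np.sum(
                        ((pos - center) / (semi - radius - margin)) ** 2
                    ) <= 1.0 if np.all(semi - radius - margin > 0) else False
                    if base.ptv == "half" and pos[0] < center[0] + radius:
                        inside = False
                    if not inside:
                        continue
                    clear = all(
                        np.linalg.norm(pos - np.asarray(t.center_mm))
                        > radius + t.radius_mm + margin
                        for t in placed
                    )
                    if clear:
                        placed.append(
                            TumorSpec(tuple(pos), radius, tnr_i, name=f"T{j + 1}")
                        )
                        ok = True
                        break
                if ok:
                    break
                vol /= 2.0  # could not place this size; try a smaller lesion
                if vol < 0.05:
                    raise RuntimeError("failed to place a tumor even at 0.05 mL")
        lsf = float(rng.uniform(*lsf_range_percent))
        specs.append(
            replace(
                base,
                tumors=tuple(placed),
                lsf_percent=lsf,
                seed=child_seeds[k],
            )
        )
    return specs
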