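"""Grid geometry, image containers, VOI algebra, and physics constants.

The in-memory model shared by every other module: a voxel grid with
physical spacing, non-negative count images on that grid, and labeled
binary volumes of interest (whole liver WL, planning target volume PTV,
individual tumors T_i) with the derived compartments used by the
partition models:

* TL   -- aggregated tumoral liver, the union of all T_i
* NL_t -- target normal liver, PTV minus TL
* NL_w -- whole normal liver, WL minus TL

Masks are binary voxel sets on the activity-image grid; sub-voxel
partial volumes are not modelled. World placement is carried only via
the NIfTI affine on I/O and never enters any computation here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridGeometry",
    "CountImage",
    "VoiSet",
    "PhysicsConstants",
    "TreatmentRecord",
    "derive_vois",
    "volume_mL",
    "MEV_TO_J",
]

#: Joules per MeV (CODATA, to the precision used in the dosimetry formulas).
MEV_TO_J = 1.6022e-13


@dataclass(frozen=True)
class GridGeometry:
    """A regular voxel grid: array shape plus physical spacing in mm."""

    shape: tuple[int, ...]
    spacing_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(shape) != len(spacing):
            raise ValueError(
                f"shape has {len(shape)} axes but spacing has {len(spacing)}"
            )
        if any(s <= 0 for s in shape):
            raise ValueError(f"all shape components must be positive, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def voxel_volume_mL(self) -> float:
        """Voxel volume in mL; product of spacings (mm^3) over 1000."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def is_cubic(self) -> bool:
        """True when all spacings agree to 1e-6 relative (required by LDM)."""
        s = np.asarray(self.spacing_mm)
        return bool(np.all(np.abs(s - s[0]) <= 1e-6 * s[0]))


@dataclass(frozen=True)
class CountImage:
    """Non-negative counts per voxel on a :class:`GridGeometry`."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("count image contains non-finite values")
        if np.any(values < 0):
            raise ValueError("count image contains negative values")
        object.__setattr__(self, "values", values)

    def total(self, mask: np.ndarray | None = None) -> float:
        """Total counts, optionally restricted to a binary mask."""
        if mask is None:
            return float(self.values.sum())
        return float(self.values[np.asarray(mask, dtype=bool)].sum())


def volume_mL(mask: np.ndarray, geometry: GridGeometry) -> float:
    """Volume of a binary mask in mL: voxel count times voxel volume.

    An empty mask yields 0 with a warning (usually a contouring mistake).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != geometry.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match geometry {geometry.shape}"
        )
    n = int(mask.sum())
    if n == 0:
        warnings.warn("volume_mL called on an empty mask", stacklevel=2)
    return n * geometry.voxel_volume_mL


@dataclass
class VoiSet:
    """Labeled binary masks (WL, PTV, T_1..T_n) with derived compartments.

    The derived masks TL, NL_t, NL_w are recomputed on access and never
    stored, so they cannot go stale if a tumor mask is replaced.
    Construction enforces the containment hierarchy T_i subset-of PTV
    subset-of WL and pairwise tumor disjointness.
    """

    geometry: GridGeometry
    wl: np.ndarray
    ptv: np.ndarray
    tumors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wl = self._check_mask(self.wl, "WL")
        self.ptv = self._check_mask(self.ptv, "PTV")
        self.tumors = {
            name: self._check_mask(m, name) for name, m in self.tumors.items()
        }
        if not self.tumors:
            raise ValueError("at least one tumor mask is required")

        n_out = int(np.count_nonzero(self.ptv & ~self.wl))
        if n_out:
            raise ValueError(f"PTV extends outside WL by {n_out} voxel(s)")
        names = list(self.tumors)
        for i, a in enumerate(names):
            n_out = int(np.count_nonzero(self.tumors[a] & ~self.ptv))
            if n_out:
                raise ValueError(
                    f"tumor {a!r} extends outside PTV by {n_out} voxel(s)"
                )
            for b in names[i + 1 :]:
                n_ov = int(np.count_nonzero(self.tumors[a] & self.tumors[b]))
                if n_ov:
                    raise ValueError(
                        f"tumors {a!r} and {b!r} overlap in {n_ov} voxel(s)"
                    )

    def _check_mask(self, mask: np.ndarray, name: str) -> np.ndarray:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.geometry.shape:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        return mask

    # -- derived compartments (recomputed, never cached) ----------------

    @property
    def tl(self) -> np.ndarray:
        """Aggregated tumoral liver: union of all individual tumors."""
        out = np.zeros(self.geometry.shape, dtype=bool)
        for m in self.tumors.values():
            out |= m
        return out

    @property
    def nlt(self) -> np.ndarray:
        """Target normal liver: PTV with the aggregated tumor removed."""
        return self.ptv & ~self.tl

    @property
    def nlw(self) -> np.ndarray:
        """Whole normal liver: WL with the aggregated tumor removed."""
        return self.wl & ~self.tl

    def mask(self, name: str) -> np.ndarray:
        """Look up any named mask: WL, PTV, TL, NLt, NLw, or a tumor name."""
        key = name.upper()
        if key == "WL":
            return self.wl
        if key == "PTV":
            return self.ptv
        if key == "TL":
            return self.tl
        if key == "NLT":
            return self.nlt
        if key == "NLW":
            return self.nlw
        if name in self.tumors:
            return self.tumors[name]
        raise KeyError(f"unknown VOI {name!r}")

    def volume_mL(self, name: str) -> float:
        return volume_mL(self.mask(name), self.geometry)

    @property
    def tumor_names(self) -> list[str]:
        return list(self.tumors)


def derive_vois(
    geometry: GridGeometry,
    wl: np.ndarray,
    ptv: np.ndarray,
    tumors: dict[str, np.ndarray],
) -> VoiSet:
    """Build a validated :class:`VoiSet` from raw labeled masks.

    Raises on overlapping tumors or a tumor escaping the PTV, naming the
    offending voxel count.
    """
    return VoiSet(geometry=geometry, wl=wl, ptv=ptv, tumors=tumors)


@dataclass(frozen=True)
class PhysicsConstants:
    """Y-90 dosimetry constants and the density/consistency conventions.

    ``energy_per_GBq_J`` is the total beta energy released per GBq of
    permanently trapped Y-90 (49.67 J/GBq as used by the compartment
    equations).  ``mean_beta_MeV_per_decay`` and ``half_life_h`` are the
    per-decay mean beta energy and the physical half-life.  These three
    printed constants are mutually inconsistent at the third digit
    (0.9267 MeV with T1/2 = 64.2 h integrates to ~49.52 J/GBq, not
    49.67), and the voxel S-value that reproduces the conventional
    1.603 Gy/(GBq.s) at 4.48 mm implies a 1.03 g/mL density while the
    compartment equations assume 1 g/mL.  ``consistency_mode`` selects
    how to resolve this:

    * ``"paper"`` (default): keep every constant as conventionally
      printed; uniform-activity voxel dose then differs from the
      compartment dose by a fixed ~3.3% factor.
    * ``"consistent"``: derive the voxel energy rate from
      ``energy_per_GBq_J`` and use the compartment density for voxels,
      so uniform-activity local-deposition dose equals the partition
      models exactly.
    """

    energy_per_GBq_J: float = 49.67
    half_life_h: float = 64.2
    mean_beta_MeV_per_decay: float = 0.9267
    voxel_density_g_per_mL: float = 1.03
    compartment_density_g_per_mL: float = 1.0
    consistency_mode: str = "paper"

    def __post_init__(self) -> None:
        for name in (
            "energy_per_GBq_J",
            "half_life_h",
            "mean_beta_MeV_per_decay",
            "voxel_density_g_per_mL",
            "compartment_density_g_per_mL",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.consistency_mode not in ("paper", "consistent"):
            raise ValueError(
                f"consistency_mode must be 'paper' or 'consistent', "
                f"got {self.consistency_mode!r}"
            )

    @property
    def half_life_s(self) -> float:
        return self.half_life_h * 3600.0

    @property
    def cumulation_factor_s(self) -> float:
        """Seconds of cumulated activity per unit activity: 1.443 x T1/2."""
        return 1.443 * self.half_life_s

    @property
    def energy_rate_J_per_GBq_s(self) -> float:
        """Beta energy released per GBq.s of cumulated activity, in J.

        In ``paper`` mode this is <E_beta> in J times 1e9 decays per
        GBq.s; in ``consistent`` mode it is derived from the compartment
        constant so that integrating over 1.443 x T1/2 recovers
        ``energy_per_GBq_J`` exactly.
        """
        if self.consistency_mode == "consistent":
            return self.energy_per_GBq_J / self.cumulation_factor_s
        return self.mean_beta_MeV_per_decay * MEV_TO_J * 1e9

    @property
    def effective_voxel_density_g_per_mL(self) -> float:
        """Voxel density actually used by the voxel engines for this mode."""
        if self.consistency_mode == "consistent":
            return self.compartment_density_g_per_mL
        return self.voxel_density_g_per_mL

    def describe(self) -> dict[str, float | str]:
        """All constants in effect, for provenance logging."""
        return {
            "energy_per_GBq_J": self.energy_per_GBq_J,
            "half_life_h": self.half_life_h,
            "mean_beta_MeV_per_decay": self.mean_beta_MeV_per_decay,
            "voxel_density_g_per_mL": self.voxel_density_g_per_mL,
            "compartment_density_g_per_mL": self.compartment_density_g_per_mL,
            "consistency_mode": self.consistency_mode,
            "energy_rate_J_per_GBq_s": self.energy_rate_J_per_GBq_s,
            "cumulation_factor_s": self.cumulation_factor_s,
        }


@dataclass(frozen=True)
class TreatmentRecord:
    """Administered Y-90 activity, lung shunt fraction, and approach."""

    activity_Y90_GBq: float
    lsf_percent: float = 0.0
    approach: str = "lobar"

    def __post_init__(self) -> None:
        if self.activity_Y90_GBq <= 0:
            raise ValueError("activity must be positive")
        if not (0.0 <= self.lsf_percent < 100.0):
            raise ValueError("lsf_percent must be in [0, 100)")
        if self.approach not in ("whole_liver", "lobar", "segmental"):
            raise ValueError(
                "approach must be 'whole_liver', 'lobar' or 'segmental', "
                f"got {self.approach!r}"
            )

    @property
    def liver_activity_GBq(self) -> float:
        """Activity reaching the liver: A x (1 - LSF/100)."""
        return self.activity_Y90_GBq * (1.0 - self.lsf_percent / 100.0)
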