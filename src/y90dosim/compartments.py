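"""Compartmental mean-dose models: the partition model and its
multi-tumor extension.

The classic partition model (PM) splits the treated liver into three
compartments — aggregated tumor (TL), target normal liver (NL_t), and
lung — and distributes the administered Y-90 activity among them in
proportion to volume and to the tumor-to-normal-liver activity
concentration ratio TNR measured on the MAA SPECT:

    D_TL  = 49.67 * A * (1 - LSF/100) * TNR / (M_TL * TNR + M_NLt)
    D_NLt = 49.67 * A * (1 - LSF/100)       / (M_TL * TNR + M_NLt)

with masses in kg from volumes at the compartment tissue density
(1 g/mL by default).  The whole-normal-liver dose is the NL_t dose
rescaled by the mass ratio M_NLt / M_NLw.

The multi-tumor partition model (MTPM) is an (n + 2)-compartment
extension that keeps the aggregate TNR in the denominator but replaces
the numerator TNR with the per-tumor concentration ratio TNR_i, giving
each individual tumor its own mean dose.  The volume-weighted mean of
the MTPM per-tumor doses recovers the PM aggregated-tumor dose exactly
whenever TNR and TNR_i come from the same count image.

Heterogeneity of uptake among tumors is summarized by the coefficient
of variation of the TNR_i values (sample SD over mean, in percent).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .core import CountImage, PhysicsConstants, TreatmentRecord, VoiSet

__all__ = [
    "CompartmentDoseReport",
    "tnr",
    "tnr_i",
    "pm_dose_tl",
    "pm_dose_nlt",
    "rescale_nlw",
    "mtpm_dose_ti",
    "cov_tnri",
    "compartment_report",
]


# ---------------------------------------------------------------------------
# Concentration ratios
# ---------------------------------------------------------------------------

def _concentration_ratio(
    counts: CountImage, num_mask: np.ndarray, vois: VoiSet, label: str
) -> float:
    nlt = vois.nlt
    if not num_mask.any():
        raise ValueError(f"{label} mask is empty; concentration ratio undefined")
    if not nlt.any():
        raise ValueError("NLt mask is empty; concentration ratio undefined")
    c_nlt = counts.total(nlt)
    if c_nlt == 0:
        raise ValueError("zero counts in NLt; concentration ratio undefined")
    v_num = num_mask.sum() * vois.geometry.voxel_volume_mL
    v_nlt = nlt.sum() * vois.geometry.voxel_volume_mL
    return (counts.total(num_mask) / v_num) / (c_nlt / v_nlt)


def tnr(counts: CountImage, vois: VoiSet) -> float:
    """Aggregate tumor-to-normal-liver activity concentration ratio.

    (C_TL / V_TL) / (C_NLt / V_NLt) from total counts and volumes.
    """
    return _concentration_ratio(counts, vois.tl, vois, "TL")


def tnr_i(counts: CountImage, vois: VoiSet, tumor: str) -> float:
    """Per-tumor concentration ratio (C_Ti / V_Ti) / (C_NLt / V_NLt)."""
    if tumor not in vois.tumors:
        raise KeyError(f"unknown tumor {tumor!r}; have {vois.tumor_names}")
    return _concentration_ratio(counts, vois.tumors[tumor], vois, tumor)


# ---------------------------------------------------------------------------
# Partition-model doses
# ---------------------------------------------------------------------------

def _mass_kg(volume_mL: float, constants: PhysicsConstants) -> float:
    return volume_mL * constants.compartment_density_g_per_mL / 1000.0


def pm_dose_tl(
    activity_GBq: float,
    lsf_percent: float,
    tnr: float,
    v_TL_mL: float,
    v_NLt_mL: float,
    constants: PhysicsConstants | None = None,
) -> float:
    """Partition-model mean dose to the aggregated tumor, in Gy."""
    constants = constants or PhysicsConstants()
    if v_TL_mL <= 0 or v_NLt_mL <= 0:
        raise ValueError("compartment volumes must be positive")
    if tnr <= 0:
        raise ValueError("TNR must be positive")
    m_tl = _mass_kg(v_TL_mL, constants)
    m_nlt = _mass_kg(v_NLt_mL, constants)
    numerator = (
        constants.energy_per_GBq_J
        * activity_GBq
        * (1.0 - lsf_percent / 100.0)
        * tnr
    )
    return numerator / (m_tl * tnr + m_nlt)


def pm_dose_nlt(
    activity_GBq: float,
    lsf_percent: float,
    tnr: float,
    v_TL_mL: float,
    v_NLt_mL: float,
    constants: PhysicsConstants | None = None,
) -> float:
    """Partition-model mean dose to the target normal liver, in Gy."""
    constants = constants or PhysicsConstants()
    if v_TL_mL <= 0 or v_NLt_mL <= 0:
        raise ValueError("compartment volumes must be positive")
    if tnr <= 0:
        raise ValueError("TNR must be positive")
    m_tl = _mass_kg(v_TL_mL, constants)
    m_nlt = _mass_kg(v_NLt_mL, constants)
    numerator = (
        constants.energy_per_GBq_J * activity_GBq * (1.0 - lsf_percent / 100.0)
    )
    return numerator / (m_tl * tnr + m_nlt)


def rescale_nlw(d_nlt_Gy: float, v_NLt_mL: float, v_NLw_mL: float) -> float:
    """Whole-normal-liver dose: NL_t dose rescaled by the mass ratio."""
    if v_NLt_mL <= 0:
        raise ValueError("V_NLt must be positive")
    if v_NLw_mL < v_NLt_mL:
        raise ValueError(
            f"V_NLw ({v_NLw_mL} mL) cannot be smaller than V_NLt ({v_NLt_mL} mL)"
        )
    # densities cancel in the mass ratio
    return d_nlt_Gy * v_NLt_mL / v_NLw_mL


def mtpm_dose_ti(
    activity_GBq: float,
    lsf_percent: float,
    tnr: float,
    tnr_i: float,
    v_TL_mL: float,
    v_NLt_mL: float,
    constants: PhysicsConstants | None = None,
) -> float:
    """Multi-tumor partition-model mean dose to one tumor, in Gy.

    The aggregate TNR stays in the denominator (it fixes the activity
    split between tumor and normal compartments); the numerator carries
    the individual tumor's TNR_i.
    """
    if tnr_i < 0:
        raise ValueError("TNR_i must be non-negative")
    base = pm_dose_nlt(activity_GBq, lsf_percent, tnr, v_TL_mL, v_NLt_mL, constants)
    return base * tnr_i


def cov_tnri(values) -> float:
    """Coefficient of variation of per-tumor TNR_i values, in percent.

    Sample (n-1) standard deviation over the mean.  Requires at least
    two tumors and a nonzero mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("COV(TNRi) requires at least two tumors")
    mean = values.mean()
    if mean == 0:
        raise ValueError("COV(TNRi) undefined for zero mean")
    return 100.0 * values.std(ddof=1) / mean


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class CompartmentDoseReport:
    """Per-compartment mean doses from PM or MTPM, with provenance."""

    method: str
    d_mean_TL_Gy: float
    d_mean_NLt_Gy: float
    d_mean_NLw_Gy: float
    tnr: float
    per_tumor: list[tuple[str, float, float]] = field(default_factory=list)
    cov_tnri_percent: float | None = None
    volumes_mL: dict[str, float] = field(default_factory=dict)
    constants: dict | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "tnr": self.tnr,
            "d_mean_TL_Gy": self.d_mean_TL_Gy,
            "d_mean_NLt_Gy": self.d_mean_NLt_Gy,
            "d_mean_NLw_Gy": self.d_mean_NLw_Gy,
            "cov_tnri_percent": self.cov_tnri_percent,
            "per_tumor": [
                {"tumor": name, "tnr_i": ti, "d_mean_Gy": d}
                for name, ti, d in self.per_tumor
            ],
            "volumes_mL": self.volumes_mL,
            "constants": self.constants,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        """One row per compartment/tumor: name, volume mL, TNRi, D_mean Gy."""
        rows = [
            ("TL", self.volumes_mL.get("TL"), self.tnr, self.d_mean_TL_Gy),
            ("NLt", self.volumes_mL.get("NLt"), None, self.d_mean_NLt_Gy),
            ("NLw", self.volumes_mL.get("NLw"), None, self.d_mean_NLw_Gy),
        ] + [
            (name, self.volumes_mL.get(name), ti, d)
            for name, ti, d in self.per_tumor
        ]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["compartment", "volume_mL", "tnr_i", "d_mean_Gy", "method"]
            )
            for name, vol, ti, d in rows:
                writer.writerow([name, vol, ti, d, self.method])


def compartment_report(
    counts: CountImage,
    vois: VoiSet,
    treatment: TreatmentRecord,
    constants: PhysicsConstants | None = None,
    method: str = "MTPM",
) -> CompartmentDoseReport:
    """Run PM or MTPM end to end on a count image and VOI set.

    With ``method="PM"`` every per-tumor dose equals the aggregated
    tumor dose (the classic model cannot see individual tumors); with
    ``method="MTPM"`` each tumor gets its own TNR_i-weighted dose.
    """
    if method not in ("PM", "MTPM"):
        raise ValueError(f"method must be 'PM' or 'MTPM', got {method!r}")
    constants = constants or PhysicsConstants()

    geom = vois.geometry
    vols = {
        "TL": vois.volume_mL("TL"),
        "NLt": vois.volume_mL("NLt"),
        "NLw": vois.volume_mL("NLw"),
    }
    for name in vois.tumor_names:
        vols[name] = vois.volume_mL(name)

    tnr_value = tnr(counts, vois)
    a = treatment.activity_Y90_GBq
    lsf = treatment.lsf_percent
    d_tl = pm_dose_tl(a, lsf, tnr_value, vols["TL"], vols["NLt"], constants)
    d_nlt = pm_dose_nlt(a, lsf, tnr_value, vols["TL"], vols["NLt"], constants)
    d_nlw = rescale_nlw(d_nlt, vols["NLt"], vols["NLw"])

    per_tumor: list[tuple[str, float, float]] = []
    tnr_is: list[float] = []
    for name in vois.tumor_names:
        ti = tnr_i(counts, vois, name)
        tnr_is.append(ti)
        if method == "PM":
            per_tumor.append((name, ti, d_tl))
        else:
            d_i = mtpm_dose_ti(
                a, lsf, tnr_value, ti, vols["TL"], vols["NLt"], constants
            )
            per_tumor.append((name, ti, d_i))

    cov = cov_tnri(tnr_is) if (method == "MTPM" and len(tnr_is) >= 2) else None
    return CompartmentDoseReport(
        method=method,
        d_mean_TL_Gy=d_tl,
        d_mean_NLt_Gy=d_nlt,
        d_mean_NLw_Gy=d_nlw,
        tnr=tnr_value,
        per_tumor=per_tumor,
        cov_tnri_percent=cov,
        volumes_mL=vols,
        constants=constants.describe(),
    )
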