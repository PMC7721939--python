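"""NIfTI and sidecar I/O for images, label maps, and dose maps.

Images travel as NIfTI-1 (plain or gzipped); voxel spacing is taken
from the header zooms, and the affine is carried through round trips
but never used in any computation.  VOI sets are stored as a single
integer label map plus a JSON role map binding label values to roles:

    {"WL": 1, "PTV": 2, "T1": 3, "T2": 4}

Labels partition the liver: voxels labeled ``WL`` are liver outside the
PTV, voxels labeled ``PTV`` are target normal liver, and each tumor has
its own label.  The nested masks are reassembled on read (WL = all
labeled voxels, PTV = PTV label plus tumors, T_i = its own label), so
the containment hierarchy holds by construction.

Dose and activity maps are written with a JSON sidecar recording units
and every physics constant in effect.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import CountImage, GridGeometry, VoiSet
from .voxel import ActivityMap, DoseMap

__all__ = [
    "read_image",
    "write_image",
    "read_labelmap",
    "write_labelmap",
    "write_map_with_sidecar",
]


def _geometry_from_nifti(img: nib.Nifti1Image) -> GridGeometry:
    shape = tuple(int(s) for s in img.shape)
    zooms = tuple(float(z) for z in img.header.get_zooms()[: len(shape)])
    return GridGeometry(shape, zooms)


def read_image(path) -> CountImage:
    """Read a 2D or 3D NIfTI count image; spacing from the header."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return CountImage(geometry=_geometry_from_nifti(img), values=data)


def write_image(
    values: np.ndarray, spacing_mm, path, dtype=np.float64
) -> None:
    """Write an array as NIfTI with a diagonal affine from the spacing."""
    values = np.asarray(values, dtype=dtype)
    spacing = tuple(float(s) for s in spacing_mm)
    affine = np.diag(list(spacing) + [1.0] * (4 - len(spacing)))
    img = nib.Nifti1Image(values, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_labelmap(vois: VoiSet, path, roles_path) -> None:
    """Write a VOI set as one integer label map plus a JSON role map."""
    labels = np.zeros(vois.geometry.shape, dtype=np.int16)
    roles: dict[str, int] = {"WL": 1, "PTV": 2}
    labels[vois.wl & ~vois.ptv] = 1
    labels[vois.nlt] = 2
    next_label = 3
    for name in vois.tumor_names:
        roles[name] = next_label
        labels[vois.tumors[name]] = next_label
        next_label += 1
    write_image(labels, vois.geometry.spacing_mm, path, dtype=np.int16)
    with open(roles_path, "w") as fh:
        json.dump(roles, fh, indent=2)


def read_labelmap(path, roles_path) -> VoiSet:
    """Rebuild a VOI set from a label map and its JSON role map."""
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(int)
    geometry = _geometry_from_nifti(img)
    with open(roles_path) as fh:
        roles = json.load(fh)
    for required in ("WL", "PTV"):
        if required not in roles:
            raise ValueError(f"role map {roles_path} is missing the {required!r} role")
    tumor_roles = {k: v for k, v in roles.items() if k not in ("WL", "PTV")}
    if not tumor_roles:
        raise ValueError(f"role map {roles_path} defines no tumor labels")
    tumors = {name: labels == lab for name, lab in tumor_roles.items()}
    tl = np.zeros(geometry.shape, dtype=bool)
    for m in tumors.values():
        tl |= m
    ptv = (labels == roles["PTV"]) | tl
    wl = (labels == roles["WL"]) | ptv
    return VoiSet(geometry=geometry, wl=wl, ptv=ptv, tumors=tumors)


def write_map_with_sidecar(
    dose_or_activity: DoseMap | ActivityMap,
    path,
    units: str,
    metadata: dict | None = None,
) -> None:
    """Write a dose/activity map as NIfTI plus a JSON units sidecar."""
    obj = dose_or_activity
    write_image(obj.values, obj.geometry.spacing_mm, path)
    sidecar = {"units": units}
    if metadata:
        sidecar.update(metadata)
    sidecar_path = Path(str(path))
    while sidecar_path.suffix in (".gz", ".nii"):
        sidecar_path = sidecar_path.with_suffix("")
    with open(str(sidecar_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
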