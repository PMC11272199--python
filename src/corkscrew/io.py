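"""NIfTI-1 and tabular I/O.

Volumes are written as uncompressed ``.nii`` with a diagonal affine
carrying the voxel spacing (so re-running a pipeline with the same seed
reproduces byte-identical files).  Acquisition context (echo time,
contrast state) travels in the NIfTI description field.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import ImageVolume

__all__ = ["save_volume", "load_volume", "save_centerline_csv",
           "save_truth_sidecar"]


def save_volume(volume: ImageVolume, path):
    """Write an :class:`ImageVolume` as NIfTI-1."""
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing_mm)
    img.header["descrip"] = (
        f"TE={volume.TE_ms}ms;{volume.contrast_state}".encode()[:79]
    )
    nib.save(img, str(path))


def load_volume(path, TE_ms=None, contrast_state=None) -> ImageVolume:
    """Read a NIfTI volume; spacing from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    desc = img.header["descrip"].tobytes().decode(errors="ignore")
    if TE_ms is None and "TE=" in desc:
        try:
            TE_ms = float(desc.split("TE=")[1].split("ms")[0])
        except ValueError:
            TE_ms = 0.0
    if contrast_state is None:
        contrast_state = "post" if "post" in desc else "pre"
    return ImageVolume(data=np.clip(data, 0.0, None), spacing_mm=spacing,
                       TE_ms=TE_ms or 0.0, contrast_state=contrast_state)


def save_centerline_csv(centerline, path):
    """Serialize a centerline as x_mm,y_mm,z_mm,arclen_mm CSV."""
    arr = np.column_stack([centerline.points, centerline.arclen])
    header = "x_mm,y_mm,z_mm,arclen_mm"
    np.savetxt(str(path), arr, delimiter=",", header=header, comments="")


def save_truth_sidecar(spec, path):
    """Ground-truth JSON sidecar for a phantom spec."""
    payload = {
        "fov_mm": list(spec.fov_mm),
        "spacing_mm": list(spec.spacing_mm),
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "vessels": [
            {
                "kind": v.curve.kind,
                "params": {k: val for k, val in v.curve.params.items()
                           if not isinstance(val, np.ndarray)},
                "radius_mm": v.radius_mm,
                "vclass": v.vclass,
                "pvs_radius_mm": v.pvs_radius_mm,
                "truth_tortuous": v.truth_tortuous,
                "arc_length_mm": v.curve.arc_length,
            }
            for v in spec.vessels
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
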