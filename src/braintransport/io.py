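"""NIfTI and sidecar I/O.

Volumes are written with a diagonal affine of the voxel size (mm); 4D
series carry frame times in a JSON sidecar next to the image.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .relaxometry import ConcentrationSeries, SignalSeries

__all__ = [
    "save_volume",
    "load_volume",
    "save_concentration",
    "load_concentration",
    "save_signal",
    "load_signal",
    "save_json",
    "load_json",
]


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def save_volume(path, data: np.ndarray, voxel_size: float) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel_size = float(img.affine[0, 0])
    return np.asarray(img.get_fdata()), voxel_size


def save_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


def _sidecar(path) -> Path:
    p = Path(path)
    name = p.name
    for suff in (".nii.gz", ".nii"):
        if name.endswith(suff):
            return p.with_name(name[: -len(suff)] + ".json")
    return p.with_suffix(".json")


def save_concentration(path, conc: ConcentrationSeries) -> None:
    save_volume(path, conc.frames, conc.voxel_size)
    save_json(
        _sidecar(path),
        {
            "frame_times_min": conc.frame_times.tolist(),
            "porosity": conc.porosity,
            "units": "mM",
        },
    )


def load_concentration(path) -> ConcentrationSeries:
    data, voxel_size = load_volume(path)
    meta = load_json(_sidecar(path))
    return ConcentrationSeries(
        frames=data,
        frame_times=np.asarray(meta["frame_times_min"]),
        voxel_size=voxel_size,
        porosity=meta.get("porosity", 0.20),
    )


def save_signal(prefix, sig: SignalSeries) -> None:
    """Write frames plus one baseline volume per flip angle.

    ``prefix`` is a path without extension; files are
    ``<prefix>_frames.nii``, ``<prefix>_baseline<angle>.nii`` and a JSON
    sidecar.
    """
    prefix = Path(prefix)
    save_volume(prefix.parent / f"{prefix.name}_frames.nii", sig.frames, sig.voxel_size)
    angles = sorted(sig.baselines)
    for a in angles:
        save_volume(
            prefix.parent / f"{prefix.name}_baseline{a:g}.nii",
            sig.baselines[a],
            sig.voxel_size,
        )
    save_json(
        prefix.parent / f"{prefix.name}.json",
        {"frame_times_min": sig.frame_times.tolist(), "flip_angles": angles},
    )


def load_signal(prefix) -> SignalSeries:
    prefix = Path(prefix)
    meta = load_json(prefix.parent / f"{prefix.name}.json")
    frames, voxel_size = load_volume(prefix.parent / f"{prefix.name}_frames.nii")
    baselines = {}
    for a in meta["flip_angles"]:
        vol, _ = load_volume(prefix.parent / f"{prefix.name}_baseline{a:g}.nii")
        baselines[float(a)] = vol
    return SignalSeries(
        frames=frames,
        frame_times=np.asarray(meta["frame_times_min"]),
        baselines=baselines,
        voxel_size=voxel_size,
    )
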