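"""Readers and writers: NIfTI volumes, the HDF5 k-space container, YAML configs.

Complex volumes are stored as paired magnitude/phase NIfTI-1 files
(``<stem>_mag.nii.gz`` and ``<stem>_phase.nii.gz``), since the phase map
is required for k-space reprocessing; loading a magnitude-only file
where a complex volume is expected raises an explicit error.

HDF5 k-space container layout::

    /samples   complex64, (n_t, n_r)   one readout line per row
    /lines     int32,     (n_t, 2)     centered phase-encode offsets
    attrs: grid_shape (3,), readout_axis (str), spacing (3, mm),
           noise_sigma (float)
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from rigidmoco.geometry import ImageVolume
from rigidmoco.operators import KSpaceData, SamplingPattern

__all__ = ["read_volume", "write_volume", "read_kspace", "write_kspace",
           "load_config", "dump_config"]

_MAG_SUFFIX = "_mag"
_PHASE_SUFFIX = "_phase"


def _stem_and_ext(path: Path) -> tuple[str, str]:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return name[: -len(ext)], ext
    return path.stem, path.suffix or ".nii.gz"


def _pair_paths(path) -> tuple[Path, Path]:
    path = Path(path)
    stem, ext = _stem_and_ext(path)
    if stem.endswith(_MAG_SUFFIX):
        stem = stem[: -len(_MAG_SUFFIX)]
    elif stem.endswith(_PHASE_SUFFIX):
        stem = stem[: -len(_PHASE_SUFFIX)]
    base = path.parent / stem
    return (base.parent / f"{base.name}{_MAG_SUFFIX}{ext}",
            base.parent / f"{base.name}{_PHASE_SUFFIX}{ext}")


def write_volume(v: ImageVolume, path) -> tuple[Path, Path]:
    """Write a complex volume as a magnitude/phase NIfTI pair.

    ``path`` may be a stem (``out``), a plain NIfTI name (``out.nii.gz``)
    or either half of an existing pair.  Voxel spacing is stored in the
    affine and zooms.  Returns the two written paths.
    """
    mag_path, phase_path = _pair_paths(path)
    affine = np.diag(list(v.spacing) + [1.0])
    for arr, p in ((np.abs(v.data), mag_path), (np.angle(v.data), phase_path)):
        img = nib.Nifti1Image(arr.astype(np.float64), affine)
        img.header.set_zooms(tuple(v.spacing))
        nib.save(img, str(p))
    return mag_path, phase_path


def read_volume(path, require_phase: bool = True) -> ImageVolume:
    """Read a magnitude/phase NIfTI pair back into a complex volume.

    With ``require_phase=False`` a missing phase file yields a real
    (zero-phase) volume instead of an error.
    """
    mag_path, phase_path = _pair_paths(path)
    if not mag_path.exists():
        single = Path(path)
        if single.exists():
            mag_path = single
        else:
            raise FileNotFoundError(f"no magnitude NIfTI at {mag_path}")
    mag_img = nib.load(str(mag_path))
    mag = np.asarray(mag_img.dataobj, dtype=np.float64)
    if mag.ndim != 3:
        raise ValueError(f"{mag_path}: expected a 3D volume, got shape {mag.shape}")
    spacing = np.asarray(mag_img.header.get_zooms()[:3], dtype=float)
    if phase_path.exists():
        phase = np.asarray(nib.load(str(phase_path)).dataobj, dtype=np.float64)
        if phase.shape != mag.shape:
            raise ValueError("magnitude and phase volumes differ in shape")
        data = mag * np.exp(1j * phase)
    elif require_phase:
        raise FileNotFoundError(
            f"complex volume requires a phase map: {phase_path} is missing "
            "(pass require_phase=False to load magnitude-only data)")
    else:
        data = mag.astype(np.complex128)
    return ImageVolume(data, spacing)


def write_kspace(d: KSpaceData, path) -> Path:
    """Write a k-space dataset to the HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("samples", data=d.samples.astype(np.complex64))
        fh.create_dataset("lines", data=d.pattern.lines.astype(np.int32))
        fh.attrs["grid_shape"] = np.asarray(d.pattern.grid_shape, dtype=np.int64)
        fh.attrs["readout_axis"] = d.pattern.readout_axis
        fh.attrs["spacing"] = np.asarray(d.spacing, dtype=np.float64)
        fh.attrs["noise_sigma"] = float(d.noise_sigma)
    return path


def read_kspace(path) -> KSpaceData:
    """Read and schema-validate a k-space container."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        for name in ("samples", "lines"):
            if name not in fh:
                raise ValueError(f"{path}: missing dataset /{name}")
        for attr in ("grid_shape", "readout_axis", "spacing"):
            if attr not in fh.attrs:
                raise ValueError(f"{path}: missing attribute {attr}")
        samples = np.asarray(fh["samples"], dtype=np.complex128)
        lines = np.asarray(fh["lines"], dtype=np.int32)
        grid_shape = tuple(int(n) for n in fh.attrs["grid_shape"])
        readout_axis = str(fh.attrs["readout_axis"])
        spacing = np.asarray(fh.attrs["spacing"], dtype=float)
        noise_sigma = float(fh.attrs.get("noise_sigma", 0.0))
    pattern = SamplingPattern(grid_shape=grid_shape, readout_axis=readout_axis,
                              lines=lines)
    return KSpaceData(samples=samples, pattern=pattern, noise_sigma=noise_sigma,
                      spacing=spacing)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path) -> None:
    """Write a fully resolved configuration next to run outputs (provenance)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
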