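"""Readers/writers for the package's on-disk formats.

Magnitude images and masks go to NIfTI with voxel dimensions derived from
FOV/matrix; complex k-space series go to HDF5 alongside their acquisition
config; phantom specs and run manifests are YAML; tables are CSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Union

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import AcquisitionConfig, KSpaceFrame, PhantomSpec
from .recon import MagnitudeImage
from .series import ChallengeSeries


def _affine(voxel_mm, slice_thickness_mm: Optional[float]) -> np.ndarray:
    dz = slice_thickness_mm if slice_thickness_mm else 1.0
    return np.diag([voxel_mm[0], voxel_mm[1], dz, 1.0])


def save_nifti(image: Union[MagnitudeImage, np.ndarray], path, voxel_mm=(1.0, 1.0),
               slice_thickness_mm: Optional[float] = None) -> None:
    if isinstance(image, MagnitudeImage):
        data, voxel_mm, slice_thickness_mm = image.values, image.voxel_mm, image.slice_thickness_mm
    else:
        data = np.asarray(image)
    vol = np.asarray(data, dtype=np.float32 if data.dtype.kind == "f" else np.uint8)[..., None]
    nib.save(nib.Nifti1Image(vol, _affine(voxel_mm, slice_thickness_mm)), str(path))


def load_nifti(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float).squeeze()


def save_phantom_spec(spec: PhantomSpec, path) -> None:
    d = dataclasses.asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    d["fov"] = list(spec.fov)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_phantom_spec(path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    d["grid_shape"] = tuple(d["grid_shape"])
    d["fov"] = tuple(d["fov"])
    return PhantomSpec(**d)


def _config_attrs(config: AcquisitionConfig) -> dict:
    d = dataclasses.asdict(config)
    d["matrix"] = list(config.matrix)
    d["fov_mm"] = list(config.fov_mm)
    if config.flip_schedule is None:
        d.pop("flip_schedule")
    else:
        d["flip_schedule"] = list(config.flip_schedule)
    if config.slice_thickness_mm is None:
        d.pop("slice_thickness_mm")
    return d


def _config_from_attrs(attrs) -> AcquisitionConfig:
    kw = dict(
        matrix=tuple(int(x) for x in attrs["matrix"]),
        fov_mm=tuple(float(x) for x in attrs["fov_mm"]),
        te_ms=float(attrs["te_ms"]),
        tr_ms=float(attrs["tr_ms"]),
        mode=str(attrs["mode"]),
    )
    if "flip_schedule" in attrs:
        kw["flip_schedule"] = tuple(float(x) for x in attrs["flip_schedule"])
    if "slice_thickness_mm" in attrs:
        kw["slice_thickness_mm"] = float(attrs["slice_thickness_mm"])
    return AcquisitionConfig(**kw)


def save_kspace_series(series: ChallengeSeries, path) -> None:
    """Write a k-space challenge series (complex data + config + dose labels)."""
    with h5py.File(path, "w") as f:
        f.attrs["dose_increments_ug"] = series.dose_increments_ug
        for i, (frame, role, cum) in enumerate(
            zip(series.frames, series.roles, series.cumulative_dose_ug)
        ):
            g = f.create_group(f"frame{i:03d}")
            g.create_dataset("data", data=frame.data)
            g.attrs["role"] = role
            g.attrs["label"] = frame.label
            g.attrs["cumulative_dose_ug"] = cum
            for k, v in _config_attrs(frame.config).items():
                g.attrs[f"config/{k}"] = v


def load_kspace_series(path) -> ChallengeSeries:
    frames, roles, cums = [], [], []
    with h5py.File(path, "r") as f:
        incs = [float(x) for x in f.attrs["dose_increments_ug"]]
        for name in sorted(k for k in f if k.startswith("frame")):
            g = f[name]
            cfg = _config_from_attrs(
                {k.split("/", 1)[1]: v for k, v in g.attrs.items() if k.startswith("config/")}
            )
            frames.append(
                KSpaceFrame(
                    data=np.asarray(g["data"]),
                    config=cfg,
                    label=str(g.attrs["label"]),
                    cumulative_dose_ug=float(g.attrs["cumulative_dose_ug"]),
                )
            )
            roles.append(str(g.attrs["role"]))
            cums.append(float(g.attrs["cumulative_dose_ug"]))
    return ChallengeSeries(frames=frames, roles=roles, dose_increments_ug=incs,
                           cumulative_dose_ug=cums)
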