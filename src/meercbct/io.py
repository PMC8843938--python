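"""On-disk formats: HDF5 sinograms, TIFF/NIfTI images, YAML configs, CSV
metric tables."""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile
import yaml

from .geometry import ScanGeometry
from .simulate import MultiChannelSinogram

__all__ = [
    "save_sinogram",
    "load_sinogram",
    "save_image_tiff",
    "save_image_nifti",
    "save_metrics_csv",
    "load_config",
    "save_config",
]


def save_sinogram(
    path, sinogram: MultiChannelSinogram, truth: dict[str, np.ndarray] | None = None
) -> None:
    """Write /B, /angles, /channel_of_view plus geometry attributes.

    Optional ground-truth maps are stored under /truth/<name>.
    """
    g = sinogram.geometry
    with h5py.File(path, "w") as fh:
        fh.create_dataset("B", data=sinogram.B)
        fh.create_dataset("angles", data=g.view_angles[sinogram.view_indices])
        fh.create_dataset("channel_of_view", data=sinogram.channel_of_view)
        fh.attrs["kvps"] = list(sinogram.kvps)
        fh.attrs["n_clamped"] = sinogram.n_clamped
        fh.attrs["source_to_isocenter"] = g.source_to_isocenter
        fh.attrs["source_to_detector"] = g.source_to_detector
        fh.attrs["n_views"] = g.n_views
        fh.attrs["n_detector_bins"] = g.n_detector_bins
        fh.attrs["detector_span"] = g.detector_span
        fh.attrs["image_shape"] = list(g.image_shape)
        fh.attrs["pixel_size"] = g.pixel_size
        if truth:
            grp = fh.create_group("truth")
            for name, arr in truth.items():
                grp.create_dataset(name, data=arr)


def load_sinogram(path) -> MultiChannelSinogram:
    with h5py.File(path, "r") as fh:
        geometry = ScanGeometry(
            source_to_isocenter=float(fh.attrs["source_to_isocenter"]),
            source_to_detector=float(fh.attrs["source_to_detector"]),
            n_views=int(fh.attrs["n_views"]),
            image_shape=tuple(int(v) for v in fh.attrs["image_shape"]),
            pixel_size=float(fh.attrs["pixel_size"]),
            n_detector_bins=int(fh.attrs["n_detector_bins"]),
            detector_span=float(fh.attrs["detector_span"]),
        )
        return MultiChannelSinogram(
            B=fh["B"][()],
            channel_of_view=fh["channel_of_view"][()],
            kvps=tuple(float(k) for k in fh.attrs["kvps"]),
            geometry=geometry,
            n_clamped=int(fh.attrs["n_clamped"]),
        )


def save_image_tiff(path, image: np.ndarray, pixel_size_cm: float) -> None:
    """32-bit float TIFF with resolution metadata (pixels per cm)."""
    res = 1.0 / pixel_size_cm
    tifffile.imwrite(
        path,
        np.asarray(image, dtype=np.float32),
        resolution=(res, res),
        resolutionunit="CENTIMETER",
    )


def save_image_nifti(path, image: np.ndarray, pixel_size_cm: float) -> None:
    mm = 10.0 * pixel_size_cm
    affine = np.diag([mm, mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), affine), str(path))


def save_metrics_csv(path, rows: list[dict]) -> None:
    if not rows:
        raise ValueError("no metric rows to write")
    keys = list(rows[0])
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=keys)
        w.writeheader()
        w.writerows(rows)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, cfg: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
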