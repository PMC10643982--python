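"""File I/O: 16-bit TIFF frames with JSON sidecars, PNG histology, CSV tables.

Frames are stored as 16-bit grayscale TIFF with intensities quantised at
``counts_per_au`` counts per arbitrary unit (default 100); the scale factor
travels in the per-heart JSON sidecar together with the wall geometry, pixel
calibration, protocol and ground truth, so a round trip recovers intensities
to 0.005 a.u.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .echoroi import UltrasoundFrame
from .geometry import WallGeometry

__all__ = [
    "DEFAULT_COUNTS_PER_AU",
    "frame_filename",
    "write_frame_tiff",
    "read_frame_tiff",
    "write_sidecar",
    "read_sidecar",
    "write_histology_png",
    "read_histology_png",
]

DEFAULT_COUNTS_PER_AU = 100.0


def frame_filename(timepoint_min: float) -> str:
    return f"frame_t{timepoint_min:g}.tif"


def write_frame_tiff(frame: UltrasoundFrame, path, counts_per_au: float = DEFAULT_COUNTS_PER_AU) -> None:
    counts = np.clip(np.rint(frame.pixels * counts_per_au), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), counts)


def read_frame_tiff(
    path,
    pixel_size_um: float,
    timepoint_min: float = 0.0,
    heart_id: str = "",
    arm: str = "",
    counts_per_au: float = DEFAULT_COUNTS_PER_AU,
) -> UltrasoundFrame:
    counts = tifffile.imread(str(path)).astype(float)
    return UltrasoundFrame(
        pixels=counts / counts_per_au,
        pixel_size_um=pixel_size_um,
        timepoint_min=timepoint_min,
        heart_id=heart_id,
        arm=arm,
    )


def write_sidecar(path, payload: dict) -> None:
    """Write the per-heart JSON sidecar (geometry, calibration, ground truth)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def geometry_to_json(geometry: WallGeometry) -> dict:
    return geometry.to_dict()


def geometry_from_json(d: dict) -> WallGeometry:
    return WallGeometry.from_dict(d)


def write_histology_png(rgb: np.ndarray, path, mask: np.ndarray | None = None, mask_path=None) -> None:
    iio.imwrite(str(path), np.asarray(rgb, dtype=np.uint8))
    if mask is not None:
        if mask_path is None:
            mask_path = Path(path).with_name(Path(path).stem + "_mask.png")
        iio.imwrite(str(mask_path), np.asarray(mask, dtype=np.uint8))


def read_histology_png(path) -> np.ndarray:
    arr = iio.imread(str(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr
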