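"""Mid-myocardial ROI extraction from short-axis B-mode frames.

Locates the four cardinal wall positions (anterior = up, lateral = right,
posterior = down, septal = left in image coordinates, transducer above the
image), places a square region of interest half-way between the endocardial
and epicardial boundaries on each cardinal ray, and extracts mean backscatter
intensity and wall thickness per timepoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryError, WallGeometry

__all__ = [
    "UltrasoundFrame",
    "CardinalROI",
    "BackscatterSeries",
    "POSITIONS",
    "FIBER_CLASS",
    "mid_myocardial_points",
    "extract_roi_mean",
    "wall_thickness",
    "build_series",
]

log = logging.getLogger(__name__)

#: Cardinal positions in fixed order, with their ray directions (row, col).
#: The beam travels down the image columns, so anterior is the top wall.
POSITIONS: dict[str, tuple[int, int]] = {
    "anterior": (-1, 0),
    "lateral": (0, 1),
    "posterior": (1, 0),
    "septal": (0, -1),
}

#: Fiber alignment relative to the angle of insonification, by wall.
FIBER_CLASS: dict[str, str] = {
    "anterior": "perpendicular",
    "posterior": "perpendicular",
    "lateral": "parallel",
    "septal": "parallel",
}


@dataclass
class UltrasoundFrame:
    """One 2-D backscatter intensity image (gain-linear arbitrary units)."""

    pixels: np.ndarray
    pixel_size_um: float
    timepoint_min: float = 0.0
    heart_id: str = ""
    arm: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("backscatter intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CardinalROI:
    """Axis-aligned square ROI at one cardinal wall position."""

    position: str
    center: tuple[float, float]
    side_um: float = 250.0

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        if self.side_um <= 0:
            raise ValueError("side_um must be positive")

    @property
    def fiber_class(self) -> str:
        return FIBER_CLASS[self.position]


def mid_myocardial_points(geometry: WallGeometry) -> dict[str, tuple[float, float]]:
    """Mid-wall point on each cardinal ray from the epicardial centroid.

    For each of the four cardinal rays, the point returned is the midpoint of
    the segment between the endocardial and epicardial boundary crossings on
    that ray. Raises :class:`GeometryError` if a ray misses either boundary.
    """
    origin = geometry.epi.center
    out: dict[str, tuple[float, float]] = {}
    for pos, d in POSITIONS.items():
        t_endo = geometry.endo.ray_crossing(origin, d)
        t_epi = geometry.epi.ray_crossing(origin, d)
        if t_endo >= t_epi:
            raise GeometryError(f"endocardium outside epicardium on {pos} ray")
        t_mid = 0.5 * (t_endo + t_epi)
        out[pos] = (origin[0] + t_mid * d[0], origin[1] + t_mid * d[1])
    return out


def roi_window(roi: CardinalROI, pixel_size_um: float) -> tuple[slice, slice]:
    """Pixel slices of the ROI square.

    The edge length in pixels is ``round(side_um / pixel_size_um)`` (minimum
    1). The window anchor is the pixel floor of the continuous center; a
    window of side ``s`` spans ``[c - (s-1)//2, c + s//2]`` inclusive on each
    axis, so even-sided windows extend one extra pixel down/right of center.
    """
    side_px = max(1, round(roi.side_um / pixel_size_um))
    cr = math.floor(roi.center[0])
    cc = math.floor(roi.center[1])
    r0 = cr - (side_px - 1) // 2
    c0 = cc - (side_px - 1) // 2
    return slice(r0, r0 + side_px), slice(c0, c0 + side_px)


def extract_roi_mean(frame: UltrasoundFrame, roi: CardinalROI) -> float:
    """Arithmetic mean backscatter inside the ROI square.

    Raises ``IndexError`` when the window is clipped by the image border;
    clipped ROIs are never silently truncated.
    """
    rs, cs = roi_window(roi, frame.pixel_size_um)
    nr, nc = frame.shape
    if rs.start < 0 or cs.start < 0 or rs.stop > nr or cs.stop > nc:
        raise IndexError(
            f"ROI at {roi.center} (rows {rs.start}:{rs.stop}, cols {cs.start}:{cs.stop}) "
            f"falls outside the {nr}x{nc} frame"
        )
    return float(frame.pixels[rs, cs].mean())


def wall_thickness(geometry: WallGeometry, position: str, pixel_size_um: float) -> float:
    """Myocardial wall thickness (µm) on one cardinal ray.

    Distance between the endocardial and epicardial boundary crossings on the
    ray from the epicardial centroid, converted with the pixel calibration.
    """
    d = POSITIONS[position]
    origin = geometry.epi.center
    t_endo = geometry.endo.ray_crossing(origin, d)
    t_epi = geometry.epi.ray_crossing(origin, d)
    if t_endo >= t_epi:
        raise GeometryError(f"endocardium outside epicardium on {position} ray")
    return (t_epi - t_endo) * pixel_size_um


@dataclass
class BackscatterSeries:
    """Per-position, per-timepoint ROI means and wall thicknesses for one heart.

    ``table`` is tidy with columns heart_id, arm, position, fiber_class,
    timepoint_min, mean_intensity, wall_thickness_um. Failed extractions are
    recorded as NaN with the reason kept in ``failures``.
    """

    heart_id: str
    arm: str
    table: pd.DataFrame
    failures: list[str] = field(default_factory=list)

    @property
    def timepoints_min(self) -> list[float]:
        return sorted(self.table["timepoint_min"].unique().tolist())

    def position_mean(self, position: str, timepoint_min: float) -> float:
        sel = self.table[
            (self.table["position"] == position)
            & (self.table["timepoint_min"] == timepoint_min)
        ]
        if sel.empty:
            raise KeyError(f"no record for {position} at t={timepoint_min}")
        return float(sel["mean_intensity"].iloc[0])

    def mean_wall_thickness_um(self, position: str | None = None) -> float:
        """Wall thickness averaged over timepoints (one position or all)."""
        t = self.table
        if position is not None:
            t = t[t["position"] == position]
        return float(t["wall_thickness_um"].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def build_series(
    frames: Sequence[UltrasoundFrame],
    geometries: WallGeometry | Sequence[WallGeometry] | Mapping[float, WallGeometry],
    side_um: float = 250.0,
) -> BackscatterSeries:
    """Assemble the position x timepoint backscatter table for one heart.

    ``geometries`` may be a single :class:`WallGeometry` reused for every
    frame, a sequence parallel to ``frames``, or a mapping from timepoint to
    geometry. Duplicate timepoints are an input error. ROIs that fall outside
    a frame are recorded as NaN with a logged reason, never as zero.
    """
    if not frames:
        raise ValueError("no frames supplied")
    times = [f.timepoint_min for f in frames]
    if len(set(times)) != len(times):
        raise ValueError("duplicate timepoints in frame list")

    def geom_for(i: int, frame: UltrasoundFrame) -> WallGeometry:
        if isinstance(geometries, WallGeometry):
            return geometries
        if isinstance(geometries, Mapping):
            return geometries[frame.timepoint_min]
        return geometries[i]

    rows = []
    failures: list[str] = []
    heart_id = frames[0].heart_id
    arm = frames[0].arm
    paired = sorted(
        ((f, geom_for(i, f)) for i, f in enumerate(frames)),
        key=lambda fg: fg[0].timepoint_min,
    )
    for frame, geom in paired:
        points = mid_myocardial_points(geom)
        for pos, center in points.items():
            roi = CardinalROI(position=pos, center=center, side_um=side_um)
            try:
                mean = extract_roi_mean(frame, roi)
            except IndexError as exc:
                reason = f"{pos} at t={frame.timepoint_min}: {exc}"
                failures.append(reason)
                log.warning("ROI skipped: %s", reason)
                mean = float("nan")
            rows.append(
                {
                    "heart_id": heart_id,
                    "arm": arm,
                    "position": pos,
                    "fiber_class": FIBER_CLASS[pos],
                    "timepoint_min": frame.timepoint_min,
                    "mean_intensity": mean,
                    "wall_thickness_um": wall_thickness(geom, pos, frame.pixel_size_um),
                }
            )
    return BackscatterSeries(heart_id=heart_id, arm=arm, table=pd.DataFrame(rows), failures=failures)
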