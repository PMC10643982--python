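"""Circular statistics for myocyte / collagen-fiber orientations.

Fiber orientations are axial data: an angle and its 180-degree opposite
describe the same fiber. Axial samples are handled by the standard
angle-doubling device — statistics are computed on 2*theta, the mean angle is
halved back into [0, 180), and the angular deviation is halved when mapped
back to orientation space (both the doubled-space and halved values are
exposed so either convention can be matched).

The angular deviation s = sqrt(2 * (1 - r)), with r the mean resultant
length, is the circular analogue of the standard deviation; it ranges from 0
(all angles identical) to sqrt(2) rad = 81.03 degrees (r = 0), or half that
under the halved axial convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrientationSample",
    "CircularSummary",
    "resultant",
    "angular_deviation",
    "summarize",
    "group_distribution",
    "group_angular_deviation",
]


@dataclass
class OrientationSample:
    """A set of orientation angles with optional grid positions.

    Axial samples hold angles in [0, 180); circular samples in [0, 360).
    """

    angles_deg: np.ndarray
    axial: bool = True
    grid: np.ndarray | None = None  # (n, 2) array of (row, col) grid positions
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if self.angles_deg.size == 0:
            raise ValueError("orientation sample must contain at least one angle")
        support = 180.0 if self.axial else 360.0
        if np.any(self.angles_deg < 0) or np.any(self.angles_deg >= support):
            raise ValueError(f"angles must lie in [0, {support:g}) for this sample")
        if self.grid is not None:
            self.grid = np.asarray(self.grid)
            if self.grid.shape != (self.angles_deg.size, 2):
                raise ValueError("grid must be (n, 2) matching the angle count")

    @property
    def n(self) -> int:
        return int(self.angles_deg.size)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"angle_deg": self.angles_deg})
        if self.grid is not None:
            df["row"] = self.grid[:, 0]
            df["col"] = self.grid[:, 1]
        return df


@dataclass(frozen=True)
class CircularSummary:
    """Mean resultant length, mean angle and angular deviation of one sample."""

    r: float
    mean_angle_deg: float
    angular_deviation_deg: float
    angular_deviation_doubled_deg: float
    n: int
    axial: bool


def _analysis_angles_rad(angles_deg: np.ndarray, axial: bool) -> np.ndarray:
    """Angles in the analysis space (doubled for axial data), radians."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return 2.0 * a if axial else a


def resultant(angles_deg, axial: bool = True) -> tuple[float, float]:
    """Mean resultant length and mean angle (degrees) of a sample.

    For axial data the angles are doubled before vector averaging and the
    mean direction is halved back into [0, 180). r is the length of the mean
    unit vector, in [0, 1].
    """
    angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles_deg.size == 0:
        raise ValueError("empty sample")
    phi = _analysis_angles_rad(angles_deg, axial)
    c = np.cos(phi).mean()
    s = np.sin(phi).mean()
    r = float(min(1.0, math.hypot(c, s)))
    mean = math.degrees(math.atan2(s, c))
    if axial:
        mean = (mean / 2.0) % 180.0
    else:
        mean = mean % 360.0
    return r, float(mean)


def angular_deviation(angles_deg, axial: bool = True) -> float:
    """Batschelet angular deviation, degrees.

    s = sqrt(2 * (1 - r)) radians computed in the analysis space; for axial
    data the value is halved to map back to orientation space (use
    ``resultant`` + the doubled-space formula directly for the unhalved
    convention, or :func:`summarize` which reports both).
    """
    r, _ = resultant(angles_deg, axial)
    s = math.degrees(math.sqrt(2.0 * (1.0 - r)))
    return s / 2.0 if axial else s


def summarize(sample: OrientationSample) -> CircularSummary:
    """Full circular summary of one orientation sample."""
    r, mean = resultant(sample.angles_deg, sample.axial)
    s_doubled = math.degrees(math.sqrt(2.0 * (1.0 - r)))
    s = s_doubled / 2.0 if sample.axial else s_doubled
    return CircularSummary(
        r=r,
        mean_angle_deg=mean,
        angular_deviation_deg=s,
        angular_deviation_doubled_deg=s_doubled,
        n=sample.n,
        axial=sample.axial,
    )


def group_distribution(
    samples: Sequence[OrientationSample],
    bin_deg: float = 5.0,
    align: bool = True,
) -> pd.DataFrame:
    """Pooled orientation histogram for a group of samples.

    With ``align=True`` (default) each sample is rotated so its mean angle is
    0 degrees before pooling, and the histogram is centred on 0 (bins span
    [-support/2, support/2)); disarray then shows as spread about 0
    independent of each heart's absolute fiber direction. With
    ``align=False`` the raw angles are pooled over [0, support).

    Returns a DataFrame with columns bin_left_deg, bin_right_deg, count.
    """
    if not samples:
        raise ValueError("no samples to pool")
    axial = samples[0].axial
    if any(s.axial != axial for s in samples):
        raise ValueError("samples mix axial and circular conventions")
    support = 180.0 if axial else 360.0
    pooled = []
    for s in samples:
        a = s.angles_deg.copy()
        if align:
            _, mean = resultant(a, axial)
            a = (a - mean) % support
            # centre on zero for a symmetric, unimodal display
            a = np.where(a >= support / 2.0, a - support, a)
        pooled.append(a)
    angles = np.concatenate(pooled)
    lo = -support / 2.0 if align else 0.0
    edges = np.arange(lo, lo + support + bin_deg / 2.0, bin_deg)
    counts, edges = np.histogram(angles, bins=edges)
    return pd.DataFrame(
        {"bin_left_deg": edges[:-1], "bin_right_deg": edges[1:], "count": counts}
    )


def group_angular_deviation(samples: Sequence[OrientationSample]) -> tuple[pd.DataFrame, float]:
    """Per-sample angular deviations and their unweighted group mean.

    Returns a tidy table (sample_id, group, n, r, mean_angle_deg,
    angular_deviation_deg, angular_deviation_doubled_deg) plus the group mean
    of the per-sample deviations.
    """
    if not samples:
        raise ValueError("no samples")
    rows = []
    for s in samples:
        summ = summarize(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "n": summ.n,
                "r": summ.r,
                "mean_angle_deg": summ.mean_angle_deg,
                "angular_deviation_deg": summ.angular_deviation_deg,
                "angular_deviation_doubled_deg": summ.angular_deviation_doubled_deg,
            }
        )
    table = pd.DataFrame(rows)
    return table, float(table["angular_deviation_deg"].mean())
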