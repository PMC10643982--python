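"""Ellipse geometry for the left-ventricular short-axis annulus.

The myocardium in a short-axis B-mode view appears as an annulus bounded by
an endocardial and an epicardial ellipse (manually annotated in practice,
supplied programmatically here). All coordinates are 0-based ``(row, col)``
pixels; angles are in degrees.

Conventions
-----------
* An :class:`Ellipse` has semi-axis ``a`` along its own first axis and ``b``
  along the perpendicular axis. At ``rotation_deg = 0`` the first axis points
  along +col (image x) and the second along +row (image y). ``rotation_deg``
  rotates both axes from +col toward +row (clockwise on screen).
* Cardinal rays are cast from the centroid of the epicardial ellipse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Ellipse", "WallGeometry", "GeometryError"]


class GeometryError(ValueError):
    """Raised when an annulus geometry is invalid or a ray misses a wall."""


@dataclass(frozen=True)
class Ellipse:
    center_row: float
    center_col: float
    semi_axis_a_px: float
    semi_axis_b_px: float
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.semi_axis_a_px <= 0 or self.semi_axis_b_px <= 0:
            raise GeometryError("ellipse semi-axes must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_row, self.center_col)

    def _axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors (row, col) of the a- and b-axes."""
        th = math.radians(self.rotation_deg)
        u = np.array([math.sin(th), math.cos(th)])   # a-axis
        v = np.array([math.cos(th), -math.sin(th)])  # b-axis
        return u, v

    def implicit(self, rows, cols):
        """Implicit value (x/a)^2 + (y/b)^2 - 1 at the given points.

        Negative inside, zero on the boundary, positive outside.
        """
        dr = np.asarray(rows, dtype=float) - self.center_row
        dc = np.asarray(cols, dtype=float) - self.center_col
        u, v = self._axes()
        x = dr * u[0] + dc * u[1]
        y = dr * v[0] + dc * v[1]
        return (x / self.semi_axis_a_px) ** 2 + (y / self.semi_axis_b_px) ** 2 - 1.0

    def contains(self, rows, cols):
        return self.implicit(rows, cols) <= 0.0

    def ray_crossing(self, origin: tuple[float, float], direction: tuple[float, float]) -> float:
        """Distance t > 0 (px) from ``origin`` to the boundary along ``direction``.

        ``direction`` is a (row, col) vector; it is normalised internally so the
        returned t is in pixels. Returns the nearest positive crossing. Raises
        :class:`GeometryError` when the ray never meets the boundary.
        """
        d = np.asarray(direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("ray direction must be non-zero")
        d = d / n
        o = np.asarray(origin, dtype=float) - np.array(self.center)
        u, v = self._axes()
        # local coordinates scaled by the semi-axes -> unit circle
        ox = (o[0] * u[0] + o[1] * u[1]) / self.semi_axis_a_px
        oy = (o[0] * v[0] + o[1] * v[1]) / self.semi_axis_b_px
        dx = (d[0] * u[0] + d[1] * u[1]) / self.semi_axis_a_px
        dy = (d[0] * v[0] + d[1] * v[1]) / self.semi_axis_b_px
        A = dx * dx + dy * dy
        B = 2.0 * (ox * dx + oy * dy)
        C = ox * ox + oy * oy - 1.0
        disc = B * B - 4.0 * A * C
        if disc < 0:
            raise GeometryError("ray does not intersect ellipse")
        sq = math.sqrt(disc)
        roots = sorted(((-B - sq) / (2 * A), (-B + sq) / (2 * A)))
        for t in roots:
            if t > 1e-12:
                return float(t)
        raise GeometryError("ray does not intersect ellipse in the forward direction")

    def boundary_points(self, n: int = 360) -> np.ndarray:
        """``n`` boundary points, shape (n, 2) as (row, col)."""
        psi = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        u, v = self._axes()
        pts = (
            np.array(self.center)[None, :]
            + self.semi_axis_a_px * np.cos(psi)[:, None] * u[None, :]
            + self.semi_axis_b_px * np.sin(psi)[:, None] * v[None, :]
        )
        return pts


@dataclass(frozen=True)
class WallGeometry:
    """Endocardial + epicardial ellipse pair bounding the myocardial annulus."""

    endo: Ellipse
    epi: Ellipse

    def validate(self, n_rays: int = 360) -> None:
        """Check the epicardium contains the endocardium along every ray
        from the epicardial centroid."""
        o = self.epi.center
        for k in range(n_rays):
            th = 2.0 * math.pi * k / n_rays
            d = (math.cos(th), math.sin(th))
            try:
                t_endo = self.endo.ray_crossing(o, d)
                t_epi = self.epi.ray_crossing(o, d)
            except GeometryError as exc:
                raise GeometryError(f"annulus invalid along ray {k}: {exc}") from exc
            if t_endo >= t_epi:
                raise GeometryError("endocardium reaches or crosses the epicardium")

    def to_dict(self) -> dict:
        def e(el: Ellipse) -> dict:
            return {
                "center_row": el.center_row,
                "center_col": el.center_col,
                "semi_axis_a_px": el.semi_axis_a_px,
                "semi_axis_b_px": el.semi_axis_b_px,
                "rotation_deg": el.rotation_deg,
            }

        return {"endo": e(self.endo), "epi": e(self.epi)}

    @classmethod
    def from_dict(cls, d: dict) -> "WallGeometry":
        return cls(endo=Ellipse(**d["endo"]), epi=Ellipse(**d["epi"]))
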