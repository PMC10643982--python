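"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: ellipse crossings are
found by scalar root-bracketing on the implicit equation, hue classification
is done per pixel with colorsys, and circular statistics by an explicit
two-pass loop.
"""

from __future__ import annotations

import colorsys
import math

import numpy as np
from scipy.optimize import brentq

from myoaniso.geometry import Ellipse, WallGeometry


def oracle_ray_crossing(ellipse: Ellipse, origin, direction, t_max: float = 1000.0) -> float:
    """Nearest positive boundary crossing by dense bracketing + brentq."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)

    def f(t):
        p = np.asarray(origin) + t * d
        return float(ellipse.implicit(p[0], p[1]))

    ts = np.linspace(1e-9, t_max, 4001)
    vals = ellipse.implicit(origin[0] + ts * d[0], origin[1] + ts * d[1])
    sign_change = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    if len(sign_change) == 0:
        raise ValueError("oracle: no crossing")
    i = sign_change[0]
    return brentq(f, ts[i], ts[i + 1], xtol=1e-10)


def oracle_parametric_crossing(ellipse: Ellipse, origin, direction, n: int = 100_000) -> float:
    """Boundary crossing from dense parametric sampling of the ellipse."""
    pts = ellipse.boundary_points(n)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    rel = pts - np.asarray(origin, dtype=float)
    t = rel @ d
    perp = np.abs(rel @ np.array([-d[1], d[0]]))
    fwd = t > 0
    perp = np.where(fwd, perp, np.inf)
    return float(t[np.argmin(perp)])


def oracle_midpoint_and_thickness(geometry: WallGeometry, direction):
    origin = geometry.epi.center
    t_endo = oracle_ray_crossing(geometry.endo, origin, direction)
    t_epi = oracle_ray_crossing(geometry.epi, origin, direction)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    mid = np.asarray(origin) + 0.5 * (t_endo + t_epi) * d
    return mid, t_epi - t_endo


def oracle_hue_bin(r: int, g: int, b: int) -> int:
    """8-bit hue via colorsys; achromatic pixels map to bin 0."""
    if r == g == b:
        return 0
    h, _, _ = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return round(h * 360.0 * 255.0 / 360.0) % 256


def oracle_classify_image(rgb: np.ndarray, brightness_floor: int):
    """Per-pixel brute-force collagen classification (no histogram).

    Applies the blue- and black-component subtractions with plain Python
    arithmetic, then counts collagen and fiber-color pixels directly.
    Returns (content_pct, proportions dict, n_collagen).
    """
    nr, nc, _ = rgb.shape
    n_total = nr * nc
    counts = {"red_orange": 0, "yellow": 0, "green": 0}
    n_collagen = 0
    for i in range(nr):
        for j in range(nc):
            r0, g0, b0 = (int(v) for v in rgb[i, j])
            r1, g1, b1 = max(r0 - b0, 0), max(g0 - b0, 0), 0
            k = 255 - max(r0, g0, b0)
            r2, g2, b2 = max(r1 - k, 0), max(g1 - k, 0), max(b1 - k, 0)
            if max(r2, g2, b2) <= brightness_floor:
                continue
            hb = oracle_hue_bin(r2, g2, b2)
            if 2 <= hb <= 128:
                n_collagen += 1
                if hb <= 38:
                    counts["red_orange"] += 1
                elif hb <= 51:
                    counts["yellow"] += 1
                else:
                    counts["green"] += 1
    content = 100.0 * n_collagen / n_total
    props = {
        k: (100.0 * v / n_collagen if n_collagen else 0.0) for k, v in counts.items()
    }
    return content, props, n_collagen


def oracle_circular(angles_deg, axial: bool):
    """Two-pass vector-sum circular summary: (r, mean_deg, s_deg_analysis_space)."""
    mult = 2.0 if axial else 1.0
    cs = 0.0
    sn = 0.0
    for a in np.atleast_1d(angles_deg):
        cs += math.cos(math.radians(mult * a))
        sn += math.sin(math.radians(mult * a))
    n = len(np.atleast_1d(angles_deg))
    r = math.hypot(cs / n, sn / n)
    mean = math.degrees(math.atan2(sn, cs)) / mult
    support = 180.0 if axial else 360.0
    return r, mean % support, math.degrees(math.sqrt(2.0 * (1.0 - min(r, 1.0))))


def random_valid_geometry(rng: np.random.Generator) -> WallGeometry:
    """A random annulus with the endo ellipse safely inside the epi ellipse."""
    cr, cc = rng.uniform(150, 250, size=2)
    epi_a = rng.uniform(80, 140)
    epi_b = rng.uniform(80, 140)
    rot_epi = rng.uniform(0, 180)
    # endo well inside: scaled-down axes, small centre offset, own rotation
    scale = rng.uniform(0.35, 0.6)
    off = rng.uniform(-8, 8, size=2)
    endo = Ellipse(cr + off[0], cc + off[1], epi_a * scale, epi_b * scale, rng.uniform(0, 180))
    epi = Ellipse(cr, cc, epi_a, epi_b, rot_epi)
    return WallGeometry(endo=endo, epi=epi)
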