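"""Picrosirius-red polarized-light collagen quantification.

Under circularly polarized light, picrosirius-red-stained collagen is
birefringent and its hue tracks fiber thickness (red -> orange -> yellow ->
green as fibers thin), while muscle appears as a dim whitish interference
color and the background is dark. The classification pipeline is:

1. subtract the blue RGB component from all channels (suppresses the whitish
   muscle signal),
2. subtract the black (K) component of the ORIGINAL image (suppresses dark
   background),
3. histogram the surviving pixels over 256 hue bins,
4. classify hue bins: red/orange 2-38, yellow 39-51, green 52-128 (inclusive);
   collagen content = pixels in 2-128 as a percentage of all image pixels,
   and each fiber color as a percentage of the collagen pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HueClassification",
    "HUE_RANGES",
    "COLLAGEN_RANGE",
    "subtract_blue_component",
    "subtract_black_component",
    "hue_histogram",
    "hue_bins",
    "classify_collagen",
    "analyze_slide",
]

#: Inclusive hue-bin ranges for the three fiber colors (8-bit hue, 0-255).
HUE_RANGES: dict[str, tuple[int, int]] = {
    "red_orange": (2, 38),
    "yellow": (39, 51),
    "green": (52, 128),
}

#: Inclusive hue-bin range counted as collagen.
COLLAGEN_RANGE: tuple[int, int] = (2, 128)

#: Default brightness floor (of 255): after the two subtractions muscle and
#: background are near-black; pixels at or below the floor are excluded from
#: hue classification so sensor noise cannot acquire a spurious hue.
DEFAULT_BRIGHTNESS_FLOOR: int = 10


@dataclass
class HueClassification:
    """256-bin hue histogram with collagen content and fiber-color proportions."""

    histogram: np.ndarray
    n_total: int
    n_collagen: int
    collagen_content_pct: float
    proportions: dict[str, float]
    excluded_dark: int
    no_collagen: bool = field(default=False)

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_collagen": self.n_collagen,
            "collagen_content_pct": self.collagen_content_pct,
            "excluded_dark": self.excluded_dark,
            "no_collagen": self.no_collagen,
        }
        for k, v in self.proportions.items():
            d[f"proportion_{k}_pct"] = v
        return d


def _as_rgb(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (rows, cols, 3)")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def subtract_blue_component(image) -> np.ndarray:
    """Subtract the blue channel from every channel, clamping at 0.

    Removes achromatic (whitish) muscle interference colors entirely:
    a gray pixel (v, v, v) maps to black.
    """
    arr = _as_rgb(image).astype(np.int16)
    out = arr - arr[..., 2:3]
    return np.clip(out, 0, 255).astype(np.uint8)


def subtract_black_component(image, original) -> np.ndarray:
    """Subtract the CMYK black component of ``original`` from ``image``.

    K = 255 - max(R, G, B) is computed per pixel on the ORIGINAL image and
    subtracted from each channel of ``image`` (normally the blue-subtracted
    image), clamping at 0.
    """
    arr = _as_rgb(image).astype(np.int16)
    orig = _as_rgb(original)
    if arr.shape != orig.shape:
        raise ValueError("image and original shapes differ")
    k = 255 - orig.max(axis=2).astype(np.int16)
    out = arr - k[..., None]
    return np.clip(out, 0, 255).astype(np.uint8)


def hue_bins(image) -> np.ndarray:
    """Per-pixel 8-bit hue index: round(H_deg * 255 / 360), achromatic -> 0.

    Uses the standard hexagonal-hexcone hue. Returned array has the image's
    2-D shape with integer bins in [0, 255].
    """
    arr = _as_rgb(image).astype(float)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = arr.max(axis=2)
    mn = arr.min(axis=2)
    delta = mx - mn
    h = np.zeros_like(mx)
    chroma = delta > 0
    rmax = chroma & (mx == r)
    gmax = chroma & ~rmax & (mx == g)
    bmax = chroma & ~rmax & ~gmax
    with np.errstate(invalid="ignore", divide="ignore"):
        h[rmax] = np.mod((g[rmax] - b[rmax]) / delta[rmax], 6.0)
        h[gmax] = (b[gmax] - r[gmax]) / delta[gmax] + 2.0
        h[bmax] = (r[bmax] - g[bmax]) / delta[bmax] + 4.0
    h_deg = h * 60.0
    bins = np.rint(h_deg * 255.0 / 360.0).astype(int)
    bins[~chroma] = 0
    return np.mod(bins, 256)


def hue_histogram(image, brightness_floor: int = DEFAULT_BRIGHTNESS_FLOOR) -> tuple[np.ndarray, int]:
    """256-bin hue histogram of an RGB image.

    Pixels whose maximum channel is at or below ``brightness_floor``, and
    achromatic pixels, are counted in bin 0; the bins sum to the pixel count.
    Returns ``(histogram, excluded_dark)`` where ``excluded_dark`` is the
    number of pixels suppressed by the brightness floor.
    """
    if not 0 <= brightness_floor <= 255:
        raise ValueError("brightness_floor must lie in [0, 255]")
    arr = _as_rgb(image)
    bins = hue_bins(arr)
    dark = arr.max(axis=2) <= brightness_floor
    bins = np.where(dark, 0, bins)
    hist = np.bincount(bins.ravel(), minlength=256).astype(int)
    return hist, int(dark.sum())


def classify_collagen(histogram, n_total: int, excluded_dark: int = 0) -> HueClassification:
    """Collagen content and fiber-color proportions from a hue histogram.

    Content is the percentage of ALL image pixels with hue in 2-128
    (inclusive); each fiber-color proportion is a percentage of the collagen
    pixels. When no collagen pixel exists the proportions are reported as 0
    with ``no_collagen`` set.
    """
    hist = np.asarray(histogram, dtype=int)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if hist.sum() != n_total:
        raise ValueError(f"histogram sums to {hist.sum()}, expected n_total={n_total}")
    lo, hi = COLLAGEN_RANGE
    n_collagen = int(hist[lo : hi + 1].sum())
    content = 100.0 * n_collagen / n_total if n_total else 0.0
    no_collagen = n_collagen == 0
    props = {}
    for name, (a, b) in HUE_RANGES.items():
        cnt = int(hist[a : b + 1].sum())
        props[name] = 0.0 if no_collagen else 100.0 * cnt / n_collagen
    return HueClassification(
        histogram=hist,
        n_total=int(n_total),
        n_collagen=n_collagen,
        collagen_content_pct=content,
        proportions=props,
        excluded_dark=int(excluded_dark),
        no_collagen=no_collagen,
    )


def analyze_slide(image, brightness_floor: int = DEFAULT_BRIGHTNESS_FLOOR) -> HueClassification:
    """Full slide pipeline: blue subtraction, black subtraction, hue classification."""
    arr = _as_rgb(image)
    step1 = subtract_blue_component(arr)
    step2 = subtract_black_component(step1, original=arr)
    hist, excluded = hue_histogram(step2, brightness_floor=brightness_floor)
    return classify_collagen(hist, n_total=arr.shape[0] * arr.shape[1], excluded_dark=excluded)
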