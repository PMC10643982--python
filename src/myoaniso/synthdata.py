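"""Synthetic data emulating the collagenase-perfusion backscatter experiment.

Generates, with known ground truth:

* short-axis B-mode phantom frames — an elliptical-annulus left ventricle
  whose expected intensity depends on angular position (maximal at the
  anterior/posterior walls, where collagen lies perpendicular to the beam,
  minimal at the lateral/septal walls where it lies parallel), with optional
  fully developed speckle;
* serial treatment time-series — frames every 2.5 min for 30 min, with the
  perpendicular/parallel intensity gap decaying exponentially during
  collagenase perfusion and frozen when perfusion stops;
* picrosirius-red histology images with exactly known hue composition;
* von Mises fiber-orientation samples on a measurement grid.

Intensity model
---------------
With the beam travelling down the image columns, the expected intensity at
annulus angle phi (measured from the anterior/top direction) is

    I(phi) = I_par' + (I_perp - I_par') * cos^2(phi),
    I_par' = I_perp - aniso_scale * (I_perp - I_par),

so ``aniso_scale = 1`` gives the full perpendicular/parallel dichotomy and
``aniso_scale = 0`` an isotropic annulus at the perpendicular level. Speckle
is multiplicative unit-mean noise per pixel (exponential for fully developed
intensity speckle, Rayleigh optionally), optionally Gaussian-smoothed to
mimic a beam point-spread function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .circstats import OrientationSample
from .echoroi import UltrasoundFrame
from .geometry import Ellipse, GeometryError, WallGeometry

__all__ = [
    "PhantomParams",
    "TreatmentProtocol",
    "HistologyComposition",
    "OrientationModel",
    "default_geometry",
    "generate_phantom_frame",
    "expected_intensity_field",
    "aniso_scale_at",
    "generate_treatment_series",
    "rgb_for_hue_bin",
    "generate_histology_image",
    "sample_orientations",
    "HISTOLOGY_CLASS_CODES",
]

SPECKLE_MODELS = ("none", "exponential", "rayleigh")
ARMS = ("control", "collagenase10", "collagenase30")


@dataclass(frozen=True)
class PhantomParams:
    """Phantom intensity model and acquisition parameters.

    Intensities are gain-linear arbitrary units (a.u.). Defaults describe a
    BDM-arrested rat left ventricle at 25 um/px: epicardial radius 160 px
    (4 mm), endocardial 80 px (2-mm wall).
    """

    intensity_perp: float = 40.0
    intensity_par: float = 10.0
    background: float = 2.0
    speckle_model: str = "exponential"
    smoothing_radius_px: int = 0
    pixel_size_um: float = 25.0
    image_size_px: tuple[int, int] = (384, 384)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.intensity_perp >= self.intensity_par >= 0):
            raise ValueError("require intensity_perp >= intensity_par >= 0")
        if self.background < 0:
            raise ValueError("background intensity must be non-negative")
        if self.speckle_model not in SPECKLE_MODELS:
            raise ValueError(f"speckle_model must be one of {SPECKLE_MODELS}")
        if self.smoothing_radius_px < 0:
            raise ValueError("smoothing_radius_px must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if min(self.image_size_px) <= 0:
            raise ValueError("image_size_px must be positive")


@dataclass(frozen=True)
class TreatmentProtocol:
    """One arm of the perfusion experiment.

    Timepoint 0 is the switch from plain perfusate to collagenase solution;
    frames are acquired every ``interval_min`` for ``duration_min``. During
    collagenase perfusion the anisotropy scale decays as exp(-k t) and is
    frozen when perfusion stops (after 10 min in the 10-min arm); control
    hearts keep aniso_scale = 1 throughout.
    """

    arm: str = "control"
    duration_min: float = 30.0
    interval_min: float = 2.5
    decay_rate_per_min: float = 0.1
    collagenase_stop_min: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if self.interval_min <= 0:
            raise ValueError("interval_min must be positive")
        if self.decay_rate_per_min < 0:
            raise ValueError("decay_rate_per_min must be >= 0")
        if self.collagenase_stop_min is None:
            stop = 10.0 if self.arm == "collagenase10" else self.duration_min
            object.__setattr__(self, "collagenase_stop_min", stop)
        if self.collagenase_stop_min > self.duration_min:
            raise ValueError("collagenase_stop_min cannot exceed duration_min")

    @property
    def timepoints_min(self) -> np.ndarray:
        n = int(math.floor(self.duration_min / self.interval_min)) + 1
        return np.arange(n) * self.interval_min


def aniso_scale_at(protocol: TreatmentProtocol, t_min: float) -> float:
    """Anisotropy scale in [0, 1] at time t under the protocol."""
    if protocol.arm == "control":
        return 1.0
    t_eff = min(t_min, protocol.collagenase_stop_min)
    return float(math.exp(-protocol.decay_rate_per_min * t_eff))


def default_geometry(params: PhantomParams) -> WallGeometry:
    """Concentric circular annulus centred in the image.

    Epicardial radius = 5/12 of the smaller image dimension, endocardial
    radius = half of that (a 2-mm wall at the default calibration).
    """
    nr, nc = params.image_size_px
    cr, cc = (nr - 1) / 2.0, (nc - 1) / 2.0
    r_epi = min(nr, nc) * 5.0 / 12.0
    r_endo = r_epi / 2.0
    return WallGeometry(
        endo=Ellipse(cr, cc, r_endo, r_endo, 0.0),
        epi=Ellipse(cr, cc, r_epi, r_epi, 0.0),
    )


def expected_intensity_field(
    geometry: WallGeometry, params: PhantomParams, aniso_scale: float
) -> np.ndarray:
    """Noise-free expected intensity at every pixel centre."""
    if not 0.0 <= aniso_scale <= 1.0:
        raise ValueError("aniso_scale must lie in [0, 1]")
    nr, nc = params.image_size_px
    rows, cols = np.mgrid[0:nr, 0:nc]
    inside_epi = geometry.epi.implicit(rows, cols) <= 0.0
    inside_endo = geometry.endo.implicit(rows, cols) <= 0.0
    annulus = inside_epi & ~inside_endo
    i_par_eff = params.intensity_perp - aniso_scale * (
        params.intensity_perp - params.intensity_par
    )
    # cos^2 of the clockwise angle from the anterior (up) direction about the
    # epicardial centroid: cos(phi) = -dr / rho.
    dr = rows - geometry.epi.center_row
    dc = cols - geometry.epi.center_col
    rho2 = dr * dr + dc * dc
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = np.where(rho2 > 0, dr * dr / np.where(rho2 > 0, rho2, 1.0), 1.0)
    field_ = np.full((nr, nc), float(params.background))
    field_[annulus] = i_par_eff + (params.intensity_perp - i_par_eff) * cos2[annulus]
    return field_


def _check_annulus_fits(geometry: WallGeometry, params: PhantomParams) -> None:
    nr, nc = params.image_size_px
    pts = geometry.epi.boundary_points(720)
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() > nr - 1
        or pts[:, 1].max() > nc - 1
    ):
        raise GeometryError("annulus does not fit inside the image bounds")


def _speckle(params: PhantomParams, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    if params.speckle_model == "none":
        return np.ones(shape)
    if params.speckle_model == "exponential":
        noise = rng.exponential(1.0, size=shape)
    else:  # rayleigh, unit mean
        noise = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=shape)
    if params.smoothing_radius_px > 0:
        noise = ndimage.gaussian_filter(noise, sigma=params.smoothing_radius_px, mode="nearest")
    return noise


def generate_phantom_frame(
    geometry: WallGeometry,
    params: PhantomParams,
    timepoint_min: float = 0.0,
    aniso_scale: float = 1.0,
    rng: np.random.Generator | None = None,
    heart_id: str = "",
    arm: str = "",
) -> UltrasoundFrame:
    """One synthetic short-axis frame.

    ``rng`` overrides the params seed (used by the series generator to draw
    consecutive frames from a single stream). With ``speckle_model='none'``
    the frame equals the expected field exactly.
    """
    _check_annulus_fits(geometry, params)
    field_ = expected_intensity_field(geometry, params, aniso_scale)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pixels = field_ * _speckle(params, field_.shape, rng)
    return UltrasoundFrame(
        pixels=pixels,
        pixel_size_um=params.pixel_size_um,
        timepoint_min=timepoint_min,
        heart_id=heart_id,
        arm=arm,
    )


def generate_treatment_series(
    geometry: WallGeometry,
    params: PhantomParams,
    protocol: TreatmentProtocol,
    heart_id: str = "",
) -> list[UltrasoundFrame]:
    """Serial frames for one heart under the protocol.

    Returns floor(duration/interval) + 1 frames (13 for 30 min at 2.5-min
    intervals), all drawn from a single RNG stream seeded by params.seed so a
    fixed seed reproduces the whole series bit-identically.
    """
    rng = np.random.default_rng(params.seed)
    return [
        generate_phantom_frame(
            geometry,
            params,
            timepoint_min=float(t),
            aniso_scale=aniso_scale_at(protocol, float(t)),
            rng=rng,
            heart_id=heart_id,
            arm=protocol.arm,
        )
        for t in protocol.timepoints_min
    ]


# ---------------------------------------------------------------------------
# Histology fixtures


#: Class codes used in generated ground-truth masks.
HISTOLOGY_CLASS_CODES = {"background": 0, "red_orange": 1, "yellow": 2, "green": 3}

_CLASS_RANGES = {"red_orange": (2, 38), "yellow": (39, 51), "green": (52, 128)}


@dataclass(frozen=True)
class HistologyComposition:
    """Known hue composition of a synthetic picrosirius-red micrograph.

    Fractions must sum to 1; each class hue must lie inside its defining
    8-bit range (red/orange 2-38, yellow 39-51, green 52-128). Collagen
    pixels are generated fully saturated at the given brightness with a zero
    blue channel (hue bins <= 85), which makes their hue exactly invariant
    under the blue-/black-component subtractions; background pixels are
    achromatic gray (muscle-like) that the blue subtraction removes.
    """

    fraction_red_orange: float = 0.03
    fraction_yellow: float = 0.01
    fraction_green: float = 0.01
    fraction_background: float = 0.95
    hue_per_class: dict = field(
        default_factory=lambda: {"red_orange": 20, "yellow": 45, "green": 60}
    )
    brightness: float = 1.0
    background_gray: int = 180
    image_size_px: tuple[int, int] = (256, 256)
    seed: int | None = None

    def __post_init__(self) -> None:
        fr = (
            self.fraction_red_orange,
            self.fraction_yellow,
            self.fraction_green,
            self.fraction_background,
        )
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {sum(fr)})")
        for name, (lo, hi) in _CLASS_RANGES.items():
            h = self.hue_per_class.get(name)
            if h is None or not lo <= h <= hi:
                raise ValueError(f"hue for {name} must lie in [{lo}, {hi}]")
        if not 0.0 < self.brightness <= 1.0:
            raise ValueError("brightness must lie in (0, 1]")
        if not 0 <= self.background_gray <= 255:
            raise ValueError("background_gray must lie in [0, 255]")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "red_orange": self.fraction_red_orange,
            "yellow": self.fraction_yellow,
            "green": self.fraction_green,
            "background": self.fraction_background,
        }


def rgb_for_hue_bin(hue_bin: int, value: int = 255) -> tuple[int, int, int]:
    """A fully saturated 8-bit RGB triple whose hexcone hue bin is ``hue_bin``.

    The triple has max channel ``value`` and min channel 0; the free channel
    is searched so the quantised hue, round(H_deg * 255 / 360), lands exactly
    on ``hue_bin``. Bins 0-85 (hue <= 120 degrees) carry a zero blue channel
    and therefore survive the blue-component subtraction with their hue
    intact; larger bins are representable but not subtraction-stable. Raises
    ``ValueError`` when no integer channel value reproduces the bin.
    """
    if not 0 <= hue_bin <= 170:
        raise ValueError("hue bins above 170 (pure blue) are not collagen-like")
    if not 1 <= value <= 255:
        raise ValueError("value must lie in [1, 255]")
    h_deg = hue_bin * 360.0 / 255.0
    sector = min(int(h_deg // 60.0), 3)
    from fractions import Fraction

    for x in range(0, value + 1):
        rgb = {
            0: (value, x, 0),
            1: (x, value, 0),
            2: (0, value, x),
            3: (0, x, value),
        }[sector]
        # exact rational hue on the 0-255 scale; sector k spans 42.5 bins
        frac_in_sector = Fraction(x, value)
        if sector in (1, 3):  # hue decreases toward the sector start channel
            scaled = Fraction(85 * (sector + 1), 2) - frac_in_sector * Fraction(85, 2)
        else:
            scaled = Fraction(85 * sector, 2) + frac_in_sector * Fraction(85, 2)
        # skip exact .5 rounding ties so every hue implementation agrees
        twice = scaled * 2
        if twice.denominator == 1 and twice.numerator % 2 == 1:
            continue
        if round(float(scaled)) == hue_bin:
            return rgb
    raise ValueError(f"no exact RGB for hue bin {hue_bin} at value {value}")


def generate_histology_image(
    comp: HistologyComposition, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic micrograph plus ground-truth class mask.

    Pixel counts per class are allocated exactly (largest-remainder rounding,
    so requested fractions are met to within one pixel) and shuffled to random
    positions. Returns ``(rgb uint8 (r, c, 3), mask uint8 (r, c))`` with mask
    codes from :data:`HISTOLOGY_CLASS_CODES`.
    """
    if rng is None:
        rng = np.random.default_rng(comp.seed)
    nr, nc = comp.image_size_px
    n = nr * nc
    names = ["red_orange", "yellow", "green", "background"]
    exact = np.array([comp.fractions[k] * n for k in names])
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(exact - counts))
    for i in range(remainder):
        counts[order[i % 4]] += 1
    labels = np.repeat(
        [HISTOLOGY_CLASS_CODES[k] for k in names], counts
    )
    mask = rng.permutation(labels).astype(np.uint8).reshape(nr, nc)
    value = int(round(comp.brightness * 255))
    rgb = np.empty((nr, nc, 3), dtype=np.uint8)
    g = comp.background_gray
    rgb[...] = (g, g, g)
    for name in ("red_orange", "yellow", "green"):
        color = rgb_for_hue_bin(int(comp.hue_per_class[name]), value=value)
        rgb[mask == HISTOLOGY_CLASS_CODES[name]] = color
    return rgb, mask


# ---------------------------------------------------------------------------
# Orientation samples


@dataclass(frozen=True)
class OrientationModel:
    """Von Mises model of fiber orientations (axial, angle-doubled).

    Doubled angles 2*theta are drawn from von Mises(2*mean_angle_deg, kappa)
    and halved back into [0, 180); kappa is the concentration on the doubled
    circle (kappa = 0 gives the uniform axial distribution). Fifty
    measurements on a 10x5 grid emulate the manual polarized-light protocol.
    """

    mean_angle_deg: float = 30.0
    kappa: float = 8.0
    n: int = 50
    grid_shape: tuple[int, int] = (10, 5)
    axial: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_angle_deg < 180.0:
            raise ValueError("mean_angle_deg must lie in [0, 180)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def sample_orientations(
    model: OrientationModel,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
    group: str = "",
) -> OrientationSample:
    """Draw one orientation sample from the model."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    mu2 = math.radians(2.0 * model.mean_angle_deg)
    doubled = rng.vonmises(mu2, model.kappa, size=model.n)
    angles = (np.degrees(doubled) / 2.0) % 180.0
    if not model.axial:
        angles = np.degrees(doubled) % 360.0
    gr, gc = model.grid_shape
    cells = np.array([(i // gc, i % gc) for i in range(gr * gc)])
    reps = int(math.ceil(model.n / len(cells)))
    grid = np.tile(cells, (reps, 1))[: model.n]
    return OrientationSample(
        angles_deg=angles, axial=model.axial, grid=grid, sample_id=sample_id, group=group
    )
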