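"""Run configuration: one YAML file with per-module blocks.

Unknown keys are rejected with the offending key named, so a typo in a config
file fails loudly rather than silently using a default. The configuration
hash (sha256 of the canonical JSON form, first 12 hex digits) is stamped into
every output CSV for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .geometry import WallGeometry
from .synthdata import HistologyComposition, OrientationModel, PhantomParams, TreatmentProtocol

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


#: Per-arm defaults for the synthetic cohort. The control arm has tightly
#: aligned fibers (high kappa) and red-shifted collagen; collagenase arms
#: show progressively more disarray (lower kappa) and green-shifted hues
#: (thinner / less crosslinked fibers), while total collagen area stays
#: similar — collagenase alters organisation, not content.
ARM_HISTOLOGY = {
    "control": {"fraction_red_orange": 0.030, "fraction_yellow": 0.010, "fraction_green": 0.010},
    "collagenase10": {"fraction_red_orange": 0.020, "fraction_yellow": 0.015, "fraction_green": 0.015},
    "collagenase30": {"fraction_red_orange": 0.015, "fraction_yellow": 0.015, "fraction_green": 0.020},
}
ARM_KAPPA = {"control": 8.0, "collagenase10": 5.0, "collagenase30": 2.0}


def _take(block: dict, allowed: set[str], where: str) -> dict:
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in config block {where!r}")
    return dict(block)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    cohort: dict = field(
        default_factory=lambda: {"control": 8, "collagenase10": 7, "collagenase30": 7}
    )
    phantom: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)  # duration_min, interval_min, decay_rate_per_min
    geometry: dict | None = None  # WallGeometry dict; default annulus when None
    roi_side_um: float = 250.0
    brightness_floor: int = 10
    histology: dict = field(default_factory=dict)  # per-arm HistologyComposition overrides
    orientation: dict = field(default_factory=dict)  # per-arm OrientationModel overrides
    counts_per_au: float = 100.0

    def __post_init__(self) -> None:
        self.seed = int(self.seed) % (2**31)
        for arm, n in self.cohort.items():
            if arm not in ARM_KAPPA:
                raise ConfigError(f"unknown arm {arm!r} in cohort")
            if int(n) < 0:
                raise ConfigError(f"negative replicate count for arm {arm!r}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        allowed = {f.name for f in fields(cls)}
        return cls(**_take(d or {}, allowed, "<root>"))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # -- derived objects ----------------------------------------------------

    def phantom_params(self, seed: int | None = None) -> PhantomParams:
        allowed = {f.name for f in fields(PhantomParams)}
        block = _take(self.phantom, allowed, "phantom")
        if "image_size_px" in block:
            block["image_size_px"] = tuple(block["image_size_px"])
        if seed is not None:
            block["seed"] = seed
        return PhantomParams(**block)

    def protocol_for(self, arm: str) -> TreatmentProtocol:
        allowed = {"duration_min", "interval_min", "decay_rate_per_min"}
        block = _take(self.protocol, allowed, "protocol")
        return TreatmentProtocol(arm=arm, **block)

    def wall_geometry(self, params: PhantomParams) -> WallGeometry:
        if self.geometry is not None:
            return WallGeometry.from_dict(self.geometry)
        from .synthdata import default_geometry

        return default_geometry(params)

    def histology_composition(self, arm: str, seed: int | None = None) -> HistologyComposition:
        allowed = {f.name for f in fields(HistologyComposition)}
        block = dict(ARM_HISTOLOGY[arm])
        block["fraction_background"] = 1.0 - sum(block.values())
        block.update(_take(self.histology.get(arm, {}), allowed, f"histology.{arm}"))
        if "image_size_px" in block:
            block["image_size_px"] = tuple(block["image_size_px"])
        if seed is not None:
            block["seed"] = seed
        return HistologyComposition(**block)

    def orientation_model(self, arm: str, seed: int | None = None) -> OrientationModel:
        allowed = {f.name for f in fields(OrientationModel)}
        block = {"kappa": ARM_KAPPA[arm]}
        block.update(_take(self.orientation.get(arm, {}), allowed, f"orientation.{arm}"))
        if "grid_shape" in block:
            block["grid_shape"] = tuple(block["grid_shape"])
        if seed is not None:
            block["seed"] = seed
        return OrientationModel(**block)

    # -- seeds and provenance -----------------------------------------------

    def heart_seed(self, index: int) -> int:
        """Per-heart frame seed: master seed + heart index (stated splitting rule)."""
        return (self.seed + index) % (2**31)

    def histology_seed(self, index: int) -> int:
        return (self.seed + 10_000 + index) % (2**31)

    def orientation_seed(self, index: int) -> int:
        return (self.seed + 20_000 + index) % (2**31)

    def canonical_json(self) -> str:
        """Canonical JSON of the scientific configuration.

        ``out_dir`` is excluded: where a run is written must not change its
        provenance hash, so reruns into fresh directories stay byte-identical.
        """
        d = asdict(self)
        d.pop("out_dir")
        return json.dumps(d, sort_keys=True, separators=(",", ":"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:12]
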