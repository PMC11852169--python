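"""Run configuration: one YAML tree covering every pipeline stage.

Profiles fix the canonical image size and the descriptor scales: CFP works
at 1000x1000 with scales (3, 5, 10); UWF at 1500x1500 with the scales
enlarged by the same 1.5 resolution factor, rounded to (5, 8, 15).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError
from .imaging import Profile
from .mcsd import MCSDParams
from .scoring import (HIGH_THRESHOLD, LOW_THRESHOLD, RING_WIDTH_FRACTION,
                      VESSEL_OVERLAP_THRESHOLD)
from .synthetic import SceneConfig
from .typing_rules import TypingParams
from .unet import UNetConfig

PROFILE_SCALES = {Profile.CFP: (3, 5, 10), Profile.UWF: (5, 8, 15)}


@dataclass(frozen=True)
class McsdConfig:
    scales: tuple[int, ...] = (3, 5, 10)
    n_directions: int = 16
    contrast_floor: float = 0.02
    vessel_floor: float = 0.06
    min_area: int = 2

    def params(self, **kw) -> MCSDParams:
        return MCSDParams(scales=self.scales, n_directions=self.n_directions,
                          **kw)


@dataclass(frozen=True)
class ScoringConfig:
    low_threshold: float = LOW_THRESHOLD
    high_threshold: float = HIGH_THRESHOLD
    ring_width_fraction: float = RING_WIDTH_FRACTION
    vessel_overlap_threshold: float = VESSEL_OVERLAP_THRESHOLD


@dataclass(frozen=True)
class PatchConfig:
    init_side: int = 10
    step: int = 5
    min_side: int = 60
    max_side: int = 120


@dataclass(frozen=True)
class RunConfig:
    profile: Profile = Profile.CFP
    seed: int = 0
    out_dir: str = "runs"
    mcsd: McsdConfig = field(default_factory=McsdConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    typing: TypingParams = field(default_factory=TypingParams)
    patches: PatchConfig = field(default_factory=PatchConfig)
    segmentation: UNetConfig = field(default_factory=UNetConfig)
    synth: SceneConfig = field(default_factory=SceneConfig)

    def with_profile_defaults(self) -> "RunConfig":
        return replace(self, mcsd=replace(self.mcsd,
                                          scales=PROFILE_SCALES[self.profile]))


_SECTIONS = {"mcsd": McsdConfig, "scoring": ScoringConfig,
             "typing": TypingParams, "patches": PatchConfig,
             "segmentation": UNetConfig, "synth": SceneConfig}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Unknown keys raise a ConfigError rather than being ignored.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        data.update(raw)
    data.update(overrides)

    kwargs: dict = {}
    if "profile" in data:
        name = str(data.pop("profile")).upper()
        try:
            kwargs["profile"] = Profile[name]
        except KeyError:
            raise ConfigError(f"unknown profile {name!r}") from None
    for key in ("seed", "out_dir"):
        if key in data:
            kwargs[key] = data.pop(key)
    for section, cls in _SECTIONS.items():
        if section in data:
            sub = data.pop(section)
            if not isinstance(sub, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            try:
                if section == "synth" and "shape" in sub:
                    sub["shape"] = tuple(sub["shape"])
                if section == "mcsd" and "scales" in sub:
                    sub["scales"] = tuple(sub["scales"])
                kwargs[section] = cls(**sub)
            except TypeError as exc:
                raise ConfigError(f"bad keys in section {section!r}: {exc}") from exc
    if data:
        raise ConfigError(f"unknown config keys: {sorted(data)}")
    cfg = RunConfig(**kwargs)
    if "mcsd" not in kwargs:
        cfg = cfg.with_profile_defaults()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["profile"] = cfg.profile.name
    d["mcsd"]["scales"] = list(cfg.mcsd.scales)
    d["synth"]["shape"] = list(cfg.synth.shape)
    for key in ("vessel_contrast", "vessel_sigma", "ma_radius", "ma_contrast",
                "hem_semi_major", "hem_axis_ratio", "hem_contrast",
                "hex_radius", "hex_contrast", "sex_radius", "sex_contrast",
                "faint_contrast"):
        d["synth"][key] = list(d["synth"][key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
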