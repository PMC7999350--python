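"""Run configuration: every tunable threshold in one human-editable YAML.

Unknown keys are rejected at load time and every numeric field is checked
against the preconditions of the operation it feeds, so a typo fails fast
instead of silently changing the analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .core import PipelineError
from .spectral import (
    DEFAULT_BLUE,
    DEFAULT_RED_A,
    DEFAULT_RED_B,
    DEFAULT_YELLOW,
    HueWindow,
)
from .synth import NoiseConfig, SynthGeometry

__all__ = ["GeometryParams", "SamplingParams", "BinningParams", "StatsParams", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class GeometryParams:
    bg_threshold: float = 0.02
    min_span_px: int = 5
    gap_tolerance_px: int = 2
    vascular_frac_threshold: float = 0.15
    dilate_cols: int = 3

    def __post_init__(self):
        if not (0.0 < self.bg_threshold < 1.0):
            raise PipelineError("BAD_WINDOW", "geometry.bg_threshold must be in (0,1)")
        if self.min_span_px < 1 or self.gap_tolerance_px < 0 or self.dilate_cols < 0:
            raise PipelineError("BAD_WINDOW", "geometry pixel counts out of range")
        if not (0.0 < self.vascular_frac_threshold < 1.0):
            raise PipelineError("BAD_WINDOW", "geometry.vascular_frac_threshold must be in (0,1)")


@dataclass(frozen=True)
class SamplingParams:
    n_transects: int = 5
    edge_margin_frac: float = 0.03

    def __post_init__(self):
        if self.n_transects < 1:
            raise PipelineError("BAD_WINDOW", "sampling.n_transects must be >= 1")
        if not (0.0 <= self.edge_margin_frac < 0.2):
            raise PipelineError("BAD_WINDOW", "sampling.edge_margin_frac must be in [0, 0.2)")


@dataclass(frozen=True)
class BinningParams:
    n_bins: int = 5

    def __post_init__(self):
        if self.n_bins < 1:
            raise PipelineError("BAD_WINDOW", "binning.n_bins must be >= 1")


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    lsd_grouping: str = "within_variety"  # or "across"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise PipelineError("BAD_WINDOW", "stats.alpha must be in (0,1)")
        if self.lsd_grouping not in ("within_variety", "across"):
            raise PipelineError("BAD_WINDOW", "stats.lsd_grouping must be within_variety|across")


@dataclass(frozen=True)
class RunConfig:
    spectral: dict = field(
        default_factory=lambda: {
            "yellow": DEFAULT_YELLOW,
            "red_a": DEFAULT_RED_A,
            "red_b": DEFAULT_RED_B,
            "blue": DEFAULT_BLUE,
        }
    )
    geometry: GeometryParams = field(default_factory=GeometryParams)
    sampling: SamplingParams = field(default_factory=SamplingParams)
    binning: BinningParams = field(default_factory=BinningParams)
    generator: SynthGeometry = field(default_factory=SynthGeometry)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    stats: StatsParams = field(default_factory=StatsParams)


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise PipelineError("BAD_WINDOW", f"unknown key(s) in {section}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sections = {"spectral", "geometry", "sampling", "binning", "generator", "noise", "stats"}
    unknown = set(data) - sections
    if unknown:
        raise PipelineError("BAD_WINDOW", f"unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    if "spectral" in data:
        windows = {}
        for name, wdata in (data["spectral"] or {}).items():
            if name not in ("yellow", "red_a", "red_b", "blue"):
                raise PipelineError("BAD_WINDOW", f"unknown spectral window {name!r}")
            windows[name] = _build(HueWindow, wdata, f"spectral.{name}")
        defaults = RunConfig().spectral
        defaults.update(windows)
        kwargs["spectral"] = defaults
    for key, cls in (
        ("geometry", GeometryParams),
        ("sampling", SamplingParams),
        ("binning", BinningParams),
        ("generator", SynthGeometry),
        ("noise", NoiseConfig),
        ("stats", StatsParams),
    ):
        if key in data:
            raw = data[key] or {}
            if key == "generator" and "n_bundles_range" in raw:
                raw = dict(raw)
                raw["n_bundles_range"] = tuple(raw["n_bundles_range"])
            kwargs[key] = _build(cls, raw, key)
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    data = {
        "spectral": {name: asdict(w) for name, w in cfg.spectral.items()},
        "geometry": asdict(cfg.geometry),
        "sampling": asdict(cfg.sampling),
        "binning": asdict(cfg.binning),
        "generator": {
            **asdict(cfg.generator),
            "n_bundles_range": list(cfg.generator.n_bundles_range),
        },
        "noise": asdict(cfg.noise),
        "stats": asdict(cfg.stats),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
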