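"""Shared domain types for the leaf cross-section fluorescence pipeline.

A micrograph enters the pipeline as an :class:`RgbSection` — one half of a
leaf lamina, midrib at the left edge, adaxial (upper) epidermis at row 0 —
and every spectral operation yields a :class:`FluorescenceMap`, a scalar
raster of isolated fluorescence intensity in [0, 1].

Treatment factors mirror the growth-chamber experiment the pipeline was
built for: two barley varieties with different oxidative-stress tolerance,
three CO2 concentrations, and two light regimes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PipelineError",
    "Variety",
    "CO2Level",
    "LightRegime",
    "Channel",
    "Orientation",
    "TreatmentLabel",
    "RgbSection",
    "FluorescenceMap",
]


class PipelineError(ValueError):
    """Error with a stable machine-readable ``code`` (e.g. ``"EMPTY_IMAGE"``)."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)


class Variety(enum.Enum):
    """Barley variety: Barke (oxidative-stress sensitive) or Bojos (tolerant)."""

    BARKE = "Barke"
    BOJOS = "Bojos"


class CO2Level(enum.Enum):
    """Growth [CO2] in ppm: low (LC), ambient (AC), elevated (EC)."""

    LC = 200
    AC = 400
    EC = 700

    @property
    def ppm(self) -> int:
        return self.value


class LightRegime(enum.Enum):
    """Light regime: low light (LL) or high light (HL)."""

    LL = "LL"
    HL = "HL"


class Channel(enum.Enum):
    """Fluorescence color class of a map.

    Yellow: flavonoid–Naturstoff-reagent chelates (the signal of interest).
    Red: chlorophyll autofluorescence (mesophyll marker).
    Blue: cell-wall / vascular autofluorescence (exclusion marker).
    """

    PHC_YELLOW = "PHC_YELLOW"
    CHLOROPHYLL_RED = "CHLOROPHYLL_RED"
    WALL_BLUE = "WALL_BLUE"


class Orientation(enum.Enum):
    ADAXIAL_TOP = "ADAXIAL_TOP"


@dataclass(frozen=True)
class TreatmentLabel:
    """Treatment metadata for one section image."""

    variety: Variety
    co2: CO2Level
    light: LightRegime
    replicate: int = 1
    section: int = 1

    def same_treatment(self, other: "TreatmentLabel") -> bool:
        """True if the experimental cell (variety, co2, light) matches."""
        return (
            self.variety == other.variety
            and self.co2 == other.co2
            and self.light == other.light
        )

    def same_replicate(self, other: "TreatmentLabel") -> bool:
        return self.same_treatment(other) and self.replicate == other.replicate


@dataclass
class RgbSection:
    """8-bit RGB raster of one half-lamina cross-section plus metadata.

    Invariant: adaxial epidermis at row 0 (images flagged abaxial-up are
    flipped on load), all channel values in 0–255.
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    meta: TreatmentLabel | None = None
    orientation: Orientation = Orientation.ADAXIAL_TOP

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise PipelineError("BAD_IMAGE", f"expected (H, W, 3) raster, got {px.shape}")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise PipelineError("BAD_IMAGE", f"expected 8-bit channels, got {px.dtype}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class FluorescenceMap:
    """Scalar raster of isolated fluorescence intensity in [0, 1].

    ``values`` is exactly 0 wherever the source pixel fell outside the
    channel's hue window.
    """

    values: np.ndarray  # (H, W) float
    channel_tag: Channel = Channel.PHC_YELLOW

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise PipelineError("BAD_IMAGE", f"expected 2-D raster, got shape {v.shape}")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise PipelineError("BAD_IMAGE", "map values outside [0, 1]")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]
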