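"""Spectral separation of fluorescence colors by hue windows.

Under blue-light excitation a Naturstoff-reagent-treated barley section
shows three fluorescence colors: yellow from flavonoid chelates, red from
chlorophyll, and blue from cell-wall phenolics and vascular tissue. The
original workflow removed chlorophyll and kept "all yellow color" with an
image-editor macro; here that step is a deterministic hue-window operator
in HSV space, with all thresholds explicit and overridable.

The intensity metric is the HSV value channel (max of R, G, B scaled to
[0, 1]) — "pixel brightness" — so pure-color identities are exact: a
saturated yellow pixel (255, 255, 0) maps to intensity 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .core import Channel, FluorescenceMap, PipelineError, RgbSection

__all__ = [
    "HueWindow",
    "DEFAULT_YELLOW",
    "DEFAULT_RED_A",
    "DEFAULT_RED_B",
    "DEFAULT_BLUE",
    "isolate_phc",
    "channel_mask",
]


@dataclass(frozen=True)
class HueWindow:
    """Inclusive hue interval (degrees) with saturation/value floors."""

    hue_low: float
    hue_high: float
    sat_min: float = 0.2
    val_min: float = 0.04

    def __post_init__(self):
        if not (0.0 <= self.hue_low < self.hue_high <= 360.0):
            raise PipelineError(
                "BAD_WINDOW", f"need 0 <= hue_low < hue_high <= 360, got [{self.hue_low}, {self.hue_high}]"
            )
        if not (0.0 <= self.sat_min <= 1.0 and 0.0 <= self.val_min <= 1.0):
            raise PipelineError("BAD_WINDOW", "sat_min and val_min must lie in [0, 1]")


# Default windows for the three fluorescence colors. The red hue range wraps
# around 0 and is expressed as two explicit sub-windows so each window keeps
# the simple low < high invariant.
DEFAULT_YELLOW = HueWindow(30.0, 90.0)
DEFAULT_RED_A = HueWindow(0.0, 30.0)
DEFAULT_RED_B = HueWindow(330.0, 360.0)
DEFAULT_BLUE = HueWindow(190.0, 270.0)


def _hsv_degrees(image: RgbSection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (hue in degrees, saturation, value), all float rasters."""
    if image.height == 0 or image.width == 0:
        raise PipelineError("EMPTY_IMAGE", "zero-sized raster")
    hsv = rgb2hsv(image.pixels.astype(np.float64) / 255.0)
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def _window_values(hue, sat, val, window: HueWindow) -> np.ndarray:
    inside = (
        (hue >= window.hue_low)
        & (hue <= window.hue_high)
        & (sat >= window.sat_min)
        & (val >= window.val_min)
    )
    return np.where(inside, val, 0.0)


def isolate_phc(image: RgbSection, window: HueWindow | None = None) -> FluorescenceMap:
    """Isolate yellow flavonoid fluorescence.

    Each pixel is converted to HSV; the output carries the pixel's value
    (brightness) where hue falls inside ``window`` and saturation/value
    clear their floors, and exactly 0 elsewhere. Deterministic.
    """
    if window is None:
        window = DEFAULT_YELLOW
    elif not isinstance(window, HueWindow):
        raise PipelineError("BAD_WINDOW", f"expected HueWindow, got {type(window).__name__}")
    hue, sat, val = _hsv_degrees(image)
    return FluorescenceMap(_window_values(hue, sat, val, window), Channel.PHC_YELLOW)


def channel_mask(
    image: RgbSection,
    tag: Channel,
    windows: dict[str, HueWindow] | None = None,
) -> FluorescenceMap:
    """Isolate a named fluorescence channel (red chlorophyll or blue walls).

    The red window wraps around hue 0 and is the OR of two sub-windows.
    ``windows`` may override the defaults with keys ``red_a``, ``red_b``,
    ``blue`` (and ``yellow`` for the PHC tag, which delegates to
    :func:`isolate_phc`).
    """
    windows = windows or {}
    if tag == Channel.CHLOROPHYLL_RED:
        hue, sat, val = _hsv_degrees(image)
        a = _window_values(hue, sat, val, windows.get("red_a", DEFAULT_RED_A))
        b = _window_values(hue, sat, val, windows.get("red_b", DEFAULT_RED_B))
        return FluorescenceMap(np.maximum(a, b), tag)
    if tag == Channel.WALL_BLUE:
        hue, sat, val = _hsv_degrees(image)
        return FluorescenceMap(
            _window_values(hue, sat, val, windows.get("blue", DEFAULT_BLUE)), tag
        )
    if tag == Channel.PHC_YELLOW:
        return isolate_phc(image, windows.get("yellow", DEFAULT_YELLOW))
    raise PipelineError("BAD_TAG", f"unknown channel tag {tag!r}")
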