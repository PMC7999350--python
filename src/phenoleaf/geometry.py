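"""Leaf geometry: tissue mask, mesophyll spans, vascular exclusion.

Mesophyll extent is delimited per column from the chlorophyll (red) map —
chlorophyll autofluorescence fills the mesophyll but is absent from
epidermal pavement cells, so the longest chlorophyll-positive run of a
column is its mesophyll span, with small gaps (intercellular air spaces,
interleaved non-red pixels) bridged. Columns dominated by blue
autofluorescence (vascular bundles, midrib sclerenchyma) are excluded from
transect placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label
from skimage.morphology import closing

from .core import FluorescenceMap, PipelineError, RgbSection

__all__ = [
    "LeafMask",
    "MesophyllSpan",
    "ExclusionMask",
    "detect_tissue",
    "mesophyll_spans",
    "vascular_exclusion",
]


@dataclass
class LeafMask:
    """Boolean raster: tissue vs background / mounting medium."""

    foreground: np.ndarray  # (H, W) bool


@dataclass(frozen=True)
class MesophyllSpan:
    """Per-column mesophyll extent (inclusive row bounds), epidermis excluded."""

    column: int
    top: int
    bottom: int
    valid: bool

    @property
    def length(self) -> int:
        return self.bottom - self.top + 1 if self.valid else 0


@dataclass
class ExclusionMask:
    """Columns unavailable for transect placement."""

    excluded_columns: frozenset


def detect_tissue(image: RgbSection, bg_threshold: float = 0.02) -> LeafMask:
    """Threshold the brightness channel and keep the largest 8-connected blob.

    ``bg_threshold`` is the value-channel floor separating tissue from the
    dark mounting medium; after thresholding, only the single largest
    connected component is retained and a 3x3 morphological closing fills
    pinholes.
    """
    if not (0.0 < bg_threshold < 1.0):
        raise PipelineError("BAD_WINDOW", f"bg_threshold must be in (0,1), got {bg_threshold}")
    value = image.pixels.astype(np.float64).max(axis=2) / 255.0
    fg = value > bg_threshold
    if not fg.any():
        raise PipelineError("NO_TISSUE", "no pixel above background threshold")
    labels = label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    fg = labels == counts.argmax()
    fg = closing(fg, footprint=np.ones((3, 3), dtype=bool))
    return LeafMask(foreground=fg)


def _longest_bridged_run(active: np.ndarray, gap_tolerance: int) -> tuple[int, int] | None:
    """Longest run of True values, bridging internal gaps <= gap_tolerance.

    Returns (top, bottom) inclusive indices of True endpoints, or None.
    """
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return None
    # split where the gap between consecutive positives exceeds the tolerance
    breaks = np.flatnonzero(np.diff(idx) > gap_tolerance + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    lengths = idx[ends] - idx[starts] + 1
    best = int(lengths.argmax())
    return int(idx[starts[best]]), int(idx[ends[best]])


def mesophyll_spans(
    chl: FluorescenceMap,
    mask: LeafMask,
    min_span_px: int = 5,
    gap_tolerance_px: int = 2,
) -> list[MesophyllSpan]:
    """Find each column's mesophyll span from the chlorophyll map.

    The span is the longest contiguous vertical run of chlorophyll-positive
    pixels inside the tissue mask, with gaps up to ``gap_tolerance_px``
    bridged; runs shorter than ``min_span_px`` are marked invalid. One span
    record is returned per image column (invalid where no run exists).
    """
    if chl.values.shape != mask.foreground.shape:
        raise PipelineError(
            "SHAPE_MISMATCH",
            f"chlorophyll map {chl.values.shape} vs mask {mask.foreground.shape}",
        )
    if min_span_px < 1:
        raise PipelineError("BAD_WINDOW", "min_span_px must be >= 1")
    active = (chl.values > 0) & mask.foreground
    spans: list[MesophyllSpan] = []
    for col in range(active.shape[1]):
        run = _longest_bridged_run(active[:, col], gap_tolerance_px)
        if run is None:
            spans.append(MesophyllSpan(column=col, top=-1, bottom=-1, valid=False))
        else:
            top, bottom = run
            valid = (bottom - top + 1) >= min_span_px
            spans.append(MesophyllSpan(column=col, top=top, bottom=bottom, valid=valid))
    return spans


def vascular_exclusion(
    blue: FluorescenceMap,
    spans: list[MesophyllSpan],
    frac_threshold: float = 0.15,
    dilate_cols: int = 3,
) -> ExclusionMask:
    """Exclude columns whose mesophyll span is dominated by blue fluorescence.

    A column is excluded when the fraction of its span pixels with blue > 0
    exceeds ``frac_threshold``; that set is dilated by ``dilate_cols``
    columns on each side. Columns with invalid spans are always excluded
    (undilated — dilating around the thin leaf margin would eat usable
    columns).
    """
    if not (0.0 < frac_threshold < 1.0):
        raise PipelineError("BAD_WINDOW", f"frac_threshold must be in (0,1), got {frac_threshold}")
    if dilate_cols < 0:
        raise PipelineError("BAD_WINDOW", "dilate_cols must be >= 0")
    width = blue.values.shape[1]
    over: set[int] = set()
    invalid: set[int] = set()
    for span in spans:
        if span.column < 0 or span.column >= width:
            raise PipelineError("SHAPE_MISMATCH", f"span column {span.column} outside map")
        if not span.valid:
            invalid.add(span.column)
            continue
        seg = blue.values[span.top : span.bottom + 1, span.column]
        if (seg > 0).mean() > frac_threshold:
            over.add(span.column)
    excluded = set(invalid)
    for col in over:
        lo = max(0, col - dilate_cols)
        hi = min(width - 1, col + dilate_cols)
        excluded.update(range(lo, hi + 1))
    return ExclusionMask(excluded_columns=frozenset(excluded))
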