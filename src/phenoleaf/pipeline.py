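"""End-to-end profiling of one section image.

Glue that chains the spectral, geometry and profiling stages with a shared
configuration: isolate the three fluorescence channels, delimit mesophyll
spans from the chlorophyll map, exclude vascular columns via the blue map,
place systematic transects, and bin the PhC profile into depth layers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .core import Channel, RgbSection
from .geometry import ExclusionMask, MesophyllSpan, detect_tissue, mesophyll_spans, vascular_exclusion
from .profiling import (
    DepthBins,
    SectionProfile,
    aggregate_section,
    bin_profile,
    extract_profile,
    place_transects,
)
from .spectral import channel_mask, isolate_phc

__all__ = ["SectionResult", "profile_section"]


@dataclass
class SectionResult:
    """Everything the pipeline derived from one section image."""

    profile: SectionProfile
    transect_bins: list
    columns: list
    spans: list
    exclusions: ExclusionMask


def profile_section(
    image: RgbSection,
    config: RunConfig | None = None,
    rng_seed: int = 0,
) -> SectionResult:
    """Run the full spectral -> geometry -> depth-profile pipeline."""
    cfg = config or RunConfig()
    yellow = isolate_phc(image, cfg.spectral["yellow"])
    chl = channel_mask(image, Channel.CHLOROPHYLL_RED, windows=cfg.spectral)
    blue = channel_mask(image, Channel.WALL_BLUE, windows=cfg.spectral)
    mask = detect_tissue(image, cfg.geometry.bg_threshold)
    spans = mesophyll_spans(
        chl, mask, min_span_px=cfg.geometry.min_span_px, gap_tolerance_px=cfg.geometry.gap_tolerance_px
    )
    excl = vascular_exclusion(
        blue,
        spans,
        frac_threshold=cfg.geometry.vascular_frac_threshold,
        dilate_cols=cfg.geometry.dilate_cols,
    )
    columns = place_transects(
        spans,
        excl,
        n=cfg.sampling.n_transects,
        edge_margin_frac=cfg.sampling.edge_margin_frac,
        rng_seed=rng_seed,
    )
    span_by_col = {s.column: s for s in spans}
    bins = [
        bin_profile(extract_profile(yellow, span_by_col[c]), n_bins=cfg.binning.n_bins)
        for c in columns
    ]
    profile = aggregate_section(bins, meta=image.meta)
    return SectionResult(
        profile=profile, transect_bins=bins, columns=columns, spans=spans, exclusions=excl
    )
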