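"""Depth profiling: systematic transects, five-layer binning, aggregation.

Five equally spaced vertical sampling lines are placed across the usable
lamina width with one shared uniform random offset (systematic uniform
random sampling — the stereological design that makes the spatial estimate
unbiased). Each transect's per-pixel intensities are binned into five
mesophyll depth layers — adaxial (AD), upper (UM), middle (MM), lower (LM),
abaxial (AB) — by the relative-depth midpoint rule, then averaged over
transects (section) and sections (replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FluorescenceMap, PipelineError, TreatmentLabel
from .geometry import ExclusionMask, MesophyllSpan

__all__ = [
    "LAYERS",
    "Transect",
    "DepthBins",
    "SectionProfile",
    "ReplicateProfile",
    "place_transects",
    "extract_profile",
    "bin_profile",
    "aggregate_section",
    "aggregate_replicate",
]

#: Depth layer labels in fixed adaxial -> abaxial order.
LAYERS = ("AD", "UM", "MM", "LM", "AB")


@dataclass
class Transect:
    """Pixel intensities along one vertical sampling line, index 0 adaxial."""

    column: int
    top: int
    bottom: int
    intensities: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.intensities, dtype=float)
        if v.size != self.bottom - self.top + 1:
            raise PipelineError("INVALID_SPAN", "intensity length does not match span")
        self.intensities = v


@dataclass
class DepthBins:
    """Layer mean intensities plus the pixel count behind each mean."""

    values: np.ndarray  # (n_bins,) float
    n_pixels: np.ndarray  # (n_bins,) int
    labels: tuple = LAYERS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if self.values.shape != self.n_pixels.shape:
            raise PipelineError("SHAPE_MISMATCH", "values vs n_pixels length")

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.values))

    @property
    def argmax_layer(self) -> str:
        return self.labels[int(self.values.argmax())]


@dataclass
class SectionProfile:
    """Layer means averaged over one section's transects."""

    bins: DepthBins
    n_transects: int
    meta: TreatmentLabel | None = None


@dataclass
class ReplicateProfile:
    """Layer means averaged over one replicate's sections."""

    bins: DepthBins
    n_sections: int
    meta: TreatmentLabel | None = None


def place_transects(
    spans: list[MesophyllSpan],
    excl: ExclusionMask,
    n: int = 5,
    edge_margin_frac: float = 0.03,
    rng_seed=0,
) -> list[int]:
    """Place ``n`` systematic vertical transect columns with a random offset.

    The usable width W is the extent of valid-span columns trimmed by
    ``edge_margin_frac`` on each side; the stride is s = W/n and a single
    offset u ~ Uniform[0, s) is drawn from the seeded generator. Nominal
    columns sit at floor(u + k*s) from the midrib (left) side — the floor
    rule gives every usable column inclusion probability exactly 1/s, so the
    systematic estimate is unbiased. A nominal column that is excluded moves
    to the nearest non-excluded column, ties broken toward the midrib;
    results are strictly increasing and distinct.
    """
    if n < 1:
        raise PipelineError("BAD_WINDOW", "n must be >= 1")
    if not (0.0 <= edge_margin_frac < 0.2):
        raise PipelineError("BAD_WINDOW", "edge_margin_frac must be in [0, 0.2)")
    # seed, Generator, or any object exposing .uniform(low, high)
    rng = rng_seed if hasattr(rng_seed, "uniform") else np.random.default_rng(rng_seed)

    valid_cols = sorted(s.column for s in spans if s.valid)
    if not valid_cols:
        raise PipelineError("TOO_FEW_COLUMNS", "no valid mesophyll spans")
    extent = valid_cols[-1] - valid_cols[0] + 1
    margin = int(np.floor(extent * edge_margin_frac))
    start = valid_cols[0] + margin
    end = valid_cols[-1] - margin
    width = end - start + 1
    if width < n:
        raise PipelineError("TOO_FEW_COLUMNS", f"usable width {width} < n={n}")

    valid_set = set(valid_cols)
    allowed = [
        c for c in range(start, end + 1)
        if c in valid_set and c not in excl.excluded_columns
    ]
    if len(allowed) < n:
        raise PipelineError("TOO_FEW_COLUMNS", f"{len(allowed)} non-excluded columns < n={n}")

    stride = width / n
    offset = rng.uniform(0.0, stride)
    allowed_arr = np.array(allowed)
    chosen: list[int] = []
    for k in range(n):
        nominal = start + int(np.floor(offset + k * stride))
        if nominal in allowed and nominal not in chosen:
            chosen.append(nominal)
            continue
        free = allowed_arr[~np.isin(allowed_arr, chosen)]
        dist = np.abs(free - nominal)
        best = dist.min()
        # ties broken toward the midrib (smaller column index)
        chosen.append(int(free[dist == best].min()))
    chosen.sort()
    return chosen


def extract_profile(phc: FluorescenceMap, span: MesophyllSpan) -> Transect:
    """Read PhC intensities down one column's mesophyll span (no interpolation)."""
    if not span.valid:
        raise PipelineError("INVALID_SPAN", f"column {span.column} has no valid span")
    vals = phc.values[span.top : span.bottom + 1, span.column]
    return Transect(column=span.column, top=span.top, bottom=span.bottom, intensities=vals)


def bin_profile(t: Transect, n_bins: int = 5) -> DepthBins:
    """Bin a transect into depth layers by the relative-depth midpoint rule.

    Pixel i of a length-L transect goes to bin floor(n_bins*(i + 0.5)/L)
    (clamped); the rule is symmetric under adaxial/abaxial flip and no two
    bins differ by more than one pixel in count. Bins left empty (only
    possible when L < n_bins) carry the value of the nearest non-empty bin
    with a pixel count of 0.
    """
    L = t.intensities.size
    if L == 0:
        raise PipelineError("EMPTY_TRANSECT", f"column {t.column}")
    if n_bins < 1:
        raise PipelineError("BAD_WINDOW", "n_bins must be >= 1")
    idx = np.minimum((n_bins * (np.arange(L) + 0.5) / L).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=t.intensities, minlength=n_bins)
    values = np.full(n_bins, np.nan)
    nonzero = counts > 0
    values[nonzero] = sums[nonzero] / counts[nonzero]
    if not nonzero.all():
        filled = np.flatnonzero(nonzero)
        for b in np.flatnonzero(~nonzero):
            # nearest non-empty bin; ties toward the adaxial side
            values[b] = values[filled[np.abs(filled - b).argmin()]]
    labels = LAYERS if n_bins == 5 else tuple(f"B{i}" for i in range(n_bins))
    return DepthBins(values=values, n_pixels=counts, labels=labels)


def _mean_bins(bins_list: list[DepthBins]) -> DepthBins:
    ref = bins_list[0]
    for b in bins_list[1:]:
        if b.labels != ref.labels:
            raise PipelineError("META_MISMATCH", "mixed bin labelings")
    values = np.mean([b.values for b in bins_list], axis=0)
    n_pixels = np.sum([b.n_pixels for b in bins_list], axis=0)
    return DepthBins(values=values, n_pixels=n_pixels, labels=ref.labels)


def aggregate_section(
    bins_list: list[DepthBins], meta: TreatmentLabel | None = None
) -> SectionProfile:
    """Unweighted mean of a section's transect bins."""
    if not bins_list:
        raise PipelineError("NOTHING_TO_AGGREGATE", "empty transect list")
    return SectionProfile(bins=_mean_bins(bins_list), n_transects=len(bins_list), meta=meta)


def aggregate_replicate(
    sections: list[SectionProfile], meta: TreatmentLabel | None = None
) -> ReplicateProfile:
    """Unweighted mean of a replicate's section profiles."""
    if not sections:
        raise PipelineError("NOTHING_TO_AGGREGATE", "empty section list")
    metas = [s.meta for s in sections if s.meta is not None]
    for m in metas[1:]:
        if not m.same_treatment(metas[0]):
            raise PipelineError("META_MISMATCH", "sections from different treatments")
    if meta is None and metas:
        meta = metas[0]
    return ReplicateProfile(
        bins=_mean_bins([s.bins for s in sections]),
        n_sections=len(sections),
        meta=meta,
    )
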