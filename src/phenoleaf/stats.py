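"""Factorial fixed-effects ANOVA, Fisher's LSD letters, pattern classification.

The inferential layer works on the tidy replicate-level table: factors are
variety (Var, 2 levels), CO2 (3), light (2), and mesophyll depth layer
(Loc, 5), with the replicate leaf as the experimental unit (sections and
transects are pre-averaged upstream, which avoids pseudo-replication).

The ANOVA is the classical balanced full-factorial decomposition computed
from marginal means by inclusion–exclusion; on balanced data every
sum-of-squares type coincides, so the decomposition is exact and fast
enough for simulation-based calibration. Unbalanced tables are rejected
rather than silently fitted with a sums-of-squares choice.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PipelineError
from .profiling import LAYERS, DepthBins, ReplicateProfile

__all__ = [
    "FACTORS",
    "build_factorial_table",
    "anova_fixed",
    "LsdGrouping",
    "fisher_lsd",
    "PatternClass",
    "classify_pattern",
]

#: Default factor columns, in the order of the four-way model.
FACTORS = ("Var", "CO2", "Light", "Loc")


def build_factorial_table(profiles: list[ReplicateProfile]) -> pd.DataFrame:
    """Tidy factorial table from replicate profiles (one row per layer mean)."""
    if not profiles:
        raise PipelineError("NOTHING_TO_AGGREGATE", "no replicate profiles")
    rows = []
    for p in profiles:
        if p.meta is None:
            raise PipelineError("META_MISMATCH", "replicate profile without metadata")
        for layer, value in zip(p.bins.labels, p.bins.values):
            rows.append(
                {
                    "Var": p.meta.variety.name,
                    "CO2": p.meta.co2.name,
                    "Light": p.meta.light.name,
                    "Loc": layer,
                    "replicate": p.meta.replicate,
                    "response": float(value),
                }
            )
    return pd.DataFrame(rows)


def _term_name(subset: tuple) -> str:
    return " x ".join(subset)


def anova_fixed(
    table: pd.DataFrame,
    factors: tuple = FACTORS,
    response: str = "response",
) -> pd.DataFrame:
    """Classical fixed-effects ANOVA for a balanced full factorial.

    Returns a DataFrame with columns term/df/sum_sq/F/p and a final
    ``Residual`` row. Sum of squares for a term S is computed from cell
    means by inclusion–exclusion over the marginal means of subsets of S —
    exact for balanced data, where all sum-of-squares types coincide.

    A constant response yields F = 0, p = 1 for every term; a zero residual
    with real effects yields F = inf, p = 0.
    """
    for col in (*factors, response):
        if col not in table.columns:
            raise PipelineError("EMPTY_CELL", f"missing column {col!r}")
    y = table[response].to_numpy(dtype=float)
    if y.size == 0:
        raise PipelineError("EMPTY_CELL", "empty table")

    levels = [np.unique(table[f].to_numpy()) for f in factors]
    shape = tuple(len(lv) for lv in levels)
    codes = [
        np.searchsorted(lv, table[f].to_numpy()) for f, lv in zip(factors, levels)
    ]
    cell_index = np.ravel_multi_index(codes, shape)
    n_cells = int(np.prod(shape))
    counts = np.bincount(cell_index, minlength=n_cells)
    if counts.min() == 0:
        raise PipelineError("EMPTY_CELL", "at least one factor-level cell is empty")
    n = int(counts[0])
    if not (counts == n).all():
        raise PipelineError(
            "UNBALANCED",
            "unequal cell sizes; pre-average to the replicate level to balance the design",
        )
    if n < 2:
        raise PipelineError("NO_RESIDUAL", "need >= 2 replicates per cell")

    order = np.argsort(cell_index, kind="stable")
    arr = y[order].reshape(*shape, n)
    N = y.size
    grand = arr.mean()
    cell_means = arr.mean(axis=-1)

    k = len(factors)
    # marginal means over every subset of factors, broadcast to full shape
    marg: dict[frozenset, np.ndarray] = {}
    for r in range(k + 1):
        for subset in itertools.combinations(range(k), r):
            keep = set(subset)
            axes = tuple(i for i in range(k) if i not in keep)
            m = cell_means.mean(axis=axes, keepdims=True)
            marg[frozenset(subset)] = m

    ss_total = float(((arr - grand) ** 2).sum())
    scale = max(1.0, float(np.abs(grand)) ** 2 * N)
    constant = ss_total <= 1e-12 * scale

    rows = []
    ss_model = 0.0
    for r in range(1, k + 1):
        for subset in itertools.combinations(range(k), r):
            effect = np.zeros_like(marg[frozenset(subset)])
            for t_size in range(r + 1):
                for sub in itertools.combinations(subset, t_size):
                    effect = effect + (-1) ** (r - t_size) * marg[frozenset(sub)]
            reps = N / np.prod([shape[i] for i in subset])
            ss = float(reps * (effect**2).sum())
            df_term = int(np.prod([shape[i] - 1 for i in subset]))
            ss_model += ss
            rows.append(
                {
                    "term": _term_name(tuple(factors[i] for i in subset)),
                    "df": df_term,
                    "sum_sq": ss,
                }
            )

    ss_resid = max(ss_total - ss_model, 0.0)
    df_resid = N - n_cells
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    for row in rows:
        if constant:
            row["F"], row["p"] = 0.0, 1.0
        elif ms_resid > 0:
            f_val = (row["sum_sq"] / row["df"]) / ms_resid
            row["F"] = f_val
            row["p"] = float(sps.f.sf(f_val, row["df"], df_resid))
        else:
            # zero residual variance but non-constant response
            has_effect = row["sum_sq"] > 1e-12 * scale
            row["F"] = np.inf if has_effect else 0.0
            row["p"] = 0.0 if has_effect else 1.0
    rows.append(
        {"term": "Residual", "df": df_resid, "sum_sq": ss_resid, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows, columns=["term", "df", "sum_sq", "F", "p"])


@dataclass
class LsdGrouping:
    """Fisher's LSD letter display: means sharing a letter do not differ."""

    means: dict  # label -> mean
    letters: dict  # label -> letter string (e.g. "a", "ab")
    lsd: float
    alpha: float


def fisher_lsd(
    cell_means: dict,
    n_per_cell: int,
    ms_resid: float,
    df_resid: int,
    alpha: float = 0.05,
) -> LsdGrouping:
    """Fisher's least-significant-difference grouping at level ``alpha``.

    LSD = t(1 - alpha/2, df_resid) * sqrt(2 * MS_resid / n); letters are
    assigned by the maximal-window insertion algorithm on the sorted means,
    so two means share a letter exactly when |difference| <= LSD.
    """
    if df_resid < 1:
        raise PipelineError("NO_RESIDUAL", "df_resid must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise PipelineError("BAD_WINDOW", "alpha must be in (0, 1)")
    if n_per_cell < 1 or ms_resid < 0:
        raise PipelineError("NO_RESIDUAL", "need n >= 1 and MS_resid >= 0")
    lsd = float(sps.t.ppf(1.0 - alpha / 2.0, df_resid) * np.sqrt(2.0 * ms_resid / n_per_cell))

    labels = sorted(cell_means, key=lambda k: (cell_means[k], str(k)))
    vals = np.array([cell_means[k] for k in labels], dtype=float)
    m = len(labels)
    # maximal windows of mutually non-significant means, ascending
    windows = []
    prev_end = -1
    for i in range(m):
        j = i
        while j + 1 < m and vals[j + 1] - vals[i] <= lsd:
            j += 1
        if j > prev_end or i == 0:
            windows.append((i, j))
            prev_end = j
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {k: "" for k in labels}
    for w, (i, j) in enumerate(windows):
        letter = alphabet[w % len(alphabet)] * (w // len(alphabet) + 1)
        for k in labels[i : j + 1]:
            letters[k] += letter
    return LsdGrouping(means=dict(cell_means), letters=letters, lsd=lsd, alpha=alpha)


class PatternClass(Enum):
    """Depth-localization pattern of a replicate profile."""

    SURFACE_DOMINANT = "SURFACE_DOMINANT"
    LOWER_MESOPHYLL_DOMINANT = "LOWER_MESOPHYLL_DOMINANT"
    FLAT = "FLAT"


def classify_pattern(profile) -> PatternClass:
    """Classify a depth profile by its dominant layer.

    FLAT when the relative range (max-min)/mean is under 5%; otherwise
    surface-dominant when the maximum sits in AD or AB, and
    lower-mesophyll-dominant when it sits in LM. An MM maximum maps to
    lower-mesophyll-dominant and a UM maximum to surface-dominant, both
    with a warning (the profile peaks in an interior layer).
    """
    if isinstance(profile, ReplicateProfile):
        bins = profile.bins
    elif isinstance(profile, DepthBins):
        bins = profile
    else:
        bins = DepthBins(values=np.asarray(profile, dtype=float), n_pixels=np.zeros(len(profile), dtype=int))
    if bins.labels != LAYERS:
        raise PipelineError("SHAPE_MISMATCH", "pattern classification needs the 5 standard layers")
    v = bins.values
    mean = v.mean()
    if mean <= 0 or (v.max() - v.min()) / mean < 0.05:
        return PatternClass.FLAT
    top = bins.argmax_layer
    if top in ("AD", "AB"):
        return PatternClass.SURFACE_DOMINANT
    if top == "LM":
        return PatternClass.LOWER_MESOPHYLL_DOMINANT
    if top == "MM":
        warnings.warn("profile peaks in MM; classified as LOWER_MESOPHYLL_DOMINANT")
        return PatternClass.LOWER_MESOPHYLL_DOMINANT
    warnings.warn("profile peaks in UM; classified as SURFACE_DOMINANT")
    return PatternClass.SURFACE_DOMINANT
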