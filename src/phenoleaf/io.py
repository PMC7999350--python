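"""Image and table I/O: TIFF/PNG sections, fluorescence maps, manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import (
    CO2Level,
    FluorescenceMap,
    LightRegime,
    PipelineError,
    RgbSection,
    TreatmentLabel,
    Variety,
)
from .geometry import ExclusionMask, MesophyllSpan
from .synth import GradientSpec, SyntheticSection

__all__ = [
    "load_section",
    "save_section",
    "save_map_tiff",
    "save_map_csv",
    "save_spans_csv",
    "save_overlay_png",
    "save_truth_json",
    "load_truth_json",
    "write_manifest",
    "read_manifest",
]

MANIFEST_COLUMNS = ["path", "variety", "co2", "light", "replicate", "section", "seed"]


def load_section(
    path,
    meta: TreatmentLabel | None = None,
    adaxial_up: bool = True,
) -> RgbSection:
    """Read a TIFF or PNG micrograph as an 8-bit RGB section.

    16-bit inputs are linearly rescaled; images flagged ``adaxial_up=False``
    are flipped vertically so row 0 is always the adaxial side.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[..., :3]
    if px.ndim != 3 or px.shape[2] != 3:
        raise PipelineError("BAD_IMAGE", f"{path}: expected RGB raster, got shape {px.shape}")
    if px.dtype == np.uint16:
        px = np.round(px.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    elif px.dtype != np.uint8:
        raise PipelineError("BAD_IMAGE", f"{path}: unsupported dtype {px.dtype}")
    if not adaxial_up:
        px = px[::-1].copy()
    return RgbSection(pixels=px, meta=meta)


def save_section(path, section: RgbSection) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, section.pixels, photometric="rgb")
    else:
        iio.imwrite(path, section.pixels)


def save_map_tiff(path, fmap: FluorescenceMap) -> None:
    """Write a fluorescence map as a single-channel 16-bit TIFF."""
    data = np.round(fmap.values * 65535.0).astype(np.uint16)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def save_map_csv(path, fmap: FluorescenceMap) -> None:
    rows, cols = np.nonzero(fmap.values)
    pd.DataFrame(
        {"row": rows, "col": cols, "value": fmap.values[rows, cols]}
    ).to_csv(path, index=False)


def save_spans_csv(path, spans: list[MesophyllSpan], excl: ExclusionMask | None = None) -> None:
    excluded = excl.excluded_columns if excl is not None else frozenset()
    pd.DataFrame(
        [
            {
                "column": s.column,
                "top": s.top,
                "bottom": s.bottom,
                "valid": s.valid,
                "excluded": s.column in excluded,
            }
            for s in spans
        ]
    ).to_csv(path, index=False)


def save_overlay_png(path, section: RgbSection, columns: list[int]) -> None:
    """QC overlay: transect columns drawn in white over the section."""
    px = section.pixels.copy()
    px[:, columns, :] = 255
    iio.imwrite(Path(path), px)


def save_truth_json(path, synth: SyntheticSection) -> None:
    meta = synth.image.meta
    payload = {
        "treatment": {
            "variety": meta.variety.name,
            "co2": meta.co2.name,
            "light": meta.light.name,
            "replicate": meta.replicate,
            "section": meta.section,
        },
        "gradient": asdict(synth.truth),
        "seed": synth.seed,
        "vascular_ranges": [list(r) for r in synth.vascular_ranges],
        "midrib_cols": list(synth.midrib_cols) if synth.midrib_cols else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_truth_json(path) -> tuple[TreatmentLabel, GradientSpec]:
    with open(path) as fh:
        payload = json.load(fh)
    t = payload["treatment"]
    label = TreatmentLabel(
        variety=Variety[t["variety"]],
        co2=CO2Level[t["co2"]],
        light=LightRegime[t["light"]],
        replicate=t["replicate"],
        section=t["section"],
    )
    return label, GradientSpec(**payload["gradient"])


def write_manifest(path, records: list[dict]) -> None:
    pd.DataFrame(records, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise PipelineError("BAD_IMAGE", f"manifest missing columns {sorted(missing)}")
    base = Path(path).parent
    for _, row in df.iterrows():
        Variety[row["variety"]]
        CO2Level[row["co2"]]
        LightRegime[row["light"]]
        if not (base / row["path"]).exists():
            raise PipelineError("BAD_IMAGE", f"manifest path missing: {row['path']}")
    dup = df.duplicated(subset=["variety", "co2", "light", "replicate", "section"])
    if dup.any():
        raise PipelineError("BAD_IMAGE", "duplicate (replicate, section) within treatment")
    return df
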