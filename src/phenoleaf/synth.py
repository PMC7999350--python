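"""Synthetic half-lamina micrographs with known depth-gradient ground truth.

The generator emulates the structures the pipeline must cope with: a
half-lamina thinning from midrib to margin, chlorophyll-free epidermis with
faint blue cell walls, red chlorophyll autofluorescence throughout the
mesophyll, strongly blue vascular bundles and midrib sclerenchyma, and a
yellow PhC signal following a treatment-dependent depth gradient, degraded
by Poisson (shot) and Gaussian (read) noise.

Depth gradients come from a closed-form family

    g(d) = total_scale * [ base
                           + ad_peak * exp(-d / decay)
                           + ab_peak * exp(-(1 - d) / decay)
                           + lm_bump * exp(-(d - center)^2 / (2 width^2)) ]

on relative depth d in [0, 1] (0 = adaxial mesophyll boundary): exponential
surface peaks express the high-light / elevated-CO2 pattern (high AD,
slightly lower AB, minimum in MM), and the Gaussian bump at d ~ 0.7 the
low-light pattern with the maximum in the lower mesophyll. The family is
the simplest closed form able to express both observed patterns.

Mesophyll PhC and chlorophyll fluorescence are interleaved on a
deterministic 1-in-3 pixel lattice (sub-cellular segregation: flavonoids in
vacuoles and walls, chlorophyll in chloroplasts); the recovered intensities
therefore carry a constant 1/3 coverage factor, which cancels in every
shape- or ratio-based comparison.

The diurnal light model reproduces the cultivation regime: piecewise-linear
ramp 05:00-10:00, plateau 10:00-15:00, ramp 15:00-20:00, night value 0.
Its daily integrals reproduce the growth-chamber numbers exactly:
PAR 14.4 / 54 mol m-2 day-1 and UV-A 27 / 144 kJ m-2 day-1 for LL / HL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad

from .core import (
    CO2Level,
    LightRegime,
    PipelineError,
    RgbSection,
    TreatmentLabel,
    Variety,
)
from .profiling import LAYERS, DepthBins

__all__ = [
    "DiurnalProfile",
    "PAR_LL",
    "PAR_HL",
    "UVA_LL",
    "UVA_HL",
    "daily_integral",
    "GradientSpec",
    "GradientEffects",
    "treatment_gradient",
    "layer_truth",
    "SynthGeometry",
    "NoiseConfig",
    "SyntheticSection",
    "render_section",
    "gradient_column",
]


# ---------------------------------------------------------------------------
# Diurnal light regime


@dataclass(frozen=True)
class DiurnalProfile:
    """Piecewise-linear diurnal course of PAR or UV-A irradiance.

    ``day_max`` is in µmol m-2 s-1 for PAR and W m-2 for UV-A; the night
    value is 0 and the schedule is given in hours of day.
    """

    day_max: float
    quantity: str = "PAR"  # "PAR" or "UVA"
    ramp_up: tuple = (5.0, 10.0)
    plateau: tuple = (10.0, 15.0)
    ramp_down: tuple = (15.0, 20.0)
    night_value: float = 0.0

    def value_at(self, hour: float) -> float:
        """Irradiance at a given hour of day (for quadrature cross-checks)."""
        u0, u1 = self.ramp_up
        p0, p1 = self.plateau
        d0, d1 = self.ramp_down
        if hour < u0 or hour >= d1:
            return self.night_value
        if hour < u1:
            return self.night_value + (self.day_max - self.night_value) * (hour - u0) / (u1 - u0)
        if hour < p1:
            return self.day_max
        return self.day_max + (self.night_value - self.day_max) * (hour - d0) / (d1 - d0)


#: Cultivation profiles: low/high light PAR and UV-A maxima.
PAR_LL = DiurnalProfile(400.0, "PAR")
PAR_HL = DiurnalProfile(1500.0, "PAR")
UVA_LL = DiurnalProfile(0.75, "UVA")
UVA_HL = DiurnalProfile(4.0, "UVA")


def daily_integral(p: DiurnalProfile) -> float:
    """Exact trapezoidal daily integral of a diurnal profile.

    Returns mol m-2 day-1 for PAR (µmol -> mol) and kJ m-2 day-1 for UV-A
    (W s -> kJ).
    """
    up = p.ramp_up[1] - p.ramp_up[0]
    plateau = p.plateau[1] - p.plateau[0]
    down = p.ramp_down[1] - p.ramp_down[0]
    if up < 0 or plateau < 0 or down < 0:
        raise PipelineError("BAD_SCHEDULE", "negative phase duration")
    hours_equiv = plateau + (up + down) / 2.0
    raw = p.day_max * hours_equiv * 3600.0  # µmol m-2 (PAR) or J m-2 (UV-A)
    if p.quantity == "PAR":
        return raw * 1e-6
    if p.quantity == "UVA":
        return raw * 1e-3
    raise PipelineError("BAD_SCHEDULE", f"unknown quantity {p.quantity!r}")


# ---------------------------------------------------------------------------
# Treatment-dependent depth gradients


@dataclass(frozen=True)
class GradientSpec:
    """Closed-form ground-truth depth gradient g(d), d in [0, 1] adaxial->abaxial."""

    base: float
    ad_peak: float
    ab_peak: float
    lm_bump: float
    decay: float = 0.18
    bump_center: float = 0.7
    bump_width: float = 0.15
    total_scale: float = 1.0

    def g(self, d):
        d = np.asarray(d, dtype=float)
        shape = (
            self.base
            + self.ad_peak * np.exp(-d / self.decay)
            + self.ab_peak * np.exp(-(1.0 - d) / self.decay)
            + self.lm_bump
            * np.exp(-((d - self.bump_center) ** 2) / (2.0 * self.bump_width**2))
        )
        return self.total_scale * shape

    def __call__(self, d):
        return self.g(d)


@dataclass(frozen=True)
class GradientEffects:
    """Generator effect sizes (the study conditions, all overridable).

    ``base_total`` is the depth-integrated mean intensity of the LL-LC
    reference cell; ``hl_ll_ratio`` fixes the HL/LL total-accumulation
    ratio per CO2 level (1.46 at LC — the observed 46% high-light increase
    — converging toward 1 with rising CO2); ``ll_co2_scale`` is the CO2
    response under LL; ``bojos_ec_boost`` raises total accumulation for the
    tolerant variety under elevated CO2.
    """

    base_total: float = 0.22
    hl_ll_ratio: dict = field(
        default_factory=lambda: {CO2Level.LC: 1.46, CO2Level.AC: 1.40, CO2Level.EC: 1.25}
    )
    ll_co2_scale: dict = field(
        default_factory=lambda: {CO2Level.LC: 1.0, CO2Level.AC: 1.08, CO2Level.EC: 1.30}
    )
    bojos_ec_boost: float = 1.12
    # surface pattern (HL or EC): strong adaxial peak, slightly weaker abaxial
    surface_base: float = 0.35
    surface_ad: float = 1.0
    surface_ab: float = 0.7
    # deep pattern (LL and LC/AC): lower-mesophyll bump, small surface peaks
    deep_base: float = 0.35
    deep_ad: float = 0.15
    deep_ab: float = 0.15
    deep_bump: float = 0.9
    decay: float = 0.18


def _shape_mean(spec: GradientSpec) -> float:
    unit = replace(spec, total_scale=1.0)
    val, _ = quad(unit.g, 0.0, 1.0, epsrel=1e-10, limit=200)
    return val


def treatment_gradient(
    t: TreatmentLabel, effects: GradientEffects | None = None
) -> GradientSpec:
    """Deterministic map from a treatment to its ground-truth gradient.

    High light or elevated CO2 force the surface-dominant pattern; low
    light at low/ambient CO2 gives the lower-mesophyll-dominant pattern.
    ``total_scale`` is solved so the depth-integrated intensity equals the
    treatment's target total, which makes the HL/LL total ratio exactly the
    configured effect size.
    """
    eff = effects or GradientEffects()
    surface = t.light == LightRegime.HL or t.co2 == CO2Level.EC
    if surface:
        spec = GradientSpec(
            base=eff.surface_base,
            ad_peak=eff.surface_ad,
            ab_peak=eff.surface_ab,
            lm_bump=0.0,
            decay=eff.decay,
        )
    else:
        spec = GradientSpec(
            base=eff.deep_base,
            ad_peak=eff.deep_ad,
            ab_peak=eff.deep_ab,
            lm_bump=eff.deep_bump,
            decay=eff.decay,
        )
    total = eff.base_total * eff.ll_co2_scale[t.co2]
    if t.light == LightRegime.HL:
        total *= eff.hl_ll_ratio[t.co2]
    if t.variety == Variety.BOJOS and t.co2 == CO2Level.EC:
        total *= eff.bojos_ec_boost
    return replace(spec, total_scale=total / _shape_mean(spec))


def layer_truth(g: GradientSpec, n_bins: int = 5) -> DepthBins:
    """Analytic layer means: (1/h) * integral of g over each depth fifth."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    vals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        v, _ = quad(g.g, lo, hi, epsrel=1e-8, limit=200)
        vals.append(v / (hi - lo))
    labels = LAYERS if n_bins == 5 else tuple(f"B{i}" for i in range(n_bins))
    return DepthBins(values=np.array(vals), n_pixels=np.zeros(n_bins, dtype=int), labels=labels)


def gradient_column(g: GradientSpec, length: int) -> np.ndarray:
    """Noiseless rendering of g along one column: samples at pixel centers."""
    d = (np.arange(length) + 0.5) / length
    return g.g(d)


# ---------------------------------------------------------------------------
# Section renderer


@dataclass(frozen=True)
class SynthGeometry:
    """Geometry of the rendered half-lamina (pixels unless noted)."""

    height: int = 240
    width: int = 600
    epidermis_px: int = 6
    midrib_frac: float = 0.05  # width fraction occupied by the midrib block
    thickness_mid_frac: float = 0.80  # lamina thickness at the midrib side
    thickness_margin_frac: float = 0.50  # lamina thickness at the margin
    n_bundles_range: tuple = (2, 4)
    bundle_width_px: int = 12
    bundle_depth_frac: float = 0.5  # mesophyll fraction occupied by a bundle
    chlorophyll_level: float = 0.55
    epidermis_blue: float = 0.18
    bundle_blue: float = 0.85
    midrib_blue: float = 0.70
    phc_lattice_mod: int = 3  # 1-in-k mesophyll pixels carry the PhC signal


@dataclass(frozen=True)
class NoiseConfig:
    """Signal-dependent shot noise plus additive read noise (0 disables)."""

    full_well: float = 500.0  # counts at intensity 1.0; 0 disables Poisson
    read_sd: float = 2.0 / 255.0  # Gaussian sd in intensity units


@dataclass
class SyntheticSection:
    """A rendered section plus its full ground truth."""

    image: RgbSection
    truth: GradientSpec
    meso_top: np.ndarray  # per-column adaxial mesophyll boundary row
    meso_bottom: np.ndarray  # per-column abaxial mesophyll boundary row
    lamina_top: np.ndarray
    lamina_bottom: np.ndarray
    vascular_ranges: list  # [(col_start, col_stop_inclusive), ...]
    midrib_cols: tuple | None
    seed: int


def render_section(
    t: TreatmentLabel,
    geometry: SynthGeometry | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    effects: GradientEffects | None = None,
) -> SyntheticSection:
    """Render one synthetic half-lamina cross-section, adaxial side up.

    Background is 0; epidermis bands carry faint blue cell-wall signal and
    no chlorophyll; the mesophyll interleaves red chlorophyll with yellow
    PhC pixels following the treatment gradient along each column's
    relative depth; vascular bundles (and an optional midrib block at the
    left edge) are strongly blue. Same seed, same treatment -> identical
    image.
    """
    geo = geometry or SynthGeometry()
    noise = noise or NoiseConfig()
    if geo.height < 60 or geo.width < 200:
        raise PipelineError("GEOMETRY_TOO_SMALL", f"{geo.height}x{geo.width} (need >= 60x200)")
    rng = np.random.default_rng(seed)
    H, W = geo.height, geo.width
    spec = treatment_gradient(t, effects)

    # lamina envelope: linear thinning from midrib to margin, centered rows
    x = np.arange(W)
    thickness = np.round(
        H * (geo.thickness_mid_frac + (geo.thickness_margin_frac - geo.thickness_mid_frac) * x / (W - 1))
    ).astype(int)
    lam_top = (H - thickness) // 2
    lam_bot = lam_top + thickness - 1
    meso_top = lam_top + geo.epidermis_px
    meso_bot = lam_bot - geo.epidermis_px
    if np.any(meso_bot - meso_top + 1 < 10):
        raise PipelineError("GEOMETRY_TOO_SMALL", "mesophyll thinner than 10 px")

    midrib_w = int(round(geo.midrib_frac * W))
    midrib_cols = (0, midrib_w - 1) if midrib_w > 0 else None

    # vascular bundles: non-overlapping column groups clear of midrib/margin
    lo, hi = geo.n_bundles_range
    n_bundles = int(rng.integers(lo, hi + 1))
    bundle_ranges: list[tuple[int, int]] = []
    min_start = midrib_w + 2 * geo.bundle_width_px
    max_start = W - 3 * geo.bundle_width_px
    for _ in range(200):
        if len(bundle_ranges) == n_bundles:
            break
        c0 = int(rng.integers(min_start, max_start))
        c1 = c0 + geo.bundle_width_px - 1
        if all(c1 < b0 - geo.bundle_width_px or c0 > b1 + geo.bundle_width_px for b0, b1 in bundle_ranges):
            bundle_ranges.append((c0, c1))
    bundle_ranges.sort()

    r = np.zeros((H, W))
    g_ch = np.zeros((H, W))
    b = np.zeros((H, W))
    rows = np.arange(H)
    in_bundle_col = np.zeros(W, dtype=bool)
    for c0, c1 in bundle_ranges:
        in_bundle_col[c0 : c1 + 1] = True

    for col in range(W):
        lt, lb = lam_top[col], lam_bot[col]
        mt, mb = meso_top[col], meso_bot[col]
        # epidermis: faint blue cell walls, no chlorophyll, no PhC
        b[lt:mt, col] = geo.epidermis_blue
        b[mb + 1 : lb + 1, col] = geo.epidermis_blue
        meso_rows = rows[mt : mb + 1]
        mlen = meso_rows.size
        d = (meso_rows - mt + 0.5) / mlen
        phc_val = spec.g(d)
        yellow = (meso_rows + col) % geo.phc_lattice_mod == 0
        if in_bundle_col[col]:
            # bundle occupies the central mesophyll fraction; strong blue
            # interleaved with bundle-sheath chlorophyll so the chlorophyll
            # span still covers the bundle
            half = geo.bundle_depth_frac / 2.0
            in_bundle_row = np.abs(d - 0.5) <= half
            blue_px = in_bundle_row & ((meso_rows + col) % 2 == 0)
            red_px = ~blue_px
            b[meso_rows[blue_px], col] = geo.bundle_blue
            r[meso_rows[red_px], col] = geo.chlorophyll_level
        else:
            r[meso_rows[~yellow], col] = geo.chlorophyll_level
            ys = meso_rows[yellow]
            r[ys, col] = phc_val[yellow]
            g_ch[ys, col] = phc_val[yellow]

    if midrib_cols is not None:
        c0, c1 = midrib_cols
        for col in range(c0, c1 + 1):
            lt, lb = lam_top[col], lam_bot[col]
            r[lt : lb + 1, col] = 0.0
            g_ch[lt : lb + 1, col] = 0.0
            b[lt : lb + 1, col] = geo.midrib_blue

    img = np.stack([r, g_ch, b], axis=-1)
    if noise.full_well and noise.full_well > 0:
        img = rng.poisson(img * noise.full_well) / noise.full_well
    if noise.read_sd and noise.read_sd > 0:
        img = img + rng.normal(0.0, noise.read_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    pixels = np.round(img * 255.0).astype(np.uint8)

    return SyntheticSection(
        image=RgbSection(pixels=pixels, meta=t),
        truth=spec,
        meso_top=meso_top,
        meso_bottom=meso_bot,
        lamina_top=lam_top,
        lamina_bottom=lam_bot,
        vascular_ranges=bundle_ranges,
        midrib_cols=midrib_cols,
        seed=seed,
    )
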