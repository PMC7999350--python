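# Methods

This note records the models, parameter choices, and numerical conventions
behind `phenoleaf`, and what the synthetic validation does and does not
demonstrate about real micrographs.

## Spectral separation

The three fluorescence colors of a Naturstoff-reagent-treated section under
blue-light excitation are separated in HSV space. Hue is the axis that
distinguishes the colors; the intensity read-out is the HSV **value**
channel (max of R, G, B scaled to [0, 1]), chosen over the channel mean so
that pure-color identities are exact (a saturated yellow pixel reads 1.0).

Default windows (degrees; saturation ≥ 0.2, value ≥ 0.04 for all):

| channel | hue window |
|---|---|
| PhC yellow | 30–90 |
| chlorophyll red | 330–360 ∪ 0–30 (two explicit sub-windows) |
| wall/vascular blue | 190–270 |

The original workflow's editor macro published no thresholds, so these four
numbers are design choices, all exposed in the config. The red wrap-around
is handled by two sub-windows rather than modular arithmetic so every
window keeps the simple `low < high` invariant. Window bounds are
inclusive; the yellow/red boundary at exactly 30° is therefore shared, a
measure-zero convention that never matters for 8-bit data off the boundary.
The saturation and value floors suppress near-gray noise and background;
whether the original macro thresholded on brightness at all is unknowable,
so `val_min = 0.04` is our (overridable) choice. 16-bit inputs are linearly
rescaled on load; images flagged abaxial-up are flipped so row 0 is always
adaxial.

## Leaf geometry

Tissue is whatever exceeds a value-channel background threshold (default
0.02), reduced to the single largest 8-connected component and closed with
a 3×3 element. The mesophyll span of a column is the longest
chlorophyll-positive vertical run — epidermis excludes itself because
epidermal pavement cells carry no chlorophyll, which is robust to
magnification, unlike fixed pixel offsets. Gaps up to 2 px are bridged
(intercellular air spaces and interleaved non-red pixels); runs under 5 px
are invalid (degenerate margins). Columns whose span blue-fraction exceeds
0.15 are excluded as vascular, dilated by 3 columns each side; invalid
columns are excluded undilated (dilating around the thin margin would eat
usable columns). The midrib needs no separate detector: its sclerenchyma is
blue-dominant and chlorophyll-free, so its columns are invalid/excluded by
construction.

## Depth profiling

Transects are vertical pixel columns (no sub-pixel lines or cycloids). The
usable width W is the valid-column extent trimmed by `edge_margin_frac`
(default 0.03) per side; the stride is s = W/n and **one** offset
u ~ U[0, s) is shared by all n lines per section — that sharing is what
makes the design systematic uniform random sampling. Nominal columns are
`floor(u + k·s)` from the midrib side; the floor rule gives every usable
column inclusion probability exactly 1/s (the strata [k·s, (k+1)·s)
partition the window), so the estimator is exactly unbiased — a round-half
rule would under-cover the edge columns. An excluded nominal column moves
to the nearest allowed column, ties toward the midrib; relocation is the
one approximation to unbiasedness and is exact when nothing is excluded.

Binning uses the relative-depth midpoint rule `bin(i) = floor(5(i+0.5)/L)`:
it is symmetric under adaxial/abaxial flip, and no two bins ever differ by
more than one pixel in count. For transects shorter than the bin count the
empty bins copy the nearest non-empty bin (ties toward the adaxial side)
with a pixel count of zero. Aggregation over transects and sections is an
unweighted mean; the leaf thins toward the margin, so weighting by transect
length would change results — unweighted matches the upstream protocol,
which states no weighting.

## Synthetic sections

The generator is the validation instrument, so its defaults *are* the study
conditions:

* geometry: 240 × 600 px, lamina thinning linearly from 80 % to 50 % of
  image height, 6 px epidermis bands, a midrib block on the left 5 % of
  columns, 2–4 vascular bundles of 12 px width occupying the central half
  of the mesophyll;
* gradient family `g(d) = c·[base + a·e^(−d/λ) + b·e^(−(1−d)/λ) +
  m·e^(−(d−0.7)²/(2·0.15²))]` with λ = 0.18; surface pattern
  (base 0.35, a 1.0, b 0.7, m 0) for high light or elevated CO₂, deep
  pattern (base 0.35, a = b = 0.15, m 0.9) for low light at low/ambient
  CO₂. The family is the simplest closed form able to express both
  observed patterns;
* effect sizes: the scale c is solved so the depth-integrated total equals
  the treatment target — low-light totals 0.22 / ×1.08 / ×1.30 at
  LC/AC/EC, and high-light/low-light total ratios 1.46 / 1.40 / 1.25 at
  LC/AC/EC. The 1.46 at low CO₂ is the observed 46 % high-light increase;
  the convergence toward 1 with rising CO₂ reflects elevated CO₂ partly
  replacing high light. Fixing the *integral* rather than a raw shape
  multiplier is deliberate: the two light regimes have different gradient
  shapes, so only the integral makes "46 % more accumulation" well defined.
  The magnitude of the elevated-CO₂ boost under low light (1.30) and the
  Bojos-under-EC boost (1.12) are qualitative observations given default
  numbers here, not measured values;
* mesophyll texture: PhC (yellow) and chlorophyll (red) pixels interleave
  on a deterministic 1-in-3 lattice, emulating sub-cellular segregation
  (vacuoles/walls vs chloroplasts). Additive color mixing would shift hue
  out of the yellow window and corrupt the value read-out, which is exactly
  why the original workflow removed chlorophyll first. The lattice imposes
  a constant 1/3 coverage factor on recovered intensities that cancels in
  every shape- and ratio-based comparison. Bundles interleave blue with
  bundle-sheath chlorophyll 1-in-2 so the chlorophyll span still covers
  them while their blue span-fraction (0.25) clears the 0.15 exclusion
  threshold;
* noise: per-channel Poisson at a 500-count full well followed by Gaussian
  read noise of sd 2/255, then clipping to [0, 1] and 8-bit quantization.

The diurnal model ramps linearly 05:00–10:00, holds 10:00–15:00, ramps down
15:00–20:00, with night values taken as exactly 0 (the protocol gives no
night number; zero reproduces the printed integrals exactly). The daily
integral has the closed form `day_max × (plateau + (ramp_up+ramp_down)/2)`,
which equals trapezoidal quadrature of the piecewise-linear course to
machine precision. UV-A integrals are reported in kJ m⁻² day⁻¹: the
cultivation protocol these regimes reproduce states daily UV-A integrals of
27 and 144 in J m⁻² day⁻¹, which is inconsistent with its own W m⁻² maxima
by a factor of 1000, so the implementation reports the dimensionally
consistent kilojoule values (27 and 144 kJ).

### What the synthetic validation shows — and what it does not

Passing recovery tests shows the pipeline correctly inverts its own image
model: hue-separable fluorophores, vertical mesophyll, linear thinning,
shot+read noise. Real micrographs additionally have depth-dependent
excitation attenuation (the sieve effect), uneven illumination and
staining, curved laminae, and out-of-focus light; none of these is
simulated, so ground-truth recovery here validates the *computational*
chain, not the optics. Intensities are arbitrary "pixel brightness" units
with no absolute calibration, as in the source protocol. Clipping at
intensity 1 slightly shaves the brightest (high-light, adaxial) pixels,
which is why the recovered high-light increase sits ~2–3 points below the
injected 46 %.

## Statistics

The ANOVA is the classical balanced full-factorial fixed-effects
decomposition, computed natively from marginal means by
inclusion–exclusion; for balanced data all sum-of-squares types coincide,
so the result is exact and ~50× faster than a formula/OLS route — which
matters because the calibration properties refit the model ~1500 times.
The OLS route (statsmodels `anova_lm`) remains in the test suite as an
independent oracle. Unbalanced tables are rejected with a hint to
pre-average rather than silently fitted with a Type-I/III choice; the
intended design is balanced because ANOVA runs on replicate-level means
only (sections and transects pre-averaged), which avoids
pseudo-replication. A constant response returns F = 0, p = 1 for every
term; a zero-residual table with real effects returns F = ∞, p = 0.

Fisher's LSD uses `t(1−α/2, df_resid)·sqrt(2·MS_resid/n)` with letters from
the maximal-window insertion algorithm on the sorted means, so two means
share a letter exactly when their difference is within the LSD. No
multiplicity correction beyond LSD is applied (matching the upstream
protocol); the reports say so. The letter grouping can be computed within
each variety or across both (`stats.lsd_grouping`), since published
analyses do both depending on the figure.

The pattern classifier calls a profile FLAT below a 5 % relative range,
surface-dominant when the maximum is in AD or AB, lower-mesophyll-dominant
when in LM. Interior maxima are mapped to the nearest class with a warning
(MM → lower-mesophyll-dominant, UM → surface-dominant); the 5 % floor and
the warnings exist because a noisy near-flat profile has an arbitrary
argmax.

## Problem sizes and determinism

Defaults: 240×600 px sections, 5 transects × 3 sections × 6 replicates ×
12 treatment cells (216 images) for a full simulated experiment; the
acceptance script uses 3 sections per cell for recovery, 1000 Monte-Carlo
offsets for the unbiasedness check, and 1000/500 simulation replicates for
type-I error/power — sizes at which every Monte-Carlo criterion has
comfortable margin. All randomness flows from one seed; per-image sub-seeds
are SHA-256 hashes of the seed and the image id, so adding images never
perturbs existing ones, and every CLI command is bit-reproducible given
(config, seed).

## Known limitations

* No optical simulation (excitation penetration, sieve effect), no
  flat-field or illumination correction, no z-stacks.
* No cell-level segmentation; stomata, trichomes and bulliform cells are
  neither rendered nor detected.
* Transect positions along the midrib–margin axis are recorded but not
  modelled.
* The hue-window operator assumes fluorophores separate in hue; strongly
  overlapping emission would require true spectral unmixing, which is out
  of scope.
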