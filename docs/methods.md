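# Methods

This note documents the models, conventions and numerical choices behind
`fric`, in the spirit of a methods supplement: what each step assumes,
which defaults matter, what the synthetic generator does and does not
emulate, and where genuinely open design decisions were resolved.

## Ratiometric model

Two channels are assumed to image the same optical section of the same
nucleus: a euchromatin-preferring histone marker (H3.3) and a
total-chromatin marker (H2B).  Within a nucleus mask M, each channel is
divided by its in-mask mean, and the ratio

r(x) = ê(x) / t̂(x),  ê = e/⟨e⟩_M,  t̂ = t/⟨t⟩_M

is unit-centred by construction: r > 1 means locally more euchromatin
marker than the nucleus-wide average mixture, r < 1 less.  This makes r
invariant to per-channel gain, laser power and expression level, and it
is the reason the method measures *relative redistribution* of chromatin
states only — a global gain or loss of euchromatin that preserves its
spatial pattern is invisible by design.

The normalization phrase "by mean and variation" admits two readings.
The primary mode divides by the mean only, which keeps r = 1 as the
no-enrichment baseline used throughout the analysis.  A studentized mode
((x − mean)/sd, re-centred at 1 so the unit-mean invariant holds) is
available via `normalization_mode: studentized`; all defaults and all
validated properties use the primary mode.  A constant channel is legal
in the primary mode (it normalizes to exactly 1) and rejected in the
studentized mode, where the z-score is undefined.

Pixels whose normalized denominator falls at or below `ratio_epsilon`
(default 1e-6, i.e. only true zero-signal pixels) are excluded and
counted; more than 10% of a mask excluded is treated as a degenerate
nucleus and is an error rather than a silently thin profile.

## Segmentation

Nuclei are segmented on the total-chromatin channel — H2B labels all
chromatin and gives the most complete outline.  The channel is smoothed
with a Gaussian whose *size* parameter (default 5 px) is a feature
diameter in the CellProfiler sense; the sigma actually applied is
size/2.35 (FWHM conversion), overridable via `smoothing_sigma`.  The
global threshold is Otsu's method (it maximizes between-class variance;
note that between well-separated modes the objective is nearly flat, so
any threshold inside the gap is equivalent).  Connected components use
8-connectivity; holes (nucleoli) are filled before measurement so that
the radial zones cover the full nuclear disc — whether the original
protocol filled holes is not documented, and this is a convention, not a
reproduced fact.  Objects are kept when the equivalent circular diameter
2·sqrt(area/π) exceeds `min_diameter` (50 px) and no pixel touches the
image border.  In z-stacks each nucleus is tracked by centroid-in-mask
overlap (nuclei are static within an acquisition) and analysed at its
largest-area (equatorial) section, ties resolved to the lower slice.
Touching-nucleus declumping is deliberately out of scope; fields should
be sparse enough that nuclei are separable by thresholding.

## Zonation

The Euclidean distance transform d(x) against the mask complement is
computed after hole filling.  Equal-width mode assigns
zone(x) = ceil(n·d(x)/max d), clipped to [1, n]: boundary-adjacent
pixels land in zone 1 and the deepest pixel in zone n (half-open bins
with a closed top bin, so the partition is exact).  Using the per-nucleus
maximum distance as "the radius" keeps the construction well defined for
elliptical and irregular nuclei.  Equal-area mode places the bin edges at
quantiles of the empirical distribution of d, balancing pixel counts to
within discretization.  Inner zones necessarily contain few pixels;
zones under 5 pixels are reported but listed as low-confidence, and
empty zones are NaN (missing), never zero.

The relative ratio P/I divides the pooled peripheral mean (zones 1–3) by
the pooled interior mean (zones 4–n).  *Pooled* means pixel-weighted:
zone means are combined with their pixel counts, equivalent to averaging
all peripheral (interior) pixels directly.  The alternative —
averaging zone means unweighted — over-weights the sparse innermost
zones and is available as `pi_pooling: zone_means` for strict
figure-style emulation; which variant the original used is not
determinable, so the pixel-weighted one is declared primary here.

## Texture

Structural organization is measured as the Haralick variance of an
8-level gray-level co-occurrence matrix: the region (by default the
inverse ratio H2B/H3.3, which weights heterochromatin) is min–max
quantized to 8 levels *within the region*, pair counts are accumulated at
the four unit offsets (E, S, SE, SW — with symmetrization this covers
all 8 neighbours), and the variance of the level index under the
normalized pair distribution is returned.  "An 8 × 8 co-occurrence
matrix" is read as matrix dimensions (8 gray levels), the standard
texture-analysis default, not an 8 × 8 pixel window.  Pairs crossing the
region boundary are excluded, so the peripheral measurement (the 10
outermost zones) is independent of the interior.  Because quantization is
min–max within the region, the statistic is invariant to additive offsets
and to pure amplitude rescaling; it responds to the *shape* of the
intensity distribution and is 0 exactly when the quantized region is
constant.  The wording "10 outermost zones" versus "10 most peripheral
pixels" is contradictory in the source description; the zone reading is
adopted as it matches the zone framework (`texture_region: pixels`
switches to a fixed pixel depth).

## Quality control

Three per-batch rules, mirroring the published outlier screen (there a
manual removal; here automatic, with `--keep-flagged` to retain
annotated):

* **Blur**: the slope of log10(radially averaged power spectral density)
  versus log10(spatial frequency), fitted between DC and Nyquist with
  the DC-adjacent and single highest-frequency bins excluded (both are
  estimation-noisy).  Blur removes high frequencies and makes the slope
  more negative; an image deviating more than 2 SD from the batch mean
  slope is flagged.  The rule needs a batch of at least 2 (it is skipped
  with a warning otherwise).
* **Saturation**: more than 0.2% of object pixels at the detector
  maximum (percent at zero is reported alongside).
* **Signal-to-noise**: an Otsu threshold, on intensity normalized to
  [0, 1] by the detector maximum, more than 0.15 above the batch
  *median* threshold.  The original states one scalar with no scale or
  reference; normalized intensity and the batch median are declared
  defaults, both configurable, not inferred facts.

## Group statistics

The nucleus is the unit of analysis, pooled across experimental repeats.
Zones are compared with the unpaired pooled-variance Student t-test
("assuming a consistent standard deviation" is the pooled assumption),
two-sided, df = n1 + n2 − 2.  No multiple-testing correction is applied
across the 40 zones, matching the reporting convention of per-zone
significance plus the run length of consecutively significant peripheral
zones; a Holm switch exists but is off by default.  The star rule is
printed in its source with ">" where the conventional reading requires
"<"; the interval interpretation (ns > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥
*** > 0.0001 ≥ ****) corrects that apparent typo and is applied
consistently.  Degenerate zones (fewer than two finite values in either
group) yield NaN statistics and are never significant.  Time-lapse series
report the zone-1 mean ± SEM trajectory per group and a final-time
two-group comparison.

One statistical consequence of per-nucleus normalization deserves note:
because each nucleus's mean ratio is fixed at 1, a genuine peripheral
deficit mechanically raises interior zone means slightly.  At large
sample sizes interior zones can therefore reach significance with small
effect sizes and opposite sign.  The peripheral run from zone 1 carries
the signal of interest; interior stars should be interpreted with this
coupling in mind.

## Synthetic generator

`SyntheticParams` defaults define the reference conditions: 256×256
frames at 0.0891 µm/px, one elliptical nucleus of radius 60–75 px
(≈ 6 µm), axis ratio up to 1.3, random orientation.  The total channel
is base intensity 1500 counts on a 12-bit detector (background offset
20), modulated by a stationary multiplicative texture (Gaussian-filtered
white noise, correlation length 3 px, relative amplitude 0.30).  The
euchromatin channel is the total channel times a radial modulation
g(depth): 1 in the interior and 1 − δ over an outer band (step, default
band = 3 of 40 zones) or a logistic transition.  The nuclear envelope is
imaged through a Gaussian point-spread function of sigma 1.2 px (≈ 250 nm
FWHM at this pixel size) applied to the *edge profile before* the radial
modulation, so the channel ratio at the soft edge preserves the local g
value instead of collapsing to the background ratio — without this the
segmented rim contaminates zone 1 with background-ratio pixels, an
artifact real diffraction-limited images do not show.  Poisson shot
noise, Gaussian read noise (sd 10), optional defect blur and forced
saturation, clipping at 4095 and integer rounding complete the camera
model; `quantize: false` keeps ideal float images for exactness tests.
The shot-noise-limited SNR at defaults is ≈ 38.

Ground truth (mask, zone map, g field, per-zone g means, pixel-pooled
P/I) is recorded pre-noise; with the step profile the true P/I is
exactly 1 − δ.

What the generator does **not** emulate: chromatin domains and
chromocenters (the texture is shared between channels, so it cancels in
the ratio — the ratio field of a synthetic nucleus carries no intrinsic
structure beyond g plus noise, and texture-variance comparisons between
biological conditions are therefore not exercised end-to-end, only the
texture statistic itself); nucleoli; cell-cycle variation; multiple or
touching nuclei per field; z-stacks with realistic axial blur.  Passing
tests demonstrate correctness of the measurement chain under a known
radial model, not biological realism.

## Measured accuracy and problem sizes

With defaults (δ = 0.2 over the outer 3 of 40 zones, SNR ≈ 38), the
full pipeline recovers a cohort-mean P/I of ≈ 0.833 against the true
0.80.  The ≈ +0.03 bias decomposes into ≈ +0.02 from Otsu placing the
mask boundary ~0.5–1 px inside the true edge (which shifts the thin
peripheral band's zones slightly inward) and ≈ +0.01 from the background
offset and edge partial-volume pixels; it is a property of threshold
segmentation shared with the original pipeline, not of the zonation
arithmetic, and lies within the ±0.05 recovery tolerance the test suite
enforces.  The validation suite uses 50 + 50 nuclei at full frame size
for parameter recovery; 50 null cohorts of 8 + 8 nuclei at 160×160
(radius 46–56 px) for the 2000-zone-test type-I calibration; and 100
batches of 8 clean + 2 degraded images at 128×128 for quality-control
discrimination — sizes chosen so the whole suite validates every claim
in minutes on one CPU while keeping every per-test sample size large
enough for the stated tolerances.

## Known limitations

* 2-D only: analysis is restricted to single equatorial sections;
  grazing sections are uninformative for radial zonation and volumetric
  (3-D) zonation is out of scope.
* The ratio is relative within each nucleus; absolute chromatin-state
  quantification and global-state shifts are out of scope by design.
* Otsu segmentation assumes sparse, well-separated nuclei on a dark
  background; clumped fields need upstream declumping.
* The saturation metric needs the true detector maximum; for
  floating-point input it must be supplied (`bit_depth_max`), as it
  cannot be inferred.
* Colocalization significance (e.g. Costes randomization) is not
  implemented; coefficients are reported descriptively.
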