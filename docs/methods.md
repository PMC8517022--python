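# Methods

This note documents the models and procedures `bloomsat` implements, the
assumptions behind them, the synthetic study conditions, and the numerical
choices made where the design was genuinely open. It states no result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Radiometry and tiling

Input scenes are 4-band (red 665 nm, green 560 nm, blue 490 nm, NIR
842 nm) top-of-atmosphere reflectances coded as integers 0–10000. They are
converted to 8 bits (0–254) as `floor(min(2540, v) / 10)` for the visible
bands and `floor(min(2540, v / 3.937) / 10)` for NIR; 3.937 = 10000/2540
compresses the full NIR range, whose vegetation values routinely exceed
2540, into the visible bands' clip range. "Converted to integer" is read
as `floor`, the common cast semantics consistent with the 0–254 ceiling.

Scene selection keeps images with < 80% cloud cover, tightened to < 25%
outside the flowering season (default flowering months December–June; both
thresholds and the month set are parameters).

Scenes are padded with nodata zeros to the next multiple of the 128-pixel
analysis cell (1.28 km at 10 m/px) and cut into 136 × 136 patches: a
128-pixel core plus a 4-pixel context margin that absorbs convolutional
border effects. Windows are 0-based and half-open; the raster origin is
top-left. Patch cores tile the padded scene exactly once, and
`reassemble_patches` inverts the tiling bit-exactly (a tested round trip).
Labels and mapped cells refer to the core only.

## 2. Patch detector

The classifier is a VGG-style encoder: `n_blocks` (default 5) blocks of
3 × 3 same-padding convolution + ReLU + 2 × 2 max-pool, with filter counts
doubling per block from a configurable base (default 16), one dense layer
(default 100 units), dropout after it (default rate 0.5, placed after the
dense layer only), and a 2-unit softmax. The implementation is a compact
single-threaded NumPy conv-net (im2col convolutions, inverted dropout,
RMSprop with rho 0.9 and epsilon 1e-7), which makes training exactly
reproducible under a fixed seed — a property the test suite asserts.

Training: 80/20 train/validation split (seeded), flip-only augmentation
(horizontal and vertical, each with probability 0.5 — atmosphere and
illumination provide the rest of the variation in real imagery),
cross-entropy with class weights {background: 1, bloom:
n_background/n_bloom}; the weights enter both the loss (the standard
imbalance remedy; can be disabled) and the accuracy metric. The model kept
is the epoch snapshot with the highest weighted validation accuracy.
Decision rule: presence iff P(bloom) ≥ 0.5, ties to presence (argmax of a
2-class softmax). Default epochs are desk-scale (≤ 50).

A deterministic color-rule detector serves as a test oracle: presence iff
the patch core contains a 4-connected clump of ≥ `min_clump` (default 9)
pixels with red > green + δ and blue > green + δ (default δ = 10 in 8-bit
units). The blue condition is what rejects pink-soil confounders (red
above green, blue below).

## 3. Observation states and frequency maps

Per 1280 m cell and day: `detected`, `clear`, `cloud` or `missing`. A cell
counts as cloud when > 50% of its source pixels are cloud-masked (the
per-cell rule is not dictated by the data conventions; majority is the
neutral choice and the threshold is a parameter). Cloud overrides a
positive detection, so cloud-artifact positives are not counted; same-day
duplicate scenes from overlapping orbits merge by OR on detection and AND
on cloud (an observation in either replicate is real). Detection frequency
is 100 · detected / (detected + clear); pixels with fewer than 4
detections over the whole span are reported as 0%, and pixels never
observed cloud-free are undefined and excluded from summary statistics.
Descriptive percentile summaries default to the (2.75, 97.5) bounds used
for reporting; both are parameters.

## 4. Flowering seasonality

**Monthly normalization.** Detections per calendar month divided by
cloud-free observations per month, pooled across years (flowering dates
are assumed stable between years; with a ~5-day revisit there are too few
observations to fit each year separately).

**Cleaning and weighting**, in order: pixels with fewer than 4 detections
over the span are excluded; a positive month backed by ≤ 2 detections
whose two calendar neighbours (circularly) have zero detections is reset
to 0 (isolated false positives); values are multiplied by 10; the months
immediately before and after each contiguous run of positive months are
set to −0.15 × the maximum of the scaled series (blooming is assumed to
start and stop within those shoulder months, so the curve is forced below
zero there); weights are 0 for zero months, 1 for shoulder months, and the
scaled value itself for positive months (the weight rule does not say
scaled or unscaled; weights only act relatively, so the scaled value is
used); finally the 12-month cycle and its weights are replicated three
times (t = 1…36). With the exact linear solver below the replication is
mathematically redundant, but it is kept for fidelity to the procedure the
series is meant to follow.

**Fit.** The three-harmonic model is linear in disguise:
`pow0·p_k·sin(ωt + ρ_k) = a_k·sin(ωt) + b_k·cos(ωt)`. The weighted
least-squares problem is therefore solved exactly in the basis {1, sin,
cos at periods 4, 6, 12 months} and the constrained parameterization is
recovered as `A_k = hypot(a_k, b_k)`, `ρ_k = atan2(b_k, a_k)`,
`pow0 = ΣA_k`, `p_k = A_k/pow0`. The simplex constraint `Σp_k = 1` and
`p_k ≥ 0` hold by construction; the fit is deterministic and global, with
no iterative optimizer and no initialization sensitivity. When fewer
points carry positive weight than there are coefficients, the
minimum-norm solution is taken (NumPy `lstsq`), a deterministic
tie-break. Degenerate constant series give `pow0 = 0`, phases 0,
`p12 = 1` by convention, and weighted R² = 1 (a constant is explained
exactly). Weighted R² is computed on the positively weighted points.

**Daily reconstruction.** The fitted curve is evaluated at
`t(d) = 12·(d − 0.5)/365 + 0.5` for d = 1…365, which places month centers
at integer t; the same uniform mapping defines the month of a day.
Negative predictions are clamped to 0 and all days of zero-weight months
are set to 0. The year is treated as circular everywhere; events may
straddle December–January.

**Event extraction.** Peaks are circular local maxima with positive
value; each event's start and end are the nearest preceding and following
pit (circular local minimum) or zero day, and plateau maxima report their
first day. When the fit is available, peak *candidates* are taken from
the smooth fitted curve itself — which can have at most three maxima per
year — and kept only where the processed series is positive. Clamping and
month-zeroing can clip a curve lobe into spurious extra maxima of the
processed series; anchoring candidates on the curve suppresses exactly
those artifacts and nothing else (boundaries still come from the
processed series). Without a fit the extractor operates on the processed
series alone.

## 5. Clustering and association

One feature row per event (two-peak pixels contribute two rows): start,
peak and end day-of-year (used linearly, not circularly; a circular
encoding exists but is off by default), the bloom values at those days,
and the metric xy coordinates divided by 100,000 and rounded to the
nearest unit — down-weighting location so clusters are not driven by
distance alone. Rounding precedes standardization. All features are
centered and scaled; constant columns are dropped to zero rather than
producing NaNs. K-means (Lloyd, squared Euclidean, 10 seeded restarts,
300 iterations) runs for k = 1…k_max; when k is not given, the largest k
whose relative within-SS improvement over k−1 exceeds 2% is chosen
(favouring the maximum number of clusters the curve supports), and k is
always user-overridable. Cluster summaries report size, share and both
the mean and the mode of member peak days.

Association: each covariate raster (block-averaged to the analysis grid,
NaN-aware) is cut into 10 quantile classes over the domain; the observed
per-class counts of the N presence pixels are compared with B = 100
replicates of N uniform random domain locations (drawn with replacement,
the bootstrap convention). A class is significant at the 5% level when the
observed count falls strictly outside the empirical (0.025, 0.975)
interval. The interval bounds are order statistics rounded *outward*
(lower bound at `method="lower"`, upper at `"higher"`): with B = 100,
interpolating between order statistics yields an anti-conservative
interval (measured null rejection ≈ 6.7%), whereas the outward-rounded
interval calibrates at the nominal 5% — the choice is an estimator
convention fixed by that calibration requirement, which the acceptance
suite re-measures. `proportion_pct = 100·observed/(observed + null_mean)`
is provided as a plotting-friendly transform; 50% marks agreement with
the null. The null ignores spatial autocorrelation; see Limitations.

## 6. Synthetic worlds: what they emulate, and what not

The generator draws, from one explicit seed: six smooth covariate fields
(elevation in m, slope in degrees, tree cover %, precipitation mm/yr, and
min/max temperatures in °C, the temperatures anti-correlated with
elevation); presence as Bernoulli draws whose probability is the
configured `background_fraction` warped through a logistic link on
standardized covariates (zero coefficients leave it exactly at
`background_fraction`); and per-pixel phenology by assigning presence
pixels to populations through spatial Gaussian membership kernels, so
flowering timing is spatially clumped. A configurable fraction of pixels
joins a second population and carries two truth rows. With no populations
configured nothing can bloom and presence is empty.

The truth bloom-intensity curve is `amplitude · exp(−Δ²/2σ²)` with
σ = duration/4, truncated at 2σ (so the support is exactly
[peak − duration/2, peak + duration/2]) and wrapped across the year
boundary. Rendering places a deterministic stand disc inside each
presence cell and adds `(green_excess + contrast·(1 + I))` to red and
blue inside it, so whenever intensity is positive both bands exceed green
by at least the configured contrast — which is what makes the color-rule
inverse check exact on noiseless scenes — while the offset still grows
with intensity. NIR dips slightly under bloom. Clouds are drawn per cell,
rendered bright in all bands and flagged in the mask; pink-soil squares
are optional confounders.

The shortcut observation simulator bypasses imagery: above a visibility
threshold a bloom is detected with probability `p_detect · intensity`,
i.e. `p_detect` is the detection probability of a stand at full bloom and
detectability ramps with the bloom. The graded form matters: a flat
detection probability produces plateau-then-cliff monthly series whose
exact harmonic interpolant oscillates wildly between month centers,
which no cleaning rule repairs — and graded ramps are what real monthly
detection-frequency series look like. Scene-based detection through the
classifier, by contrast, is binary per scene; the end-to-end pipeline
test therefore asserts timing only to roughly the bloom half-width, while
the sharper recovery claims are made under the graded simulator.

**Study conditions of the recovery experiments** (fixed in
`bloomsat.evaluation`): peak days uniform over the year, duration 55–75
days, amplitude 0.9–1.0, `p_detect` 0.95, one year of daily observations
(≈ 30 per month, binomial noise), no clouds — monodominant stands in full
synchronized bloom for several weeks, detected almost surely when fully
visible. Under these conditions the recovered peak day falls within ±5
days of truth for > 90% of pixels and two-peak pixels (peaks ≥ 90 days
apart) yield exactly two events essentially always; both numbers are
recomputed by the acceptance script.

What the generator does **not** emulate: radiative transfer and
atmospheric variation, topographic shading, orbit/tile geometry, spatially
correlated cloud fields, mixed pixels at stand borders, inter-annual
phenology shifts, and detector confusion with other magenta-flowering
taxa. Passing tests therefore demonstrate the correctness and calibration
of the *pipeline machinery* under controlled conditions, not field
accuracy on real imagery.

## 7. Problem sizes and other fixed choices

The test suite and acceptance script run desk-scale problems chosen as the
smallest sizes at which each statistical claim is meaningful: 200 pixels
for recovery studies, 20 seeds for clustering agreement, 100 trials × 10
classes for null calibration, 500 patches / ≤ 30 epochs for detector
training, and a 20 × 20-cell demo world with 48 monthly scenes. Seeds are
explicit everywhere; a single `--seed` drives the acceptance script, and
every randomized component takes its own `numpy` `Generator` — no global
state.

## 8. Known limitations

- The harmonic fit interpolates exactly whenever ≤ 7 points carry
  positive weight; estimates then transmit observation noise fully, and
  peak-day precision degrades for wide, flat-topped bloom episodes.
- Day-of-year cluster features are linear, so populations straddling the
  year boundary can split; the circular option exists but changes the
  feature space.
- The bootstrap null treats pixels as exchangeable; with spatially
  autocorrelated presence the test is anti-conservative.
- The NumPy conv-net is CPU-bound and meant for small patches and
  desk-scale corpora, not for full-archive training.
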