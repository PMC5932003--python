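# Methods

This note documents the models implemented in peatflux, the defaults and
their rationale, the synthetic-data generator's scope, and the numerical
choices a user or reviewer would want stated explicitly.

## Radiocarbon calibration

A date r ± σ (¹⁴C yr BP) is calibrated against a curve giving the expected
radiocarbon age μ(θ) and curve error τ(θ) at calendar age θ (cal yr BP,
before 1950). The likelihood on a uniform calendar grid (default step
1 yr) is

    L(θ) ∝ (σ² + τ²(θ))^(−1/2) exp[−(r − μ(θ))² / 2(σ² + τ²(θ))],

with μ and τ linearly interpolated between curve knots. The
(σ² + τ²)^(−1/2) prefactor follows the convention of the standard
calibration programs; it matters where the curve error varies across the
support of a date. The grid is truncated to the smallest window holding
all but 10⁻⁶ of the mass and renormalised to sum exactly 1.

Reported ranges are highest-posterior-density (HPD) sets: grid points
ranked by mass, ties broken toward the older age, accumulated to the
level (default 95%), merged into contiguous intervals. Because published
tables print a single range even for multimodal dates, the table-facing
"calibrated age range" is the min–max envelope of the HPD intervals,
rounded to whole years. In the exactly-linear, zero-curve-error limit the
95% envelope equals r ± 1.96σ to within one grid step; this closed form
is a standing test.

### Calibration-curve fixture

The package ships a deterministic **synthetic stand-in** curve generator,
not the measured IntCal13 dataset. The stand-in has the broad structure
of the Northern Hemisphere radiocarbon timescale — a calendar-minus-¹⁴C
offset growing from ~0 in the last two millennia to ~800 yr in the
mid-Holocene and several thousand years in the late glacial, centennial
wiggles of ~20 yr, knot spacing of 5/10/20 yr, and a curve error growing
with age — and is strictly monotone in both axes. It exists so that every
calibration, age-model and simulation code path runs offline and is
exactly reproducible. Calendar ages calibrated against it are **not**
comparable with published chronologies; analyses of real cores must
supply a measured curve file in the IntCal text dialect (comma-separated
`cal BP, ¹⁴C age, error`, `#` comments ignored).

## Age-depth modelling

The model is classical-calibration Monte Carlo: per iteration, one
calendar age is drawn from each date's calibrated distribution (grid
point drawn with its probability mass; at 1-yr grids within-bin jitter is
immaterial), a cubic smoothing spline of age on depth is fitted, and the
iteration is rejected if fitted age decreases anywhere on the evaluation
grid. The point estimate is the per-depth mean of accepted iterations;
the envelope the 2.5/97.5 percentiles. A run whose acceptance falls below
1% of proposals raises an error advising outlier screening.

The smoother is the natural cubic smoothing spline in Reinsch form
(misfit + λ·∫g″², penalty K = Q R⁻¹ Qᵀ on the depth knots), solved by one
Cholesky factorisation per date set and reused across all Monte-Carlo
draws. The user-facing 0–1 smoothing parameter s maps to
λ = r·256^(3s−1) with r = n/tr(K) on depth standardised to [0, 1] — the
same functional form the classical spline smoothers use. On the packaged
Draftinge date set this mapping gives 10.1 effective degrees of freedom
at s = 0.3 versus 10.5 for the reference B-spline smoother, i.e. the knob
is directly comparable. Default s = 0.3; with exactly 4 dates the fit is
an interpolating natural cubic. Depth slices are half-open
[top, top + thickness) cm; slice ages are evaluated at midpoints; ages
increase downward.

Sedimentation rates per grid interval are thickness/Δage. Two summaries
are produced: per-iteration rates (mean and 2.5/97.5 percentiles) and the
rate of the point-estimate chronology. Downstream deterministic rates use
the latter: the mean of 1/Δage across iterations is biased high (Jensen)
wherever Δage gets small. Near-zero age increments are capped at a
configurable maximum (default 10 cm/yr) with a warning.

### Outlier screening

An outlier is a stratigraphically inconsistent date: its 95% calibrated
envelope lies entirely older than the envelope of some deeper date. The
screen repeatedly takes the most severe reversing pair and flags one
member: the bulk-peat member when exactly one is bulk (bulk fen peat
carries reworked/dissolved old carbon and is the standard suspect against
macrofossil dates), otherwise the member whose removal leaves the smaller
total misfit against a refitted spline. Removal scoring rather than
largest-own-gap flagging is masking-proof: a mutually supporting pair of
too-old dates pulls the model between the chains, so the largest single
gap tends to sit on an innocent neighbour. Dates that sit away from the
model without reversing stratigraphy are not flagged. On the packaged
Draftinge table the screen flags exactly the two bulk dates at 308 and
338 cm.

## Accumulation rates and inventories

Units are field-standard: bulk density ρ = m/(πr²h) in g/cm³ (default
corer radius 3.75 cm — a 7.5-cm Russian corer), sedimentation rate s in
cm/yr, PAR = ρ·s·10⁴ g m⁻² yr⁻¹, CAR = PAR·C%/100, element
MAR = PAR·conc·10⁻⁶.

The Monte-Carlo error model perturbs the *measurements*: uniform ±0.1 cm
on radius and thickness, ±0.002 g on mass, uniform ±5% on the
sedimentation rate, and Normal(conc, SD) on concentrations with the SD
from analytical replicates (a configurable relative-SD fallback, default
10%, applies with a warning when a slice lacks one). Negative thickness,
radius or concentration draws are redrawn. Default 100,000 draws per
slice; errors are reported as the 25th/75th percentiles of the draw set
(linear, type-7 interpolation — fixed for reproducibility). Element-MAR
draws reuse the PAR sub-streams at matched seed, so PAR and MAR share
measurement perturbations.

Carbon inventories over an age interval use rate × time:
M = Σᵢ CARᵢ·Δtᵢ·area with partial slices weighted by age overlap. A
stock-side cross-check (thickness × ρ × C% × area) is provided; the two
agree to < 2% whenever the rates derive from the same chronology, since
rate × time telescopes back to thickness.

## Dust provenance proxies

All indices are normalised to an upper-continental-crust (UCC) reference;
three published tables ship as CSV files with provenance headers
(McLennan 2001 default; Taylor & McLennan 1985 and Rudnick & Gao 2003
selectable — which table a given study used is rarely stated, and on
ratios the choice largely cancels). La/Lu and Gd/Lu are reported
UCC-normalised by default (raw ratios available). The Eu anomaly uses the
geometric mean, Eu* = √(Sm_N·Gd_N); the arithmetic variant sits behind a
flag since the literature contains both. The anomaly is scale-invariant
and equals exactly 1 on the reference pattern — both standing tests.
Replicate-based proxy errors are value × RSD. Dust flux is Al MAR divided
by the crustal Al mass fraction (default 0.0804).

## Organic-matter quality

The eight OM variables are C, N, C/N, δ¹³C, δ¹⁵N, DPH (humification
absorbance), carbohydrate/lignin (FTIR 1040/1650 cm⁻¹) and
carbohydrate/aliphatic (1040/2920 cm⁻¹; "carbohydrates/lipids" in some
usage — same quantity). DPH is corrected for slow catotelm decomposition
by first-order regression *on age* (the process is temporal), keeping the
residual + mean so the series stays on the absorbance scale.

PCA runs in correlation mode: columns z-scored with the n−1 sample SD,
eigen-decomposition of the correlation matrix, loadings =
eigenvector × √eigenvalue (variable–component correlations), scores
standardised to unit variance, components ordered by eigenvalue. Each
component is oriented so its largest-|loading| variable is positive —
principal-axis signs are arbitrary, so only |loadings| are comparable
across implementations. Exact invariants under test: eigenvalues sum to
the number of variables, L·Lᵀ reproduces the correlation matrix at full
rank, and the result is invariant to row order and to affine rescaling of
any column.

## Changepoint detection

The series model between changepoints is a constant mean plus Gaussian
noise with one global SD σ ("significant jumps in the mean"; the
variability about segment means measures the noise). Segment means carry
a conjugate Normal(m₀, v₀) prior and are **marginalised analytically**
(collapsed sampler). This removes transdimensional mean proposals, makes
the small-series enumeration oracle exact, and reduces the birth/death
acceptance ratio to the marginal-likelihood ratio; approaches that sample
means explicitly match in posterior expectation.

Priors: k uniform on 0…k_max (default 20), positions
exchangeable-uniform on the observation span, σ log-uniform on
[10⁻⁴, 10] × SD(y). Defaults m₀ = ȳ and v₀ = range(y)² are deliberately
weak. Moves (birth 0.15, death 0.15, move 0.20, σ 0.50): birth proposes a
position uniform on the span; death deletes a uniform choice; move
perturbs one position by Normal(0, span/20) with reflection; σ random
walks on the log scale (step 0.25). Proposals that empty a segment are
rejected (empty segments are unidentifiable); impossible moves (death at
k = 0, birth at k_max) count as rejected attempts, which preserves
detailed balance with unit proposal-ratio corrections. Defaults: 100,000
iterations, 20,000 burn-in, thinning 10; a stretch of > 10,000 consecutive
rejections raises a convergence error.

The expected curve at t is the posterior average of the conditional
posterior mean of the segment containing t,
(m₀/v₀ + nȳ/σ²)/(1/v₀ + n/σ²). The 95% credible band comes from full
conditional posterior *draws* of the segment means (mean plus conditional
variance): percentiles of the conditional means alone collapse to a band
that ignores each segment level's own uncertainty and covers a known step
function at 0% of grid points.

The enumeration oracle sums prior × marginal likelihood over every
admissible configuration for n ≤ 30, k ≤ 2: one changepoint per
inter-observation gap (the continuous position prior contributes
k!/spanᵏ × Π gap widths per distinct-gap combination; same-gap
configurations carry zero mass, exactly as in the sampler) and a log-σ
grid integrated with trapezoid weights. Sampler-vs-oracle agreement is
checked as total-variation distance on p(k).

Two spec-level expectations were corrected against this oracle: with the
weak default priors the oracle itself puts ~0.3 posterior mass on k = 2
for a clean 100-point step, so the position density concentrates ~70%
(not ≥95%) at the true jump; and the prior-recovery property (uniform
p(k) under constant likelihood) holds only where the
min-one-observation truncation is negligible, i.e. for n ≫ k_max gaps.

## Synthetic cores

`simulate_core` emulates an ombrotrophic *Sphagnum* bog record of the
southern-Scandinavian type. Defaults are the study conditions, not knobs:
8,900 yr duration; base sedimentation 0.06 cm/yr; stage-dependent bulk
density (fen 0.095 → 0.075 → 0.065 → 0.055 g/cm³ upward) giving
background PAR ≈ 45 g m⁻² yr⁻¹; C ≈ 49%; a high-accumulation event
between 5420 and 4550 cal BP multiplying the rate by 7; constant
background dust flux 0.25 g m⁻² yr⁻¹ whose element concentrations obey
the dilution law conc = flux/PAR; a two-endmember REE mixture (clay-like,
Eu/Eu* ≈ 0.67 versus felsic, Eu/Eu* ≈ 1.33, elevated La/Lu and Gd/Lu)
shifting to 70% felsic during the event; OM proxies driven by a
decomposition latent that grows with age and drops during the event; and
19 radiocarbon dates (±30 ¹⁴C yr) drawn through the calibration curve
with the curve error added in quadrature. The event changes accumulation
and dust source but not carbon content — an accumulation anomaly, not a
vegetation change. Concentration noise is lognormal (positive,
multiplicative analytical error); density and OM noise Normal. All
randomness flows through named sub-streams of one seed; identical
(spec, curve, seed) reproduce the core byte-for-byte.

What the generator does *not* emulate: compaction and autocompaction,
bog-growth/water-table feedbacks, hiatuses, heterogeneous date quality
(reservoir effects, bulk-vs-macrofossil bias), sampling gaps, and
correlated analytical error across elements. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to every pathology of real cores.

### Event recovery

Recovering the event from observations uses two complementary
fingerprints. The dilution law makes conservative-element concentrations
drop by the rate factor at the event boundaries — sharply in *depth*,
untouched by age-model smoothing — so the changepoint sampler on log
concentration versus depth locates the boundary depths as the half-fall
edges of the minimum plateau of its mean curve (smaller concentration
steps from density-stage changes stay above the half-fall level). A
continuous piecewise-linear chronology
age = a + b·depth + c·(clip(depth, d_top, d_bottom) − d_top) fitted to
the calibrated mean ages then gives the onset age at the deeper boundary
and the amplification as the slope ratio b/(b + c). Reading the onset
through the smoothing-spline chronology instead is biased ~150 yr old at
the kink — a smoothing spline cannot place a slope discontinuity more
precisely than the local date spacing, which is the reason the segmented
readout exists. Across seeds the recipe recovers the onset within ±40 yr
and the amplification within 8%.

Summary statistics reported by the acceptance script read the event
plateau as the median CAR between the recovered boundaries (50 yr inside
each edge) and the background as the median PAR 150 yr outside them;
per-slice extremes near the boundaries are chronology artifacts (spline
corners), not burial rates. In slice space the event occupies ~43% of the
record (10% of the time at 7× the rate), so the first OM principal
component mixes the secular decomposition trend with the event signature
and its correlation with age is weaker than in a record analysed on a
time-balanced grid.

## Problem sizes

The test suite and acceptance script run the sampler-versus-oracle check
at 150,000 iterations on 16-point series (TV < 0.05 required, observed
< 0.01), event recovery on 5 seeds of the full 847-slice default core,
quartile-coverage at 1,500–2,000 replicates of 1,000-draw Monte-Carlo
runs, and pipeline Monte-Carlo sizes of 2,000–20,000 draws per slice;
these sizes hold every check's sampling error well below its tolerance
while keeping a full run in the tens of seconds. The n = 100,000 default
for production runs is unchanged.

## Known limitations

* The bundled calibration curve is a synthetic stand-in; published
  calendar-age reproduction requires a measured IntCal file (see above).
* Chronologies are spline-based; piecewise-autoregressive (Bacon-style)
  models, reservoir offsets and post-bomb curves are out of scope.
* One global noise SD per changepoint analysis; no per-segment variance,
  no joint multi-proxy changepoints.
* No decomposition/compaction correction is applied to accumulation
  rates; concentrations are taken on dry mass as deposited.
* The carbon inventory is reported as rate × time × area; printed
  literature inventories for the emulated event are an order of magnitude
  smaller than this product implies, so inventory comparisons across
  studies should re-derive units from the stated rates and areas.
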