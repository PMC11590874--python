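# Methods

This note documents the models implemented in `dyadsync`, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical choices that matter for reproducing results.

## Study design being modelled

Two strangers each receive a 150 JPY endowment and decide how much to
transfer in an exchange-protocol prisoner's dilemma — once toward an
anonymous stranger before a 10-minute unstructured conversation
(*cooperativeness*) and once toward the partner afterwards (*cooperative
behavior*). Transfers are doubled on delivery (`payoff_A = 150 − a + 2b`),
so keeping money strictly dominates while joint transfer maximizes the
pair's total — a continuous-cooperation dilemma. The dyadic index is the
transferred proportion of the joint endowment, `(a + b)/300`.

During the conversation, facial behavior is coded per second (Duchenne
smile: AU 6 + 12; gaze at partner: yes/no) and prefrontal hemodynamics
are recorded by wearable two-channel fNIRS (source–detector separations
of ~1 cm and ~3 cm). All analyses use the final 300 s of the
conversation, the window most proximal to the game decision; readers
accept longer recordings and slice that window (`coding_window_s`,
configurable).

## Behavior scoring

Smiling-with-gaze is the per-second conjunction of the two codes; its
proportion of the window, averaged over both members, is the dyad's
index. Inter-coder reliability uses the intraclass correlation from the
two-way ANOVA decomposition. The variant is ICC(2,1) — two-way
random-effects, single-rater, absolute agreement —

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n),

computed per doubly-coded clip (seconds as subjects, coders as raters)
and averaged pairwise across clips. Rationale: "average pairwise
reliability" across coders with coders treated as a random sample calls
for the two-way random absolute-agreement form; ICC(1,1) and ICC(3,1)
are available through the `variant` argument for sensitivity checks.
Zero-variance clips (all codes identical) make the ICC undefined and
raise an error rather than returning a conventional value.

## fNIRS artifact reduction

Two steps, in order: (1) linear detrending of both channels (ordinary
least squares on the sample index), (2) short-channel ("dual
source–detector") regression of the deep on the shallow channel,

    x_deep = a₀ + a₁·x_shallow + x_neural,

keeping the residual as the neural signal and (a₀, a₁, r²) as metadata.
Detrending precedes regression; the regression spans the full recording
(no windowing). The residual is exactly orthogonal to the shallow
regressor and the constant, making the operation idempotent. A
zero-variance shallow channel cannot be regressed out; the detrended
deep channel is returned with a `degenerate_shallow` flag. Conversion
from raw light intensities to hemoglobin changes (modified
Beer–Lambert) happens upstream of this package; synthetic signals are
generated directly on the total-Hb-change scale. Only the left probe
feeds the synchrony analysis (the right probe is read and carried but
unused), matching the left-prefrontal focus of the design.

## Wavelet coherence and the IBS index

The continuous Morlet transform (center frequency ω₀ = 6) is computed
in the Fourier domain with zero padding; the Fourier period is
`4π·s/(ω₀ + √(2 + ω₀²))` (≈ 1.03·s for ω₀ = 6). The period grid is
logarithmic with 12 voices per octave over 4–64 s by default; periods
longer than half the record are trimmed with a warning. The cone of
influence is the e-folding time √2·s of the wavelet envelope, marked
per time point and excluded from time averages by default.

Coherence uses the standard smoothed-ratio estimator

    R²(s,t) = |S(s⁻¹ W_xy)|² / ( S(s⁻¹|W_x|²) · S(s⁻¹|W_y|²) ),

where S smooths with a Gaussian in time of standard deviation s/√2
(matched to the squared Morlet envelope) followed by a boxcar across
scale spanning the 0.6-scale decorrelation length (7 voices at 12 per
octave, truncated and renormalized at the grid edges). Both kernels are
positive, so R² ∈ [0, 1] cell-wise by Cauchy–Schwarz; values are
clipped only against floating-point round-off, and cells with zero
smoothed power (identically zero signals) are defined as 0.

The empirical null for interaction-driven coherence is the set of
*permuted dyads*: unordered pairs of participants belonging to
different real dyads, sampled without replacement from all admissible
pairs (C(2k, 2) − k of them for k dyads) under a caller-supplied seed;
180 pairs by default against 36 genuine dyads. Per period, the
time-averaged coherence of the two groups is compared with Welch's
unequal-variance t-test (Welch–Satterthwaite fractional df), two-sided
p-values are Benjamini–Hochberg-adjusted across all non-degenerate
periods in the analyzed range, and Cohen's d uses the pooled SD.
Periods of interest (POIs) are maximal contiguous runs with q < α and
genuine mean above permuted mean; no significant period yields an empty
result, not an error. A dyad's IBS index is the unweighted mean of its
time-averaged coherence over the POI periods. When several POIs emerge
the pipeline uses the one with the smallest mean q (a single band is
the expected outcome; the choice is recorded in the report). A fixed
period band can be supplied instead (`poi_band_s`), which is also how
parameter-recovery studies decouple IBS measurement from POI detection.

### Performance note

For the many-pair comparisons (36 genuine + 180 permuted pairs share 72
participants) the per-participant transforms and smoothed auto-spectra
are computed once and reused. In this batch path the wavelet fields are
decimated in time by a factor of 4 before smoothing: the carrier
frequency cancels in `W_x·conj(W_y)` and `|W|²`, leaving envelope-scale
content whose bandwidth is far below the decimated Nyquist rate for all
periods ≥ 4 s. Agreement with the undecimated estimator is within 0.02
per period on the time-averaged coherence (tested), which is an order
of magnitude below the genuine-vs-permuted contrasts of interest. The
pairwise `wtc()` entry point remains undecimated.

## Inference

**Mediation** (trait → smiling-with-gaze → behavior) uses the nested
OLS estimators: a from `m ~ x`, b and c′ from `y ~ x + m`, c from
`y ~ x`; ACME = a·b, ADE = c′, total = c, proportion = ACME/c. The
decomposition total = ADE + ACME is then an algebraic identity.
Uncertainty comes from case-resampling the dyads (1000 resamples by
default) with bias-corrected 95% CIs (BC; z₀ from the fraction of
resamples below the point estimate, no acceleration term —
percentile intervals via config) and bootstrap two-sided p-values
`2·min(P(θ* ≤ 0), P(θ* ≥ 0))`. Resamples in which x or m collapses to a
constant are redrawn and counted. If the mediator is *exactly*
collinear with the treatment the two-predictor equation is not
identified; the estimator returns the vanishing-noise limit (full
attribution through the mediator), which preserves the decomposition
identity. Results are bit-reproducible given (seed, n_boot). Mediation
uses all dyads; dyads lacking IBS are only excluded from the path model
(complete-case), mirroring the differing n per analysis in this design.

**Path analysis** fits the recursive model M1 ← X, M2 ← X,
Y ← X + M1 + M2 with independent residuals and freely covarying
exogenous variables; with four variables this leaves df = 1 (no
M1–M2 residual covariance — a declared default, exposed through the
path list). For recursive models with independent residuals the ML
estimates coincide with equation-wise OLS, so coefficients and residual
variances are computed directly from the sample covariance S (ddof = 1)
and the implied covariance is Σ̂ = (I−B)⁻¹Ψ(I−B)⁻ᵀ. Global fit:
T = (N−1)·F_ML with F_ML = ln|Σ̂| + tr(S·Σ̂⁻¹) − ln|S| − p, referred to
χ²(df); CFI against the independence baseline (diagonal of S, free
variances); SRMR as the root mean square of correlation-metric residual
moments over the p(p+1)/2 unique entries (diagonal included).
Standard errors use the expected information (OLS formula with the ML
residual variance, i.e. denominators of N), z = estimate/SE, and
standardized β rescale by the variables' SDs. The per-equation r² is
the squared multiple correlation of that outcome. A non-positive-
definite S or a cyclic path list raises an error naming the offending
eigenvalue/variables. The conventional joint good-fit rule
(nonsignificant χ², SRMR ≤ 0.08, CFI ≥ 0.95) is provided as
`PathFit.good_fit()`.

## Synthetic cohorts

The generator emulates the cohort the analysis assumes — not the
biophysics. Per dyad: a standard-normal trait x; latent mediators and
outcome from the linear structural model with configurable standardized
paths (defaults: X→Y 0.64, X→M1 0.35, X→M2 = M1→Y = M2→Y = 0 — the
direct-effect pattern this design is powered to detect); residual
variances keep every latent at unit variance, and an infeasible beta
combination (implied variance > 1) is rejected at config time.

* **Offers** map the dyad latent affinely onto the endowment
  (75 ± 37.5 per latent SD), add per-participant noise (SD 0.15 latent
  units ≈ 6 JPY), quantize to 10 JPY steps and clamp to [0, 150]. The
  noise SD is small enough that the observed indices remain faithful
  measures of the latents (trait recoverability within ±0.1 at n = 500
  is a design requirement of the generator); the true offer
  distribution of such experiments is unknown, so this distribution is
  declared, not inferred.
* **Behavior codes** are two-state Markov chains (bouts, not i.i.d.
  coin flips; mean ON dwell 3 s for smiles, 4 s for gaze) whose
  stationary ON probability follows a logistic link in the smiling
  latent M1 (base rates 0.15 smile, 0.65 gaze; slopes 0.9 and 0.4).
  Slopes were set so that the dyad-level sampling noise of a 300 s
  window attenuates the X→M1 effect by well under the ±0.1 recovery
  tolerance.
* **fNIRS**: each member's neural series mixes a dyad-shared unit-
  variance component, band-limited to 0.04–0.06 Hz by Fourier masking
  of common white noise, with idiosyncratic 1/f-flavored noise:
  `neural = √c·shared + √(1−c)·idio`, scaled to 0.02 mM·mm. The mixing
  weight c is `coupling · max(0, 1 + 0.4·M2)` capped at 0.95, so
  coupling = 0 means *no* shared signal (the exact global null) and the
  genuine-minus-permuted contrast grows monotonically with coupling.
  The default coupling 0.3 gives an in-band coherence elevation that a
  36-vs-180 Welch comparison detects essentially always, because the
  narrowband shared component dominates the idiosyncratic in-band
  power. Measured channels add a pink drift (SD 0.05), a random linear
  trend, and contamination `deep = a₀ + a₁·shallow + neural + trend`
  with a₁ ∈ [0.8, 1.2]. Sampling rate defaults to 10 Hz and is carried
  as metadata, never hard-coded.

Defaults mirror the study conditions: 45 dyads, 36 with usable fNIRS
(the rest have missing IBS), 600 s conversations, 300 s analysis
windows. All randomness flows through one `numpy` generator seeded from
the config, so cohorts and their CSV serializations are byte-
reproducible.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: realistic hemodynamic response
shapes, motion artifacts beyond linear trends, facial-dynamics
structure beyond bout durations, non-Gaussian offer distributions,
heterogeneous coupling spectra, or any cultural/contextual effect.
Tests demonstrate that the estimators recover the structure they assume
when it is present and stay calibrated when it is absent; they cannot
validate the substantive interpretation of any real cohort.

## Problem sizes used in the validation suites

The calibration and recovery suites run 50 replicate cohorts each at
the full study conditions (36 fNIRS dyads, 180 permuted pairs, 600 s at
10 Hz). Parameter recovery uses one 500-dyad cohort with IBS measured
over the fixed generating band. The monotonicity-in-coupling check runs
on reduced cohorts (8 dyads, 300 s, 40 permuted pairs, 6 seeds per
coupling level), a size at which the contrast ordering is already
stable. The null-calibration check accepts a false-positive fraction up
to 0.10 at α = 0.05 over 50 replicates, covering Monte-Carlo error and
the mild anti-conservatism induced by permuted pairs sharing
participants (the group's members are not fully independent — an
inherent property of the permuted-dyad design, not of this
implementation).

## Known limitations

* The permuted-dyad t-test treats surrogate pairs as independent
  samples although they share participants; q-values near the
  threshold should be read accordingly.
* The BC bootstrap omits the acceleration term (BCa); for the ratio
  quantity (proportion mediated) bootstrap draws can be unstable when
  the total effect is near zero — the CI is reported as computed.
* The path model covers observed variables only (no latent factors,
  no multilevel structure), with expected-information SEs; a
  nonparametric-bootstrap SE option would be a natural extension.
* POI selection assumes a contiguous band; physiologically plausible
  multi-band synchrony would be reported as multiple POIs, of which the
  pipeline indexes one.
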