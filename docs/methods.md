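# Methods

## The trilateration observer

Touch at location `L` on a 1-D sensory surface bounded by a proximal
landmark `X1` (the hand, 0% of tool space) and a distal landmark `X2` (the
tip, 100%) is localized by estimating the distance from each landmark and
fusing the two resulting beliefs. Each variable is a Gaussian likelihood;
distance noise is linear in distance,

    σi(di) = ε̂i + di·σ̂ ,

with a shared slope `σ̂` (noise per % of space) and landmark-specific
intercepts `ε̂1`, `ε̂2` that absorb uncertainty about where each landmark
is. Assuming a flat prior over touch location, the maximum-likelihood fusion
of the two landmark-anchored estimates has

    μINT = (μ1/σ1² + μ2/σ2²)·σINT² ,   σINT² = σ1²σ2²/(σ1²+σ2²) ,

so predicted variable error traces an inverted-U across the surface. Both
component estimates are unbiased, so the observer predicts variable error
only; constant error is summarized by the pipeline but not modeled.

The curve has an interior maximum exactly when `|ε̂1 − ε̂2| < (X2−X1)·σ̂`
(each landmark is the more reliable cue at its own end). Outside this
*anchored regime* one landmark dominates everywhere and the curve is
monotone; the sign of the fused variance's derivative at `X1` is the sign of
`(ε̂2 + (X2−X1)σ̂)³ − ε̂1³`. Raising `ε̂2` above `ε̂1` moves the peak
toward the tip, which is the asymmetry the behavioral data show.

Multisegment rods trilaterate locally: each segment uses its own endpoints
as landmarks, a location exactly on a breakpoint belongs to the segment on
its left, and the predicted profile is one inverted-U per segment with
minima at all breakpoints.

Canonical units are % of tool space throughout. The proximal landmark
defaults to the hand (0 cm) rather than the handle/shaft junction (12 cm);
this is a configuration choice (`SurfaceFrame`), not a fact about the data.

## The vibratory feature space

The rod is a clamped-free Euler–Bernoulli beam of normalized unit length.
Mode `n` has shape

    φn(x) = cosh(βn x) − cos(βn x) − αn (sinh(βn x) − sin(βn x)),
    αn = (cosh βn + cos βn)/(sinh βn + sin βn),

with `βn` the n-th root of `cosh β · cos β = −1` (found by bracketed root
finding near `(2n−1)π/2`, residuals < 1e-8). Only the first five modes are
kept — higher modes fall outside mechanoreceptor bandwidth. Shapes are
normalized to unit peak magnitude on a 10⁻⁴-resolution grid; an exposed
amplitude scale (default 1.0) keeps motifs inside the mode layer's tuning
support [−1.5, 1.5]. The *motif* of a location is the 5-vector of mode
shapes evaluated at that position. On the default 1% grid all motifs are
pairwise distinct (minimum separation ≈ 0.012 amplitude units) and
nearest-motif lookup is an exact round trip, which is the operational sense
in which vibration space is isomorphic to rod space. The beam model carries
no physical units (no frequencies, material constants, or damping): only
the location → modal-weight mapping matters here.

## The population-coding network

Three layers of independent-Poisson units (Fano factor 1), Gaussian tuning
`f(s) = κ·exp(−(s−μ)²/2σ²)`:

| layer | tuning centers | κ (or κ0) | σ (or σ0) | β | γ |
|---|---|---|---|---|---|
| mode (×5 subpopulations) | −1.5 : 0.02 : 1.5 | 25 | 0.08 | — | — |
| feature | −40 : 1 : 140 | 25 | 3.40 | — | — |
| distance 1 (anchor 0) | 0 : 1 : 140 | 25 | 3.40 | 0.01 | 0.5 |
| distance 2 (anchor 100) | −40 : 1 : 100 | 25 | 3.40 | 0.01 | 0.5 |

Distance-layer units carry gradients in distance `d` from their anchor:
gain `κ(d) = κ0/(1+βd)²` and width `σ(d) = (γ·ln(d+1)+1)·σ0`
(Weber–Fechner). The gain expression is deliberately the *decreasing* form:
the gradient must run high-to-low from the anchor outward for gain to encode
precision; the reciprocal reading is the only one consistent with that
requirement.

Forward pass per trial: the touch location is jittered by sensory noise
(Gaussian, SD 0.5% of space — applied to the location before the motif
lookup, since that is the unit the noise is stated in), converted to a
motif, and encoded by the mode layer (Poisson around tuning-curve means).
Feature-layer synaptic weights are matched filters: each unit's weight
vector is the unit-norm mode-layer template of its preferred location
(units preferring locations outside the physical rod get zero weights). The
winner-take-all of the synaptic drive (ties to the lower index) selects the
effective stimulus; all feature units then emit uninherited Poisson spikes
around their tuning means at the winner's preferred location. The
alternative of adding Poisson noise to the raw synaptic drive itself would
inherit mode-layer noise twice and is not used. Distance-layer drives are
`W·rS` with non-negative weights solved per decoding unit by non-negative
least squares so that the mean drive over locations reproduces the
prespecified gradient tuning curve (worst per-unit RMS residual ≈ 0.25% of
the unit's peak; the solver falls back to bounded least squares when the
active-set method stalls on this near-degenerate Gaussian basis); spike
counts are Poisson around the drive.

Decoding uses log-tuning kernels `h(L) = ln max(fD(L), 1e-12)` on a 1%-step
grid spanning the full feature range (−40..140, so decodes near the rod's
ends are not truncated; decoded values outside [0, 100] are retained). The
estimate is `argmax_L h(L)·r`, ties to the smaller location; an all-zero
response decodes to the grid midpoint and is degenerate by construction.
Integration sums the two subpopulations' log-likelihood profiles before the
argmax.

Simulations default to touches at 10..90% of the space in steps of 10. The
analysis driver and acceptance script use 500 runs per location, which
bounds the SE of a per-location SD near 3%; `run_simulation` supports the
full 5,000. Stochastic entry points refuse to run unseeded unless an
explicit opt-out is passed.

### What the network does and does not show

With the defaults above, decoded estimates are unbiased to < 1% of space;
single-subpopulation noise grows monotonically with distance from the
anchor (X-shaped pattern; Spearman ≈ 0.95 over the nine locations); and the
integrated estimate's SD is an inverted-U that never exceeds the better
single cue. The integrated variance also matches the Bayesian fusion
prediction — but only once the noise that is *common* to both
subpopulations is accounted for. The two decoders share the sensory jitter,
the winner-take-all relay, and the decoding grid, so their errors correlate
positively (r ≈ 0.3–0.5). Writing `c = Cov(L̃1, L̃2)` and
`ik² = Var(L̃k) − c`, the integrated variance equals
`c + i1²i2²/(i1²+i2²)` within ~15% at every location. The naive prediction
that treats `Var(L̃1)` and `Var(L̃2)` as conditionally independent
understates the integrated variance by 40–60% and should not be expected to
hold for this architecture; the covariance-aware check is the meaningful
test of optimal integration.

## The synthetic cohort

The generator emulates the study design: 38 participants, a 60-cm rod
(12-cm handle, part of response bookkeeping only), touches at 10–60 cm from
the hand in 10-cm steps (16.7–100% of tool space — the most distal touch is
at the tip itself), 10 trials per location per task, two report tasks.
Judgment noise lives in % of tool space and is shared by both tasks, since
the study found no effect of task: under the trilateration law the judgment
is `Normal(L, σINT(L)²)`; under the boundary-truncation alternative it is
`Normal(L, σT²)` truncated to `[γ1, γ2]`. The image task maps the judgment
onto a 20-cm drawing recorded in pixels (default 10 px/cm); responses
beyond the drawing are clamped at its ends, as a constrained cursor would
be — note this makes tip-location image responses genuinely
response-truncated. The space task maps the judgment onto screen cm via the
participant's judged tip, which is drawn from `Normal(56.5, 1.62·√38)` cm
truncated positive — the study-reported cohort mean with the SEM scaled
back to a participant-level SD.

Participant parameters are drawn uniformly from `σ̂ ∈ [0.02, 0.10]`,
`ε̂ ∈ [0.5, 5]` % — ranges that produce variable errors on the 1–6% scale
of the behavioral data; the resulting cohorts yield a median
trilateration-fit R² of ≈ 0.75–0.80 against their own variable errors,
matching the scale reported for human participants. Truncation cohorts draw
`σT ∈ [6, 12]`, `γ1 ∈ [−5, 10]`, `γ2 ∈ [90, 110]`, inside the fitting
bounds and on the same error scale. Constant errors default to zero; an
optional per-participant response slope/intercept exercises the regression
analysis with miscalibrated cohorts. The generator does not simulate motor
dynamics of striking, auditory masking, or familiarization.

## The analysis pipeline

Normalization: image-task pixels → proportion of the drawing → % tool
space; space-task cm → proportion of the participant's judged tip → % tool
space. Variable error per participant × location pools both tasks after
removing each task's own cell mean (pooled SD with n − n_tasks degrees of
freedom), so a constant between-task offset cannot inflate the SD;
non-demeaned pooling is available as an option. Accuracy is per-participant
OLS of mean judgment on true location with t-based group CIs.

Both variance-law models are fit by bounded least squares on the SD profile
(`scipy.optimize.least_squares`, trf) with 10 seeded multistarts, keeping
the best-RSS solution. The SD profile is the quantity the models predict
and the quantity whose goodness-of-fit (R² = 1 − RSS/TSS, negative values
permitted) is reported, so least squares on SDs is the objective; the
trilateration parameters are constrained non-negative, the truncation
parameters to `σT ∈ [1, 40]`, `γ1 ∈ [−30, 30]`, `γ2 ∈ [70, 130]` (% of rod
surface). A fit with `σ̂` pinned at 0 (flat profile) or truncation
parameters on their bounds is flagged. The truncated-normal SD uses the
closed form via `scipy.stats.truncnorm`; tests verify it against direct
Monte-Carlo sampling.

BIC uses the Gaussian-residual form `n·ln(RSS/n) + k·ln(n)` with `k = 3`
for both models and `n = 6` variance points per participant (one per
location after collapsing tasks; `n = 12` per-task points available for
sensitivity analysis). With equal `k` the comparison reduces to the RSS
ratio. ΔBIC = BIC(truncation) − BIC(trilateration); |ΔBIC| < 2 is weak
evidence, 2–6 moderate, > 6 strong.

## Known limitations

* **Study-scale model identifiability is weak.** With 6 SD points per
  participant and ~12% sampling error per point (20 trials/location), the
  two three-parameter families overlap substantially: the truncation model
  can shadow trilateration's low-variance anchors by placing a bound in the
  far tail (its bounds extend to γ2 = 70, below the most distal touch
  location), and multistart optimization reliably finds these solutions.
  BIC then identifies the generating model in only ~55–75% of synthetic
  participants per cohort. Discrimination is essentially perfect at large
  trial counts (hundreds per cell), which is what the pipeline's
  label-integrity test asserts.
* **Parameter recovery at study scale is noise-limited.** Median relative
  parameter error is ≈ 20% when data are generated directly in % space and
  ≈ 25–30% through the full task pipeline (tip responses in the image task
  clamp at the drawing edge, compressing the tip SD); participants with
  nearly flat generating curves are poorly identified, capping the median
  fitted-vs-generating-curve R² near 0.7–0.8.
* The network's integrated-variance optimality holds in the
  covariance-aware sense only (see above); architectures without shared
  input noise would be needed for the independence-based prediction.
* The mode layer abstracts away mechanoreceptor transduction and mode
  decomposition; motifs enter as noiseless functions of (jittered)
  location.
* One spatial dimension only; flat location prior; no learning of weights
  or temporal spiking dynamics.
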