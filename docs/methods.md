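# Methods

## Generative task

A trial is ten periods long. The latent regime starts red; before each
period — including the first — an independent Bernoulli(*q*) draw
decides whether it shifts to blue, and once blue it stays blue (a single
absorbing change point per trial). The period's signal is then drawn
from the current regime's urn: the dominant color appears with
probability *d*/(*d*+1), so *d* = 9 means a 90:10 urn and *d* = 1.5 a
60:40 urn. Signals are coded internally as *r*<sub>t</sub> ∈ {0 = blue,
1 = red}, matching the indicator in the observer equations. A session is
a set of blocks; each block presents the nine (q, d) cells once in a
fresh random order, and the full design is 11 blocks (8 behavioral + 3
scanner), i.e. 99 trials and 990 estimates per subject. The quadratic
bonus 30·(0.1 − 0.2(P−B)²) TWD per estimate spans exactly [−3, 3] and is
maximized when the stated probability equals the regime indicator. The
end-of-session lottery that realizes the bonus over ten random trials is
not part of the computational pipeline.

Every stochastic operation takes an explicit `numpy.random.Generator`;
dataset metadata records the run seed, so fixed seeds give byte-identical
datasets.

## Observer models

The Bayesian posterior odds factor into prior odds
(1−(1−q)<sup>t</sup>)/(1−q)<sup>t</sup> and a likelihood ratio that sums
over the disjoint possible shift times *j* = 1..*t*, each weighted by its
conditional probability q(1−q)<sup>j−1</sup>/(1−(1−q)<sup>t</sup>) and
carrying the diagnosticity term *d*<sup>t+1−j−2Σr</sup>. Correctness is
enforced three ways: the closed form, an explicit enumeration over shift
times with exact emission likelihoods, and a recursive two-state filter
with absorbing blue state (prior<sub>t</sub> = post<sub>t−1</sub> +
(1−post<sub>t−1</sub>)·q followed by a likelihood-ratio update). The
three routes agree to 1e−10 on randomized instances; `posterior_oracle`
raises if they ever disagree.

The system-neglect observer applies *α·q* **only inside the prior
odds**; the shift-time mixture weights keep the undistorted *q*. That is
the printed form of the model and the default here; because the model
could also be read as distorting the weights, a
`distort_mixture_weights` flag applies *α·q* there too as a sensitivity
analysis (off by default). Signal-dependent variants choose the whole
(α, β) pair by the *current* period's signal class — the period is the
unit at which parameters were estimated separately for change-consistent
and change-inconsistent signals — giving 6 (shared), 9 (one family
doubled) or 12 (both doubled) parameters.

Numerics: the posterior is computed in log space throughout —
`log1p`/`expm1` for the survival and prior-odds terms, `logsumexp` for
the shift-time mixture — so it is stable from q ≈ 1e−300 up to q = 1 and
for |β| ≤ 10 at any d, where the linear-space diagnosticity term would
overflow. The posterior at t = 0 is defined as 0 (the trial starts red
with certainty); it only enters the optional full-revision IO
convention below.

## Synthetic populations

The human cohort is emulated by a log-normal population over the
weighting parameters, *mean*-anchored at the group means α = (3.69,
1.04, 0.65), β = (1.69, 0.77, 0.57): log values are
ln m − s²/2 + s·(√ρ·u + √(1−ρ)·ε) with dispersion s = 0.35 and shared
subject-level factor weight ρ = 0.5, so within-family correlations
across levels are positive (≈ρ) while the α and β families are
independent — the correlation structure observed in the fitted human
parameters. Draws violating α·q < 1 are rejected and redrawn. The
distributional form, s and ρ are package choices (the study reports
only the group means); s = 0.35 gives a realistic between-subject
spread without crowding the α·q < 1 boundary, and the sampled means
stay within 2% of the anchors.

Response noise is additive Gaussian in probability space, either
homoscedastic or heteroscedastic with the SD drawn per period from the
empirical five-bin residual-SD profile (0.1015, 0.1296, 0.1987, 0.1929,
0.2061 over [0, 0.2) … [0.8, 1]) indexed by the noiseless model
probability. Noisy values are clipped to [0, 1] (clipping never moves an
in-range value; the clipped fraction is recorded in metadata) — chosen
over resampling for simplicity. Optional quantization rounds to the
two-digit button grid 0.00–0.99; it is off for recovery studies and on
for task-realistic simulation. Missing periods ("too slow" responses)
are flagged, never dropped silently.

What the generator does **not** emulate: learning or drift across
trials, sequential dependencies beyond the model-plus-white-noise
structure, and any relation between response time and accuracy. Passing
tests therefore certify the estimation machinery under the model's own
assumptions, not the model's adequacy for human data.

## Fitting

Per-subject estimation minimizes the sum of squared deviations between
observed and model probabilities over all non-missing periods
(trust-region reflective least squares, cost tolerance 1e−10, numerical
Jacobian), with box constraints α<sub>i</sub> ∈ [0, (1−ε)/q<sub>i</sub>]
and β<sub>j</sub> ∈ [−10, 10]; the wide β floor admits pathological fits
but keeps the space open. Multi-start policy: all-ones, the group means,
and three random draws; best RSS wins, ties broken by start order;
failure on all starts returns a flagged, unconverged result. Fits are
invariant to trial order, and a noiseless round trip recovers generating
parameters to 1e−4.

The Gaussian-MLE path is exact by profile likelihood: the RSS minimizer
is the MLE of the model parameters and σ̂ = √(RSS/n) the MLE of the
noise SD, so no second optimization is needed. Note that boundary
clipping truncates the generator's noise, so σ̂ on clipped synthetic
data sits *below* the generating σ (e.g. ≈0.12 for σ = 0.15 on the full
design); the MLE consistency check therefore uses unclipped data, where
the Gaussian model is exactly true. AIC uses k = model parameters + 1
(for σ) and includes the Gaussian constant, so the NLS and MLE paths
give identical values; model comparison reports group-mean AIC and
paired two-tailed t-tests on per-subject AIC.

### Parameter recovery

The recovery harness follows the four-step procedure: draw each
subject's true parameters, simulate their estimates on a fresh
full-size design, refit, and correlate truth with estimates — then
repeat with noise σ ∈ {0.01, 0.05, 0.1, 0.2, 0.3}. Correlations pool
truth-estimate pairs across subjects *and* the three levels of a family
(90 pairs per family for 30 subjects); the per-level breakdown is also
reported, and is systematically lower because pooling adds the large
between-level variance. The heteroscedastic variant rescales the
five-bin SD profile so its mean equals each level's σ, making the
homo/hetero comparison well defined per noise level (the original
analysis ran the profile once at its empirical scale, ≈0.17 mean).
Default problem size — 30 subjects × 11 blocks × 5 noise levels — runs
in well under a minute on one CPU.

## Bias metrics

IO = ΔP<sub>t</sub> − ΔP<sub>t</sub><sup>B</sup> is computed per period
for t = 2..10 by default, averaged per trial, then per subject ×
condition, then across subjects (equal weights at every stage; the
hierarchical weighting is not pinned down elsewhere, so the simplest
convention is used and exposed). An optional full-revision convention
(t from 1, against P₀ = 0) is provided; under it the trial-mean IO
telescopes to (P<sub>T</sub> − P<sub>T</sub><sup>B</sup>)/T, which makes
the sign prediction from (α, β) vs 1 exact. The default t = 2..10
convention can flip the sign in the fast corner cell (q = 0.1, d = 9)
even for uniformly inflated weights, because the overreaction there
lives in the excluded first-period jump and both posteriors saturate by
t = 10 — the property test uses the full-revision convention for this
reason, while the group-mean pattern check keeps t = 2..10.

The behavioral slope γ regresses the subjectively weighted parameter on
its objective level (three points, OLS with intercept): β<sub>j</sub>·ln
d<sub>j</sub> on ln d<sub>j</sub> for diagnosticity, and — the most
direct analogue — the effective transition probability
α<sub>i</sub>·q<sub>i</sub> on q<sub>i</sub> for volatility. Both give
γ = 1 at Bayesian parameters and γ = 0 at complete neglect. Slopes
outside (−0.5, 1.5) (configurable) are flagged excluded, never dropped.
Position tests are one-sample two-tailed t-tests against 0, 1 and 0.5;
degenerate zero-variance cohorts return t = 0 (p = 1) at the matching
reference rather than NaN.

Design regressors per period: P, ΔP, certainty |P − 0.5|, period
number, signal code s (+1 blue, −1 red), strength of change evidence
s·ln d, the intertemporal prior ln((1−(1−q)^t)/(1−q)^t), and the
action-handedness code of the two-digit entry (digits 1–5 left hand,
6–9 and 0 right; both-left −1, mixed 0, both-right +1).

## Correlation statistics

Dependent correlations sharing a variable are compared two ways. The
parametric z test: z = (z<sub>r1</sub> − z<sub>r2</sub>)·√((N−3)/(2(1−r<sub>x</sub>)h))
with r̄² = (r₁²+r₂²)/2, f = (1−r<sub>x</sub>)/(2(1−r̄²)) capped at 1,
h = 1 + r̄²(1−f)/(1−r̄²); Fisher transforms are guarded at |r| =
1−1e−12. Its two-tailed type-I error at N = 30 is calibrated (within
[0.03, 0.07] at nominal 0.05 over 10⁴ null cohorts). The nonparametric
route resamples subjects (joint rows) with replacement, 100,000 times by
default; the one-tailed p is the (+1-corrected) fraction of resampled
differences on the opposite side of 0 from the observed difference —
one convention among several, recorded in the output rather than
asserted as canonical. Degenerate resamples with a constant column are
redrawn and counted. The default tail is one-tailed, mirroring the use
case where one correlation is already known to be positive; two-tailed
is available.

## Problem sizes and known limitations

Tests run the full recovery (30 × 11 blocks × 5 σ, homo- and
heteroscedastic) plus reduced-size harness checks (2-block designs,
small cohorts for the AIC-selection rate); the analysis drivers use the
full cohort sizes. Known limitations: no hierarchical or Bayesian
population fitting; no cross-validation or regularization; two regimes
and a single change point only; the log-normal population is a modeling
convenience, not an empirical claim; recovery correlations at σ = 0.3
sit close to the reported floor and individual seeds can dip slightly
below it; and σ̂ estimates on clipped data inherit the truncation bias
described above.
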