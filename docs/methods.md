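# Methods

## The task

The package implements the classical four-deck gambling task ("ABCD"
version): 100 trials, one card per trial, starting balance 2000 EUR. Each
deck is a fixed stack of 40 cards whose payoffs repeat in 10-card cycles.
Decks A and B pay 100 EUR per card but lose 250 EUR net per full cycle
(disadvantageous); decks C and D pay 50 EUR per card and gain 250 EUR net
per cycle (advantageous). A and C spread five losses across each cycle
(A: 150–350 EUR; C: 25–75 EUR), B and D concentrate the cycle's loss in a
single card (1250 and 250 EUR). Per-card gains for C and D are not part of
the published task description beyond the cycle nets; 50 EUR is the
classical magnitude and is the only value consistent with five losses of
25–75 EUR summing to 250 and a +250 cycle net. Deck A's five cycle losses
are fixed at {150, 200, 250, 300, 350} (sum 1250) and deck C's at
{25, 50, 50, 50, 75} (sum 250); within-cycle positions follow the classical
fixed order, with an optional seeded within-cycle shuffle for sensitivity
analyses. Money is integer EUR throughout — no floating-point currency.

A deck drawn 40 times is exhausted and removed from the choice set (the
choice policy contract and the likelihood both honor this). The task's
1-second minimum inter-choice interval is metadata used when generating
timestamps; the engine has no real-time behavior.

## The PVL model

Choice behavior is modelled by Prospect Valence Learning. On trial *t*
the net outcome x(t) (gain − loss of the drawn card) is valued by a
prospect-theory utility

    u(t) = x(t)^alpha            if x(t) >= 0
    u(t) = -lambda * |x(t)|^alpha  otherwise

with outcome-sensitivity alpha and loss aversion lambda. Deck
expectancies E_j(t) start at zero and are updated by one of two rules:

* **decay**: E_j(t) = A·E_j(t−1) + δ_j(t)·u(t) — every deck's
  expectancy decays by the recency factor A each trial; the chosen deck
  additionally absorbs the current utility;
* **delta** (Rescorla–Wagner): E_j(t) = E_j(t−1) + A·δ_j(t)·[u(t) −
  E_j(t−1)] — only the chosen deck moves toward u(t) at learning rate A.

Choice follows a softmax over θ(t)·E_j(t) with inverse temperature
θ = 3^c − 1, so c = 0 gives uniform random choice and large c
near-deterministic choice. The softmax is evaluated in the log domain
with a max shift; exhausted decks are masked to probability zero and the
rest renormalized. θ is always recomputed from c, never stored.

**Outcome scaling.** Net payoffs are divided by 100 (outcomes in units of
100 EUR) before entering the utility. With raw EUR values and c near its
upper bound of 5 the softmax exponent θ·E overflows double precision;
rescaling is the standard practice for this model and leaves ordinal
behavior unchanged. The factor is a parameter (`outcome_scale`) of every
function that consumes outcomes, because published fits do not always
state their scaling and fitted parameter magnitudes depend on it.

## Estimation

**Maximum likelihood (per subject).** The sequence log-likelihood
(uniform trial-1 probabilities, exhaustion masking identical to the task
engine) is maximized over the open box alpha ∈ (0,1), lambda ∈ (0,5),
A ∈ (0,1), c ∈ (0,5) by L-BFGS on a logistic ("z = logit(theta/upper)")
reparameterization — the likelihood is never evaluated outside the box by
construction. 20 starts drawn uniformly inside the box under a seed;
best log-likelihood wins, first-found on ties. The likelihood core is a
compiled (numba) scalar loop; an independently written trial-by-trial
replay through the public single-step operations serves as its oracle in
the tests (agreement to 1e−10).

**Hierarchical Bayes (per cohort).** The standard probit-normal
construction for bounded parameters: for each parameter p with upper
bound U_p (alpha ∈ (0,2), lambda ∈ (0,10), A ∈ (0,1), c ∈ (0,5)),

    theta_ip = U_p · Phi(mu_p + sigma_p · z_ip),  z_ip ~ N(0,1)
    mu_p ~ N(0,1),  sigma_p ~ HalfNormal(1)

(non-centered, so the sampler works on well-scaled unconstrained
coordinates; sigma is sampled on the log scale with the Jacobian
correction). Sampling uses a differential-evolution ensemble MCMC
(80% DE moves, 20% DE-snooker) with 2·dim + 2 walkers, vectorized so the
whole ensemble evaluates the compiled likelihood in one call. Post-warmup
walkers are regrouped into pseudo-chains and split-R̂ and effective sample
size are computed with ArviZ for every group-level location and scale; a
fit is flagged `converged` only if all split-R̂ ≤ 1.1, and is never
silently reported otherwise. Groups can be fit jointly or separately
(`mode: per_group` is the pipeline default).

Defaults are 4 diagnostic chains and 1000 retained iterations after 1000
warmup steps; the bundled recovery studies run at reduced sizes (15
subjects, 1000 warmup + 300 retained; ten repetitions) — chosen as the
smallest runs at which split-R̂ stays below 1.1 with margin.

Observed estimator behavior at interior truth (alpha 0.5, lambda 2.5,
A 0.5, c 1.0; 100 trials, 200 agents), computed by the test suite:
per-parameter median absolute errors are below their recovery SDs;
lambda is weakly identified at n = 100 and carries a positive bias of
about +1.0 (MAE ≈ 1.1, recovery SD ≈ 1.3) — reported here rather than
hidden, and consistent with the general difficulty of separating loss
aversion from outcome sensitivity in 100-trial data. The hierarchical
fit shrinks per-subject estimates toward the group (posterior-mean
variance ≤ MLE variance on the same data).

## Skin-conductance profiling

Conductance (μS) is averaged in fixed half-open windows locked to the
per-trial card-selection markers: anticipatory = [marker − 1250 ms,
marker), post-election = [marker, marker + 1250 ms). The post-election
duration is not dictated by the anticipatory definition; 1250 ms is the
symmetric default and is configurable. The aSCR index is the mean
anticipatory conductance before disadvantageous (A/B) choices minus that
before advantageous (C/D) choices; a positive index labels the subject
aSCR+, negative aSCR−, and an exact zero is labelled `indeterminate` and
excluded from group contrasts (the dichotomy offers no rule for ties).
A 60-second pre-task segment provides the baseline mean. No
deconvolution, peak scoring, or tonic/phasic decomposition is applied —
the analysis averages the raw signal in windows, so the pipeline does
exactly that.

## Synthetic cohorts

`synthetic_cohort` generates complete datasets with the statistical
structure the analysis assumes: two groups (14 aSCR−, 15 aSCR+), each
subject a PVL agent whose parameters are drawn from truncated normals
inside the MLE box around group means/SDs (defaults: aSCR− alpha 0.557,
lambda 3.00, A 0.495, c 0.365; aSCR+ alpha 0.165, lambda 2.57, A 0.458,
c 0.998 — the reported MLE group profiles), tonic baselines near 4.82 μS
(aSCR−) and 6.66 μS (aSCR+), and response times drawn from lognormals
whose block-wise means decrease from ≈2.9 s in block 1 to ≈1.8 s in
block 5, the steepest drop between blocks 1 and 2.

Traces are built as tonic level + AR(1) drift (coefficient 0.95 at
32 Hz, innovation SD 0.02 μS) + white noise (SD 0.02 μS) + one phasic
bump per trial confined to the 1250 ms pre-choice window. The bump is a
half-Gaussian (σ = 300 ms) rising to its peak at the marker — any shape
concentrated in the window would do; this one is fixed for
reproducibility, and a rectangular option exists for exact-arithmetic
fixtures. Amplitudes are 0.5 μS before the "preferred" deck type and
0.2 μS before the other (preferred = disadvantageous for aSCR+,
advantageous for aSCR−), i.e. a ≈0.09 μS expected index magnitude after
window averaging — small against the ~5 μS tonic level, as real
anticipatory responses are, but reliably recoverable by averaging ~50
windows per deck type. 32 Hz sampling gives 40 samples per window; any
rate ≥ 8 Hz keeps ≥ 10.

What the generator does **not** emulate: motion/electrode artifacts,
non-responders, habituation of phasic amplitude across blocks,
correlation between SCR amplitude and behavior within subject, and the
exact cell values of published group tables (those are study data, not
model outputs). Passing recovery tests therefore shows the pipeline is
correct and well-calibrated under clean event-locked structure — not
that it is robust to artifactual real-world recordings.

## Group statistics

Contrasts are computed from group summaries (n, mean, SD): pooled-
variance t with df = n1 + n2 − 2, and Welch t with Welch–Satterthwaite
df; two-sided p values. Two effect sizes are always reported with
explicit labels: Cohen's d (pooled SD) and the r-type effect size
sqrt(t²/(t² + df)). Published reports sometimes print the r-type value
under the label "d" — for the canonical gambling-index contrast
(−2.29 ± 13.38, n=14 vs 12.00 ± 18.99, n=15) the r-type value is 0.41
while pooled d is 0.86 — so the package never makes a silent choice
between them. No multiplicity correction is applied by default
(planned-contrast convention); a Holm flag is available. Repeated-
measures ANOVA is out of scope: the pipeline reports descriptives and
planned contrasts only.

## Numerical and degenerate-input choices

* Softmax: log-sum-exp with max shift; probabilities renormalized after
  exhaustion masking; all-unavailable is an error.
* Likelihood at c → 0 is exactly n·log(1/4) (θ = 0 exactly in floating
  point for c below ~1e−16).
* RT summary cells with no observations are missing, never zero; the SD
  of a single observation is missing (sample SD undefined).
* aSCR index is an error (not a default) if a deck type was never
  chosen; windows that leave the recording raise boundary errors.
* MLE ties across starts: first-found best kept (deterministic under
  seed); non-finite starts are dropped and total failure raises a
  diagnostic-carrying error.
* Fits accept 1-trial sessions (the likelihood is flat: every parameter
  attains log(1/4)); empty sessions are rejected.

## Known limitations

* Loss aversion (lambda) and, to a lesser degree, alpha are weakly
  identified from single 100-trial sessions; per-subject MLEs of lambda
  should be interpreted as ordinal at best. The hierarchical fit
  mitigates but does not remove this.
* The ensemble MCMC is gradient-free; very large cohorts (hundreds of
  subjects) would make the walker ensemble high-dimensional and slow to
  mix. For the cohort sizes this package targets (tens of subjects)
  split-R̂ stays well under 1.1 at the default settings.
* The probit-normal hierarchical model and the truncated-normal cohort
  generator are deliberately different distributions; hierarchical
  recovery tests use cohorts simulated from the model's own generative
  process, while pipeline-level tests use the study-style generator.
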