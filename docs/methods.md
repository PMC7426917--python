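# Methods

## The task and its data

The pay-to-know task presents, on each of 126 trials, a single trait word
(63 positive, 63 negative) and a binary choice between learning an
evaluation one received on that trait ("to know", TK) and not learning it
("not to know", NTK).  The options carry token payoffs whose difference
Δm = m_TK − m_NTK takes the seven values −3…3, with 18 trials per level
(9 per valence).  Choosing TK when Δm ≤ 0 is *costly* knowing.  The package
represents a session as a `TaskSchedule` of validated `TrialDesign` cells
and a dataset as a flat CSV of `ChoiceRecord` rows.

Only the payoff difference enters any model, so absolute payoffs are
anchored at a configurable NTK base (default +5 tokens in the gain frame,
−5 in the loss frame) with m_TK = base + Δm.  The TK option's screen side is
randomized 50/50 per trial, making side orthogonal to Δm in expectation;
trial order is one seeded shuffle of the full 126-trial list (no
within-block balancing of Δm is imposed).

## The choice model

The subjective value of knowing relative to not knowing is

    ΔV = α·u(Δm) + β_v·d(t)

with money weight α ≥ 0, unknown-aversion weight β_v ∈ [−1, 1] (positive
values mean not-knowing is costly; β may be shared across valences or split
into β_pos / β_neg by trait valence), an optional per-trial discount
d(t) = δ^(t−1) on the value of knowing, and an optional loss-averse money
utility u(m) = m for m ≥ 0, λ·m for m < 0 applied per option before
differencing.  Choice probabilities follow a softmax with symmetric lapse,

    P(TK) = (1 − 2ε)·σ(γ·ΔV) + ε,

with inverse temperature γ > 0 and lapse rate ε ∈ [0, 0.5]; the (1 − 2ε)
form makes [0, 0.5] the only interpretable lapse range, and probabilities
are compressed into [ε, 1 − ε].  The model is coded in the TK−NTK frame,
which is algebraically identical to a left/right frame with an evaluation
indicator of ±1 (property-tested).

**Identifiability.**  The likelihood depends only on (γα, γβ, ε): rescaling
(α, β) by c and γ by 1/c changes nothing.  Estimation therefore pins α = 1,
making fitted β the identified ratio β/α — the value of knowing in token
units, which is also the negative of the model's exact indifference point —
and fitted γ the product γα.  Freeing α (`fit_alpha=True`) is supported for
likelihood computations but leaves the parameter scale meaningless, and the
free-parameter count used by BIC includes α only when it is actually freed.

## Estimation

Each subject-session is fitted by bounded L-BFGS-B with an analytic
gradient, from 20 Latin-hypercube starting points plus one field-typical
centre start; the best optimum is kept and the procedure is deterministic
given (data, spec, n_starts, seed).  Bounds: β ∈ [−1, 1], γ ∈ (0, 30],
ε ∈ [0, 0.5], δ ∈ (0, 1], λ ∈ [1, 5]; parameters landing on a bound are
flagged.  Likelihoods are floored at 1e−12 per trial so ε = 0 stays finite.

The lapse-softmax likelihood has a well-known pathology at this trial
count: a nearly flat ridge toward very large γ where the choice rule
degenerates into a step function, the fitted β becomes arbitrary within a
payoff level, and the "global" optimum can sit 0.01–0.1 nats above a far
more plausible interior solution.  The default objective therefore adds a
weakly-informative lognormal penalty on γ (median 3, log-SD 1, covering
roughly the 1–8 decade of typical softmax sensitivities); `gamma_prior=None`
gives pure maximum likelihood.  Reported `neg_log_lik` and BIC are always
the unpenalized likelihood at the returned point, so model comparison
remains a likelihood comparison.  An 80-start control run confirmed the
20-start search already attains the global optimum of the objective.

Per-subject models are scored by BIC = k·ln(n) + 2·NLL and compared by the
group sum; the lowest group BIC wins.  In-sample prediction accuracy counts
a trial correct when the higher-probability option matches the observed
choice, with 0.5 credit for exact ties.  Cross-validation is deliberately
not the headline metric because the comparison statistic of record here is
in-sample accuracy of the winning model.

## Psychometrics

Knowing ratios per Δm level are fitted with the four-parameter base-10
sigmoid f(x) = m_i + (m_j − m_i)/(1 + 10^(−b(x − x0))), bounded so the
asymptotes straddle 50% (m_i ∈ [0, 0.5), m_j ∈ (0.5, 1], b ∈ (0, 20],
x0 ∈ [−5, 5]), initialized from the curve extrema and the steepest observed
step.  The point of subjective equivalence is the closed-form inversion

    PSE = x0 − (1/b)·log10((m_j − 0.5)/(0.5 − m_i)),

so f(PSE) = 0.5 holds to machine precision (the "derivative" notation
sometimes used for this quantity is read as functional inversion, the only
reading consistent with its verbal definition).  A negative PSE means
subjects forgo tokens to know.

Group PSEs use a 200-iteration bootstrap resampling *subjects* with
replacement, averaging per-Δm knowing ratios across the resampled subjects,
fitting and inverting; per-subject PSEs from individual curves are exposed
separately (`per_subject_pse`).  Failed fits are recorded as missing, never
re-drawn (re-drawing would bias the interval), and a warning is attached
when more than 20% fail.  Contrasts use the bootstrap distribution of PSE
differences, jointly resampled when paired; an effect is significant when 0
falls outside the 95% percentile interval.  For homogeneous agents the
model's exact indifference point −β/α is the analytic oracle: bootstrap
means converge to it and the percentile CI covers it ~93% of the time in
100 replicated 12-subject cohorts (nominal 95%, n_iter = 200).

## Synthetic cohorts

The generator draws per-subject parameters from truncated normals
respecting all bounds.  Valenced means are the reported group values
(β_pos = 0.35, β_neg = 0.23 for social evaluation; shared β = 0.32 for
nonsocial) and their SDs are inverted from the corresponding one-sample
t-statistics (SD = mean·√n/t at n = 36: 0.219, 0.331, 0.246), which is
exact for a one-sample t.

γ and ε populations are not reported anywhere, so they are calibrated once
against the printed observables of the fitted model: the per-subject β
estimation noise implied by those t-statistics (≈0.1–0.2) and an in-sample
prediction accuracy near 88%.  Both point to sharp choice curves; defaults
are γ ~ N(6.0, 1.5²) truncated to (0, 30] and ε ~ N(0.08, 0.04²) truncated
to [0, 0.5].  α is fixed at 1 with zero population SD: under the α = 1
normalization only (γα, β/α, ε) are identifiable, so population variation
in α is operationally part of γ's spread, and a nonzero α SD would push the
identified ratio β/α outside the model's own [−1, 1] range for some
subjects.

BDI scores (truncated normal, mean 8, SD 6, range [0, 63], rounded) are
coupled to β_pos through a Gaussian copula at a target correlation of
−0.35, preserving both marginals.  Treatment cohorts simulate each subject
under placebo and oxytocin (counterbalanced order): oxytocin shifts β_neg
additively (default −0.135, the midpoint of the reported paired-test
interval; the placebo-session level is not separately reported, so this is
a calibration knob) and shifts β_pos by a BDI-dependent slope (default
0.005 per centred BDI point, direction from the reported positive
correlation of the oxytocin effect with depression scores).

Population draws are quantile-stratified by default (permuted stratum
midpoints pushed through the copula), so a 36- or 50-subject cohort's
realized moments match the configured population values instead of
wandering by a third of the tolerance bands used in validation; iid
sampling is available with `stratified=False`.  Self-relevance ratings are
written as a single constant (default 5), so the mean-split filter retains
every simulated trial under its tie rule.

What the generator does *not* emulate: response times, serial dependence or
learning across trials, session-order effects, valence-arousal structure of
individual trait words, and any misspecification of the choice rule itself
(real subjects need not be softmax-lapse agents).  Passing recovery and
selection checks on these cohorts therefore validates the estimation
machinery, not the model's adequacy for real data.

## Statistics

The 2×2 χ² uses the Yates continuity correction by default,
Σ(max(|O−E|−0.5, 0))²/E with df = 1: on the published counts of
unknown-averse participants (35/36 positive vs 26/36 negative) the
corrected form reproduces the reported 6.87 exactly, while the uncorrected
form gives ≈8.7, which is the evidence for the default; the uncorrected
variant is an option.  The paired structure of those counts is deliberately
ignored (independent-table χ²) because only that choice reproduces the
reported statistic.  Cohen's d for dependent samples is the mean difference
divided by the SD of the differences.  The self-relevance "medium split"
retains trials rated at or above the subject's own mean rating (ties kept).
The 2×2 mixed ANOVA (within: valence; between: source) is delegated to
pingouin and cross-checked in the tests against hand-computed balanced
sums-of-squares identities; the covariate-adjusted control analysis
residualizes the dependent variable on per-subject covariates first.
Zero-variance inputs raise explicit errors rather than returning NaNs.

## Validation sizes and known limitations

Recovery is validated on five replicate 50-subject cohorts at 126 trials
(averaging across replicates to suppress Monte-Carlo noise in the measured
bias: a single cohort's group-mean fitted β has an SE of ≈0.035 from
estimation noise alone, comparable to the ±0.05 band being checked).
Model-selection consistency uses 36-subject cohorts; the shared-aversion
regime is selected essentially always, but the valence-specific regime is
*not* reliably selected at 126 trials: the mean per-subject likelihood-ratio
statistic between the two models plateaus at ≈3.9–4.3 nats across all
plausible calibrations, below the per-subject BIC penalty difference
ln(126) ≈ 4.84, so group BIC prefers the shared model for most simulated
cohorts.  This is an information limit of the design size, not an optimizer
failure (verified against multistart controls and the Fisher information),
and it is reported as measured.  The gap closes at larger designs, since
the BIC penalty grows only logarithmically in the trial count while the
likelihood-ratio information grows linearly.

The bootstrap CI coverage check (100 replications × 200 iterations) and
the model-selection runs dominate the test-suite runtime; the acceptance
script uses 10 cohorts per selection regime as its standard report size.
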