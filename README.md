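# paytoknow

Analysis toolkit for the **pay-to-know choice task**, in which people trade
token payoffs against the opportunity to learn evaluations of themselves
(from other people, or from a computer program).  On each of 126 trials a
trait word is shown and the subject chooses between a "to-know" (TK) and a
"not-to-know" (NTK) option whose payoffs differ by Δm ∈ {−3…3} tokens.
The package is for researchers who want to quantify how much knowing is
worth: it provides the task data model, model-free indices, psychometric
estimation of the point of subjective equivalence (PSE), a family of
softmax-lapse value models with maximum-likelihood fitting and group-BIC
comparison, the classical test battery, and a synthetic-cohort generator
with known ground truth so every stage is testable without any
experimental data.

## The model

The value of knowing relative to not knowing is

```
ΔV = α·Δm + β_v          P(TK) = (1 − 2ε)·σ(γ·ΔV) + ε
```

where β_v ∈ [−1, 1] is the *unknown aversion* — the subjective cost of not
knowing — either shared across trait valences or split into β_pos / β_neg;
γ is the softmax inverse temperature and ε a symmetric lapse rate.
Variants add temporal discounting of the value of knowing or loss-averse
money utility.  Because only (γα, γβ, ε) are identified, fitting pins
α = 1, so fitted β is in token units and −β is the model's exact
indifference point.  Model-free, the same quantity is estimated as the PSE
of a four-parameter sigmoid fitted to the knowing ratio against Δm, with a
200-iteration subject-level bootstrap for group estimates and contrasts.
Per-subject models are compared by summed (group) BIC.

## Worked example

```python
from paytoknow import (CohortConfig, simulate_cohort, run_analysis,
                       PipelineConfig, render_markdown)

data, truth = simulate_cohort(CohortConfig(n_subjects=12, cohort_seed=2,
                                           schedule_seed=2))
report = run_analysis(data, PipelineConfig(seed=1, n_boot=50, n_starts=5))
print(render_markdown(report))
```

prints (abridged):

```
# Pay-to-know analysis report

Subjects: 12, trials: 1512

## Model-free indices

- overall knowing ratio: 0.5271
- knowing ratio (negative): 0.5185
- knowing ratio (positive): 0.5357
- knowing ratio vs 50%: t(11) = 2.45, p = 0.0323, d = 0.71

## Point of subjective equivalence (bootstrap)

- PSE[positive]: -0.430 tokens (95% CI -0.866 to -0.092)
- PSE[negative]: -0.175 tokens (95% CI -0.428 to 0.008)
- PSE[all]: -0.309 tokens (95% CI -0.481 to -0.072)
- PSE[positive_minus_negative]: -0.258 tokens (95% CI -0.845 to 0.062, n.s.)

## Model comparison (group BIC)

- valence_specific: 1220.1
- shared_beta: 1197.0 <- winner
- winning-model mean in-sample accuracy: 0.8737
```

Reading it: these twelve simulated subjects chose to know more often than
chance and effectively paid ≈0.3 tokens per trial for the opportunity
(negative PSE = paying to know), with a larger price for positive-trait
evaluations; at n = 12 the valence gap is not yet significant and the
parsimonious shared-aversion model wins the BIC comparison — the valence
effect needs a larger sample to justify its extra parameter.  The
same pipeline is available from the shell:

```
paytoknow simulate --out sim --seed 3 --n-subjects 36
paytoknow analyze sim/cohort.csv --out results --seed 1
```

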