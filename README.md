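# fetchstats

Statistics for small-N forced-choice **fetch tasks**: experiments in which a
word-trained subject (here, label-experienced Border Collies) hears a novel
label during a naming phase and must then retrieve the labelled object from
a small array. Every published result in this paradigm is a function of a
handful of printed counts — *k* correct retrievals out of *n* trials — so
the entire analysis is reproducible from those counts alone, provided the
statistical conventions (chance level, tail handling, treatment of failed
trials, Monte-Carlo procedure) are made explicit. This package makes them
explicit, implements them, and stress-tests them with agent-based
simulation.

It is written for comparative-cognition researchers and statisticians who
want to (a) re-run or audit this family of analyses, (b) simulate the three
experiment designs under competing learner models, and (c) quantify what a
24- or 28-trial single-subject design can and cannot detect.

## The statistics

**Monte-Carlo chance null for the mean-attempts statistic.** On each trial a
chance agent draws objects sequentially without replacement until it finds
the target, so its attempt index is uniform on `1..N` for an `N`-object
array. A run of `n` trials yields a mean attempt index `X̄`; the null
distribution of `X̄` is simulated with 10,000 replicate runs (and available
exactly, by convolving the uniform pmf). The p-value is

> p = P( X̄_sim ≤ X̄_obs ),  ties included.

A real subject stops after `max_attempts`; under the default failure policy
a failed trial is assigned attempt index `N` (the target would have been
found on the forced last draw), which puts subject and simulation on the
same scale.

**Exact binomial tests with explicit tails.** One-tailed p-values are the
smaller exact tail, `min(P(X ≥ k), P(X ≤ k))` under `Binomial(n, p0)`;
two-tailed p-values double the smaller tail and cap at 1. The
3-alternative chance level defaults to the reporting convention `p0 = 0.33`
(pass `1/3` explicitly for the unrounded value); 2-alternative analyses use
`p0 = 0.5`.

**Pearson chi-square for 2×2 tables**, no continuity correction, `df = 1`.

**Agent models** (`random`, `knower`, `associative`, `enhancement`,
`learner`, `weighted`) generate synthetic trial records for all three
designs, with counterbalanced, constraint-checked schedules; `power`
estimates type-I error and power of any of the pipeline's tests under these
agents.

## Worked example

```python
from fetchstats import (FailurePolicy, build_null, design_for, exact_p,
                        mc_p, observed_mean_attempts, paper_fixture)

design = design_for("exp1")                      # 24 trials, 3 objects, 2 attempts
records = paper_fixture()["Paddy", "exp1"]       # trial records from printed counts
observed = observed_mean_attempts(records, design, FailurePolicy())
null = build_null(24, 3, n_sims=10_000, seed=42)
print(f"{observed:.4f}", f"{mc_p(observed, null):.4f}", f"{exact_p(observed, 24, 3):.4f}")
```

prints

```
1.5833 0.0079 0.0082
```

— the observed mean attempt index (38/24, against a chance expectation of
2.0), the simulated probability of a chance run at least that efficient,
and the same probability by exact enumeration. A two-line follow-up gives
the first-attempt binomial:

```python
from fetchstats import binom_pvalue
binom_pvalue(12, 24, 0.33, tail="smaller").p_value   # 0.0631
```

The `examples/` directory has one short script per capability (chance
null, tail conventions, agent simulation, full reproduction, power), and
the `fetchstats` CLI exposes the same operations
(`fetchstats paper-repro`, `fetchstats binom --k 12 --n 24 --p0 0.33`,
`fetchstats simulate --experiment 3 --seed 4 -o trials.csv`, ...).

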