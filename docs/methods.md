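# Methods

## The designs

Three single-subject, forced-choice retrieval designs are modelled. Each
trial has a naming phase (a novel label is produced while the owner directs
referential behaviour at a hidden or visible target) and a requesting phase
(the subject must fetch the labelled object from an array in another room).

* **exp1** — 24 trials, 3 objects hidden in buckets during naming, 3
  objects at request, up to 2 retrieval attempts per trial. Analysis chance
  level 0.33.
* **exp2** — 24 trials, two labelled targets each paired with a distracter
  during naming; 4 objects at request (target, labelled non-target, two
  distracters), chance 0.5 for the two-labelled-objects analysis. A return
  with no object consumes an attempt slot (role `none`) but removes nothing
  from the array; two slots are allowed.
* **exp3** — 28 trials, 2 objects, one occluded behind a barrier during
  naming; in half the trials the named target is the occluded one. One
  attempt; chance 0.5.

Trial records store object **roles** (target / labelled non-target /
distracter / none), not identities: every analysis implemented here is a
function of roles. Trial indices are 1-based; the "first 12 / last 12"
windows are trials 1–12 and (n−11)–n, so with 28 trials the middle 4 trials
belong to neither window.

## The mean-attempts chance null

Under chance, sequential draws without replacement make the target's
attempt index uniform on `1..set_size` (each of the `set_size!` orderings is
equally likely and each position holds the target in exactly
`(set_size−1)!` of them). The null of the per-run mean is therefore the
mean of `n_trials` iid uniforms. `build_null` simulates it by drawing the
attempt indices directly from that uniform (vectorized over all
`n_sims × n_trials` trials); `sample_attempt_index` performs the literal
shuffle-and-find draw and is tested against the enumeration argument.
`exact_sum_pmf` convolves the uniform pmf `n_trials` times and is the
oracle for every Monte-Carlo p-value; its support is
`n_trials..n_trials·set_size` and its mean `n_trials(set_size+1)/2`.

The p-value counts simulations with mean attempts **as small as or
smaller** than observed (ties reject). Default `n_sims` is 10,000 with a
fixed documented seed (20140319); both are overridable everywhere.

**Failure policy.** The simulated chance agent keeps drawing until it finds
the target; a real subject stops after `max_attempts` (2 in exp1). The
default policy (`assign_set_size`) scores a failed trial as attempt index
`set_size` — with 3 objects and 2 failed attempts, the target is
deterministically the remaining object, so this is the forced third draw
rather than an imputation. It is the only policy under which observed and
simulated runs live on the same scale, and it reproduces the published
Monte-Carlo p-values that are reproducible at all (see Limitations).
`exclude` and `assign_max_attempts` are provided for sensitivity analysis;
reports always print the policy used.

## Tail conventions

* One-tailed: the smaller exact binomial tail (the tail containing `k`).
* Two-tailed: twice the smaller tail, capped at 1. This — not the
  minimum-likelihood definition — reproduces the published two-tailed
  values; `two_sided_minlike` is available but never the default.
* 3-alternative chance level: `0.33` exactly, matching the convention of
  rounding chance before testing (with `p0 = 1/3` the 12/24 upper tail is
  0.0677 rather than the printed 0.063). `1/3` can be passed explicitly.
* Chi-square: Pearson, no continuity correction, df = 1; undefined (raises)
  on a zero margin.
* Every report carries a conventions block (chance level, tail, failure
  policy, seed, n_sims, window) sufficient to recompute its numbers.

## The packaged fixture

`paper_fixture()` reconstructs trial-level records from the published
per-subject counts: exp1 first-attempt/overall counts per run (second-
attempt successes are overall minus first-attempt; failures are 24 minus
overall), exp2 per-pair correct counts plus the 4 labelled-non-target
errors, exp3 per-condition and first/last-window counts. Counts fix
aggregates, not trial order; unconstrained placement is deterministic:
successes earliest-first, and for exp3 an alternating open/occluded
schedule (6/6 per window, 2/2 in the gap) with a lower-bound-aware
earliest-first split of each window's successes between conditions so that
overall, per-condition and windowed counts are all met simultaneously.
Analyses are order-invariant, so this choice cannot affect any statistic;
it only makes the fixture reproducible byte-for-byte.

## Agent models

`choice_distribution` maps an agent and a trial context to a probability
vector over the array:

* `random` — uniform (the chance model).
* `knower` — mass `theta` on the true referent, remainder uniform. `theta`
  is exactly the first-attempt success probability, so the moment estimator
  `first_attempt_correct / n` recovers it; an optional per-pair `theta`
  models asymmetric learning of the two exp2 pairs.
* `associative` — mass `theta` on the object visible during naming; uniform
  when nothing was visible (exp1/exp2 naming happens in buckets). In exp3
  this yields ~14/14 vs ~0/14 across conditions at `theta = 1` — at chance
  overall, the dissociation that separates association from referential
  learning.
* `enhancement` — probabilities proportional to `1 + w` on the attended
  location's object and `1` elsewhere; a low-level salience account.
* `learner` — a knower whose accuracy ramps logistically over trial index
  from `theta_start` to `theta_end` with slope `rate`, centered on the
  middle trial; models within-study acquisition (improving last-window
  performance with flat per-condition structure).
* `weighted` — explicit per-role weights for hypothetical strategies.

Second attempts renormalize the first-attempt distribution over the
remaining objects: the agent keeps no memory of the refusal. Schedules come
from `generate_schedule`, which rejection-samples balanced sequences until
the constraint checker passes (positions counterbalanced; exp3 conditions
exactly 14/14; exp2 pairs 12/12 with no pair in more than 2 consecutive
trials) and raises after a bounded retry budget.

What the simulators emulate is the *design and the choice process*, not dog
cognition: no fatigue, no memory decay, no label phonology, no session
structure. Passing tests show the statistics behave correctly under these
generative models; they say nothing about which model describes real dogs.

## Power and calibration

`estimate_type1` and `power_curve` replicate a whole study per repetition —
simulate records, run the chosen pipeline test, reject at `p ≤ alpha` (ties
reject, matching the null's tie handling). The Experiment-1 Monte-Carlo
test is replicated in full, building a fresh 10,000-sample null per
replicate, so the calibration includes the null's own simulation noise.
Because the statistics are discrete, exact tests are conservative: the
achievable p-values of the 24-trial mean-attempts null nearest 0.05 are
0.0299 (sum ≤ 40) and 0.0518 (sum ≤ 41), so the true type-I error at
α = 0.05 is just below 0.03 for the exact test and near 0.035 once
Monte-Carlo noise in the null smooths the boundary. Default problem sizes
(2,000 replicates for calibration, 500 per power point) keep Monte-Carlo
standard errors below ~0.005 while remaining desk-scale.

## Numerical choices

* Mean-attempts ties: `samples ≤ observed + 1e-9` (all achievable means are
  multiples of `1/n_trials`, so the epsilon only absorbs float rounding);
  the exact p thresholds at `⌊observed·n_trials + 1e-9⌋` and clips to 1 at
  the top of the support.
* The exact pmf is renormalized after convolution to absorb accumulated
  rounding; dense convolution is refused above 10^6 support points.
* Seeds: every stochastic routine takes an explicit seed; derived seeds are
  drawn below 2^31 from a `numpy` Generator seeded with the caller's seed.
* Degenerate inputs raise `ValidationError` with the violated rule named
  (empty record sets after exclusion, zero chi-square margins, unsatisfiable
  schedules, `n_reps < 100` power estimates).

## Known limitations

* Two published Experiment-1 Monte-Carlo p-values (Arco run 1, printed
  .4215; Joey run 1, printed .3002) are not reproducible from the printed
  counts under any failure policy (exact values .3545 and .2669 under the
  default); the original handling of those runs — possibly no-object
  returns — is not recoverable from the counts. They are reported under the
  documented convention, without adjustment. Betsy run 1 (.1895), Joey
  run 2 (.0826), and the run-2 values for Arco/Betsy are reproduced within
  Monte-Carlo error.
* The Experiment-2 "labelled non-target among incorrect retrievals" test
  has no principled chance level derivable from the design; the default
  `p0 = 1/3` (three non-target objects) is a convention and the result is
  flagged as such in reports.
* How no-object returns entered the published Experiment-2 totals is
  unknown; encoding them as attempt-consuming `none` roles is this
  package's convention and is stated in reports that depend on it.
* Fixture records are reconstructions constrained only by published
  aggregates; any statistic sensitive to trial order beyond the windowed
  counts would not be meaningful on them.
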