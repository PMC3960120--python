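"""Type-I error and power of the fetch-task tests under agent models.

Each estimate simulates many replicate studies of a given design under an
agent (random for type-I error, a knower with accuracy theta for power),
runs the chosen test on each replicate, and reports the rejection rate at
level alpha with its Monte-Carlo standard error. Rejection compares
``p <= alpha`` (ties reject), matching the tie handling of the chance-null
p-value itself. Because the tests are exact/discrete, type-I error is
typically a little below alpha.

The Experiment-1 Monte-Carlo test is replicated in full: each simulated
study gets its own freshly simulated null distribution, exactly as a real
analysis would build one, so the calibration reflects both the discreteness
of the statistic and the Monte-Carlo noise of the null itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .agents import AgentSpec, simulate
from .chance_null import FailurePolicy, build_null, mc_p, observed_mean_attempts
from .exact_tests import CHANCE_2ALT, CHANCE_3ALT, binom_pvalue
from .trial_model import ExperimentDesign, TrialRecord, ValidationError, design_for

#: pipeline analyses usable as rejection tests, keyed by label
TEST_LABELS = (
    "exp1_mc",
    "exp1_first_binomial",
    "exp2_overall_binomial",
    "exp3_overall_binomial",
)


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection rate of one test under one agent, with Monte-Carlo SE."""

    test: str
    experiment: str
    theta: float | None
    alpha: float
    n_reps: int
    seed: int
    rejection_rate: float
    mc_se: float


def _pvalue_fn(
    test: str, design: ExperimentDesign, n_sims: int
) -> Callable[[Sequence[TrialRecord], int], float]:
    if test == "exp1_mc":
        policy = FailurePolicy()

        def p_mc(records: Sequence[TrialRecord], null_seed: int) -> float:
            null = build_null(
                design.n_trials, design.set_size, n_sims=n_sims, seed=null_seed
            )
            return mc_p(observed_mean_attempts(records, design, policy), null)

        return p_mc
    if test == "exp1_first_binomial":
        return lambda records, _seed: binom_pvalue(
            sum(r.first_attempt_success for r in records), len(records),
            CHANCE_3ALT, tail="smaller",
        ).p_value
    if test in ("exp2_overall_binomial", "exp3_overall_binomial"):
        return lambda records, _seed: binom_pvalue(
            sum(r.success for r in records), len(records),
            CHANCE_2ALT, tail="two_sided_double",
        ).p_value
    raise ValidationError(f"unknown test {test!r}; choose from {TEST_LABELS}")


def _experiment_of(test: str) -> str:
    return test.split("_", 1)[0]


def rejection_rate(
    test: str,
    agent: AgentSpec,
    design: ExperimentDesign | None,
    alpha: float,
    n_reps: int,
    seed: int,
    n_sims: int = 10_000,
) -> PowerEstimate:
    """Rejection rate of ``test`` at level ``alpha`` under ``agent``."""
    if n_reps < 100:
        raise ValidationError("n_reps < 100 gives a meaningless estimate")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    if test not in TEST_LABELS:
        raise ValidationError(f"unknown test {test!r}; choose from {TEST_LABELS}")
    experiment = _experiment_of(test)
    design = design or design_for(experiment)
    rng = np.random.default_rng(seed)
    pfn = _pvalue_fn(test, design, n_sims=n_sims)
    rejections = 0
    for _ in range(n_reps):
        records = simulate(experiment, agent, design, int(rng.integers(2**31)))
        if pfn(records, int(rng.integers(2**31))) <= alpha:
            rejections += 1
    rate = rejections / n_reps
    theta = agent.theta if agent.kind in ("knower", "learner") else None
    return PowerEstimate(
        test=test,
        experiment=experiment,
        theta=theta,
        alpha=alpha,
        n_reps=n_reps,
        seed=seed,
        rejection_rate=rate,
        mc_se=float(np.sqrt(rate * (1 - rate) / n_reps)),
    )


def estimate_type1(
    test: str,
    design: ExperimentDesign | None = None,
    alpha: float = 0.05,
    n_reps: int = 2000,
    seed: int = 0,
    n_sims: int = 10_000,
) -> PowerEstimate:
    """Type-I error: rejection rate under the random (chance) agent."""
    return rejection_rate(
        test, AgentSpec(kind="random"), design, alpha, n_reps, seed, n_sims=n_sims
    )


def power_curve(
    test: str,
    thetas: Sequence[float],
    design: ExperimentDesign | None = None,
    alpha: float = 0.05,
    n_reps: int = 500,
    seed: int = 0,
    n_sims: int = 10_000,
) -> list[PowerEstimate]:
    """Power against knower agents of increasing accuracy.

    One estimate per theta; each theta gets its own derived seed so the
    curve is deterministic for a fixed top-level seed.
    """
    rng = np.random.default_rng(seed)
    return [
        rejection_rate(
            test,
            AgentSpec(kind="knower", theta=theta),
            design,
            alpha,
            n_reps,
            int(rng.integers(2**31)),
            n_sims=n_sims,
        )
        for theta in thetas
    ]
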