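"""Monte-Carlo chance model for the mean-attempts statistic.

The chance model: on each trial an indifferent agent picks objects from the
array one after the other, without replacement, until it finds the target.
The attempt index at which the target turns up is then uniform on
``1..set_size`` (every ordering of the objects is equally likely), so a run
of ``n_trials`` trials yields a mean attempt index whose null distribution
is the mean of ``n_trials`` iid uniforms. We provide both the simulated
(Monte-Carlo) null — 10,000 replicate runs by default — and its exact twin
via dense convolution of the uniform pmf, which serves as an oracle.

Observed runs need a convention for failed trials (the real subject stops
after ``max_attempts``; the simulated agent never stops). The default policy
assigns a failed trial the attempt index ``set_size``, i.e. treats the
target as found on the forced last draw — the only reading that puts subject
and simulation on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .trial_model import ExperimentDesign, TrialRecord, ValidationError

DEFAULT_N_SIMS = 10_000
DEFAULT_SEED = 20140319

FailureMode = Literal["assign_set_size", "exclude", "assign_max_attempts"]


@dataclass(frozen=True)
class FailurePolicy:
    """How a trial where the target was never retrieved enters the mean."""

    mode: FailureMode = "assign_set_size"

    def __post_init__(self) -> None:
        if self.mode not in ("assign_set_size", "exclude", "assign_max_attempts"):
            raise ValidationError(f"unknown failure policy {self.mode!r}")


@dataclass(frozen=True)
class NullDistribution:
    """Null distribution of the per-run mean attempt index.

    ``kind='monte_carlo'``: ``samples`` holds ``n_sims`` simulated means.
    ``kind='exact'``: ``pmf`` holds the distribution of the *sum* of attempt
    indices on support ``n_trials .. n_trials*set_size``.
    """

    n_trials: int
    set_size: int
    kind: Literal["monte_carlo", "exact"]
    n_sims: int | None = None
    seed: int | None = None
    samples: np.ndarray | None = None
    pmf: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "monte_carlo":
            if self.samples is None or len(self.samples) != self.n_sims:
                raise ValidationError("monte_carlo null needs n_sims samples")
        elif self.kind == "exact":
            if self.pmf is None:
                raise ValidationError("exact null needs a pmf")
            if abs(float(np.sum(self.pmf)) - 1.0) > 1e-12:
                raise ValidationError("exact pmf must sum to 1")
        else:
            raise ValidationError(f"unknown null kind {self.kind!r}")

    @property
    def support(self) -> np.ndarray:
        """Achievable sums of attempt indices (exact kind)."""
        return np.arange(self.n_trials, self.n_trials * self.set_size + 1)


def sample_attempt_index(set_size: int, rng: np.random.Generator) -> int:
    """Attempt index at which sequential no-replacement draws hit the target.

    Simulated literally: shuffle the ``set_size`` objects and report the
    1-based position of the target in the draw order.
    """
    if set_size < 1:
        raise ValidationError("set_size must be >= 1")
    order = rng.permutation(set_size)
    return int(np.nonzero(order == 0)[0][0]) + 1


def build_null(
    n_trials: int,
    set_size: int,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = DEFAULT_SEED,
) -> NullDistribution:
    """Simulate the Monte-Carlo null of the per-run mean attempt index.

    Uses the uniformity of the attempt index (see module docstring) to draw
    all ``n_sims * n_trials`` trial outcomes vectorized; reproducible for a
    fixed seed.
    """
    if n_trials < 1 or set_size < 1 or n_sims < 1:
        raise ValidationError("n_trials, set_size and n_sims must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.integers(1, set_size + 1, size=(n_sims, n_trials))
    return NullDistribution(
        n_trials=n_trials,
        set_size=set_size,
        kind="monte_carlo",
        n_sims=n_sims,
        seed=seed,
        samples=draws.mean(axis=1),
    )


def exact_sum_pmf(n_trials: int, set_size: int) -> NullDistribution:
    """Exact pmf of the sum of attempt indices by iterated convolution."""
    if n_trials < 1 or set_size < 1:
        raise ValidationError("n_trials and set_size must be positive")
    if n_trials * set_size > 10**6:
        raise ValidationError("support too large for dense convolution")
    unit = np.full(set_size, 1.0 / set_size)
    pmf = np.array([1.0])
    for _ in range(n_trials):
        pmf = np.convolve(pmf, unit)
    pmf /= pmf.sum()  # renormalize away accumulated rounding
    return NullDistribution(
        n_trials=n_trials, set_size=set_size, kind="exact", pmf=pmf
    )


def observed_mean_attempts(
    records: Sequence[TrialRecord],
    design: ExperimentDesign,
    policy: FailurePolicy = FailurePolicy(),
) -> float:
    """Mean attempt index of the target over a subject's trials.

    Successful trials contribute their ``success_attempt``; failed trials are
    handled by ``policy`` (assigned ``set_size``, assigned ``max_attempts``,
    or excluded from numerator and denominator).
    """
    values: list[int] = []
    for r in records:
        if r.success_attempt is not None:
            values.append(r.success_attempt)
        elif policy.mode == "assign_set_size":
            values.append(design.set_size)
        elif policy.mode == "assign_max_attempts":
            values.append(design.max_attempts)
        # exclude: skip
    if not values:
        raise ValidationError("no trials left after applying the failure policy")
    return float(np.mean(values))


def mc_p(observed: float, null: NullDistribution) -> float:
    """P(mean attempts as small as or smaller than observed) under the null.

    Ties count as extreme. For an exact null this is
    ``P(sum <= observed * n_trials)``.
    """
    if null.kind == "monte_carlo":
        assert null.samples is not None
        return float(np.mean(null.samples <= observed + 1e-9))
    assert null.pmf is not None
    threshold = int(np.floor(observed * null.n_trials + 1e-9))
    if threshold >= int(null.support[-1]):
        return 1.0
    return float(np.sum(null.pmf[null.support <= threshold]))


def exact_p(observed: float, n_trials: int, set_size: int) -> float:
    """Closed-form twin of :func:`mc_p` via the exact sum pmf."""
    return mc_p(observed, exact_sum_pmf(n_trials, set_size))
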