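"""Agent-based simulators for the three fetch-task designs.

Each agent is a generative model of how a subject picks an object at request
time, formalizing the competing explanations of fetch-task performance:

* ``random`` — indifferent chooser (the chance model).
* ``knower`` — maps the label to its true referent with accuracy ``theta``,
  regardless of whether the referent was visible during naming; the
  remaining mass is uniform over the other objects.
* ``associative`` — maps the label to whatever object was *visible* during
  naming; with the target occluded it therefore prefers the wrong object.
  Where nothing was visible during naming it falls back to uniform.
* ``enhancement`` — low-level local enhancement of the attended location:
  mixes a uniform choice with extra weight ``w`` on the object whose
  location the owner attended (probabilities proportional to 1 + w there).
* ``learner`` — a knower whose accuracy follows a logistic ramp over trial
  index from ``theta_start`` to ``theta_end`` at slope ``rate`` (centered on
  the middle trial), modelling within-study acquisition of the task.
* ``weighted`` — explicit per-role weights; a convenience for constructing
  hypothetical strategies (e.g. all mass on the labelled objects).

Simulators draw the first attempt from the agent's choice distribution and
any further attempt from the same distribution renormalized over the
remaining objects (the agent keeps no memory of why the first fetch was
refused); they emit validated :class:`~fetchstats.trial_model.TrialRecord`
lists and are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trial_model import (
    ExperimentDesign,
    TrialRecord,
    TrialSetting,
    ValidationError,
    generate_schedule,
)

AGENT_KINDS = ("random", "knower", "associative", "enhancement", "learner", "weighted")

#: Cosmetic vocabulary for generated trials, styled on the novel labels used
#: with label-trained dogs (phonologically distinctive nonsense/loan words).
LABEL_VOCABULARY = (
    "Gysi", "Hot Dog", "Gluehbirne", "Bruno", "Lumpi", "Beetle", "Spirale",
    "Muente", "Heini", "Spektrum", "Snutig", "Boomer", "Harlikin", "Petzi",
    "Topolino", "Neopren", "Alfons", "Schrubka", "Titifax", "Columbus",
    "Klecksi", "Propeller", "Tantalus", "Arabella", "Torpedo", "Schokodrop",
    "Knautschli", "Rabe", "Miranda", "August",
)


@dataclass(frozen=True)
class AgentSpec:
    """Generative learner model used by the simulators."""

    kind: str = "random"
    theta: float = 0.5
    w: float = 0.0
    theta_start: float = 0.5
    theta_end: float = 0.5
    rate: float = 1.0
    theta_by_pair: Mapping[int, float] | None = None
    role_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValidationError(f"unknown agent kind {self.kind!r}")
        for name in ("theta", "theta_start", "theta_end"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.w < 0:
            raise ValidationError("enhancement weight w must be >= 0")
        if self.kind == "weighted" and not self.role_weights:
            raise ValidationError("weighted agent needs role_weights")

    def accuracy_at(self, trial_index: int, n_trials: int) -> float:
        """Knower accuracy at a given trial (logistic ramp for learners)."""
        if self.kind != "learner":
            return self.theta
        mid = (n_trials + 1) / 2.0
        ramp = 1.0 / (1.0 + np.exp(-self.rate * (trial_index - mid)))
        return self.theta_start + (self.theta_end - self.theta_start) * float(ramp)


@dataclass(frozen=True)
class ChoiceContext:
    """What the agent knows when choosing: the array and the naming history."""

    roles: tuple[str, ...]  # role of the object at each array slot
    condition: str = "default"
    trial_index: int = 1
    n_trials: int = 1
    pair: int | None = None
    visible_role: str | None = None  # role of the object visible during naming
    attended_slot: int | None = None  # array slot whose location was attended


def _spread(theta: float, focus: Sequence[bool]) -> np.ndarray:
    """theta mass spread over focus slots, remainder uniform over the rest."""
    focus_arr = np.asarray(focus, dtype=bool)
    n, k = len(focus_arr), int(focus_arr.sum())
    probs = np.empty(n)
    if k == 0 or k == n:
        return np.full(n, 1.0 / n)
    probs[focus_arr] = theta / k
    probs[~focus_arr] = (1.0 - theta) / (n - k)
    return probs


def choice_distribution(agent: AgentSpec, context: ChoiceContext) -> np.ndarray:
    """Probability vector over the available objects for one trial."""
    roles = context.roles
    n = len(roles)
    if n < 2:
        raise ValidationError("a choice needs at least 2 objects")
    if agent.kind == "random":
        return np.full(n, 1.0 / n)
    if agent.kind in ("knower", "learner"):
        theta = agent.accuracy_at(context.trial_index, context.n_trials)
        if agent.kind == "knower" and agent.theta_by_pair and context.pair is not None:
            theta = agent.theta_by_pair.get(context.pair, theta)
        return _spread(theta, [r == "target" for r in roles])
    if agent.kind == "associative":
        if context.visible_role is None:
            return np.full(n, 1.0 / n)
        return _spread(agent.theta, [r == context.visible_role for r in roles])
    if agent.kind == "enhancement":
        weights = np.ones(n)
        if context.attended_slot is not None:
            weights[context.attended_slot] += agent.w
        return weights / weights.sum()
    if agent.kind == "weighted":
        assert agent.role_weights is not None
        weights = np.array([float(agent.role_weights.get(r, 0.0)) for r in roles])
        if weights.sum() <= 0:
            raise ValidationError("role_weights assign no mass to any available role")
        return weights / weights.sum()
    raise ValidationError(f"unknown agent kind {agent.kind!r}")


def _run_trial(
    agent: AgentSpec,
    context: ChoiceContext,
    max_attempts: int,
    rng: np.random.Generator,
) -> tuple[tuple[str, ...], int | None]:
    """Draw up to ``max_attempts`` choices; later draws renormalize over
    the remaining objects."""
    base = choice_distribution(agent, context)
    available = list(range(len(context.roles)))
    attempts: list[str] = []
    success: int | None = None
    for attempt in range(1, max_attempts + 1):
        probs = base[available]
        probs = probs / probs.sum()
        slot = available[rng.choice(len(available), p=probs)]
        attempts.append(context.roles[slot])
        available.remove(slot)
        if context.roles[slot] == "target":
            success = attempt
            break
        if not available:
            break
    return tuple(attempts), success


def _require(design: ExperimentDesign, experiment: str) -> None:
    if design.experiment != experiment:
        raise ValidationError(
            f"design is for {design.experiment}, simulator is for {experiment}"
        )


def _labels(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(LABEL_VOCABULARY), size=n)
    return [LABEL_VOCABULARY[i] for i in idx]


def simulate_exp1(
    agent: AgentSpec,
    design: ExperimentDesign,
    seed: int,
    subject_id: str = "sim",
) -> list[TrialRecord]:
    """Three objects named in buckets; request among 3; second attempt allowed."""
    _require(design, "exp1")
    rng = np.random.default_rng(seed)
    schedule = generate_schedule(design, int(rng.integers(2**31)))
    labels = _labels(rng, design.n_trials)
    records = []
    for setting, label in zip(schedule, labels):
        roles = ("target",) + ("distracter",) * (design.set_size - 1)
        context = ChoiceContext(
            roles=roles,
            trial_index=setting.trial_index,
            n_trials=design.n_trials,
            visible_role=None,  # objects stay hidden during naming
            attended_slot=0,  # owner attends the target's bucket
        )
        attempts, success = _run_trial(agent, context, design.max_attempts, rng)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                experiment="exp1",
                trial_index=setting.trial_index,
                set_size=design.set_size,
                requested_label=label,
                attempts=attempts,
                success_attempt=success,
            )
        )
    return records


def simulate_exp2(
    agent: AgentSpec,
    design: ExperimentDesign,
    seed: int,
    subject_id: str = "sim",
) -> list[TrialRecord]:
    """Two labelled targets plus two distracters; four objects at request."""
    _require(design, "exp2")
    rng = np.random.default_rng(seed)
    schedule = generate_schedule(design, int(rng.integers(2**31)))
    labels = _labels(rng, design.n_trials)
    records = []
    for setting, label in zip(schedule, labels):
        roles = ("target", "labelled_nontarget", "distracter", "distracter")
        context = ChoiceContext(
            roles=roles,
            trial_index=setting.trial_index,
            n_trials=design.n_trials,
            pair=setting.pair,
            visible_role=None,
            attended_slot=0,
        )
        attempts, success = _run_trial(agent, context, 1, rng)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                experiment="exp2",
                trial_index=setting.trial_index,
                set_size=design.set_size,
                requested_label=label,
                pair=setting.pair,
                attempts=attempts,
                success_attempt=success,
            )
        )
    return records


def simulate_exp3(
    agent: AgentSpec,
    design: ExperimentDesign,
    seed: int,
    subject_id: str = "sim",
) -> list[TrialRecord]:
    """Two objects, one occluded during naming in half the trials."""
    _require(design, "exp3")
    rng = np.random.default_rng(seed)
    schedule = generate_schedule(design, int(rng.integers(2**31)))
    labels = _labels(rng, design.n_trials)
    records = []
    for setting, label in zip(schedule, labels):
        roles = ("target", "distracter")
        visible = "target" if setting.condition == "target_open" else "distracter"
        context = ChoiceContext(
            roles=roles,
            condition=setting.condition,
            trial_index=setting.trial_index,
            n_trials=design.n_trials,
            visible_role=visible,
            attended_slot=0,  # the owner names (attends) the target
        )
        attempts, success = _run_trial(agent, context, design.max_attempts, rng)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                experiment="exp3",
                trial_index=setting.trial_index,
                set_size=design.set_size,
                condition=setting.condition,
                requested_label=label,
                attempts=attempts,
                success_attempt=success,
            )
        )
    return records


SIMULATORS = {"exp1": simulate_exp1, "exp2": simulate_exp2, "exp3": simulate_exp3}


def simulate(
    experiment: str,
    agent: AgentSpec,
    design: ExperimentDesign,
    seed: int,
    subject_id: str = "sim",
) -> list[TrialRecord]:
    try:
        sim = SIMULATORS[experiment]
    except KeyError:
        raise ValidationError(f"unknown experiment {experiment!r}") from None
    return sim(agent, design, seed, subject_id=subject_id)
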