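"""Domain model for fetch-task trials.

A *trial* is one naming-then-retrieval episode: a label is introduced for a
target object and the subject is then asked to fetch it from a small array.
The subject may get one or more retrieval attempts; each attempt is recorded
as the *role* of the chosen object (target, labelled non-target, distracter,
or ``none`` when the subject returned without any object), not its identity —
the analyses only ever distinguish roles.

This module provides the record and design types, CSV round-tripping,
subject-level summarization (overall / first-attempt / per-condition /
windowed correct counts), and a constrained schedule generator for the three
experiment designs.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

EXPERIMENTS = ("exp1", "exp2", "exp3")
CONDITIONS = ("default", "target_open", "target_occluded")
ROLES = ("target", "labelled_nontarget", "distracter", "none")

#: sub-list delimiter inside the ``attempts`` CSV column
ATTEMPTS_SEP = ";"

_CSV_COLUMNS = [
    "subject_id",
    "experiment",
    "trial_index",
    "set_size",
    "condition",
    "requested_label",
    "attempts",
    "success_attempt",
    "pair",
]


class ValidationError(ValueError):
    """A record or schedule violates a model invariant."""


class ParseError(ValueError):
    """A tabular source could not be interpreted as trial records."""


@dataclass(frozen=True)
class TrialRecord:
    """One experimental trial: design context plus ordered retrieval attempts.

    ``attempts`` holds the role of the object chosen at each attempt, in
    order. ``success_attempt`` is the 1-based attempt index at which the
    target was retrieved, or ``None`` if it never was.
    """

    subject_id: str
    experiment: str
    trial_index: int
    set_size: int
    condition: str = "default"
    requested_label: str = ""
    attempts: tuple[str, ...] = ()
    success_attempt: int | None = None
    pair: int | None = None  # exp2: which labelled pair was requested

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValidationError(f"unknown experiment {self.experiment!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.experiment != "exp3" and self.condition != "default":
            raise ValidationError(
                "open/occluded conditions only apply to exp3 "
                f"(got {self.condition!r} for {self.experiment})"
            )
        if self.trial_index < 1:
            raise ValidationError("trial_index is 1-based and must be >= 1")
        if self.set_size < 2:
            raise ValidationError("set_size must be >= 2")
        for role in self.attempts:
            if role not in ROLES:
                raise ValidationError(f"unknown attempt role {role!r}")
        # roles other than `none` are physical objects drawn without
        # replacement; `none` removes nothing and may repeat
        n_targets = sum(r == "target" for r in self.attempts)
        n_labelled = sum(r == "labelled_nontarget" for r in self.attempts)
        if n_targets > 1 or n_labelled > 1:
            raise ValidationError(
                "object roles repeat within a trial (draws are without replacement)"
            )
        if self.success_attempt is not None:
            i = self.success_attempt
            if not (1 <= i <= len(self.attempts)):
                raise ValidationError("success_attempt outside attempts list")
            if self.attempts[i - 1] != "target":
                raise ValidationError("success_attempt must point at a target attempt")
            if "target" in self.attempts[: i - 1]:
                raise ValidationError("target retrieved before success_attempt")
        elif "target" in self.attempts:
            raise ValidationError("target attempt present but success_attempt absent")

    @property
    def success(self) -> bool:
        return self.success_attempt is not None

    @property
    def first_attempt_success(self) -> bool:
        return self.success_attempt == 1


@dataclass(frozen=True)
class ExperimentDesign:
    """Static design of one experiment.

    ``chance_level`` is the success probability of an indifferent chooser in
    the *analysis* convention (0.33 for the 3-object design, 0.5 for the
    two-alternative analyses). ``conditions`` maps condition name to its
    trial count; ``counterbalance`` names the constraints the schedule
    generator must honor.
    """

    experiment: str
    n_trials: int
    set_size: int
    max_attempts: int
    chance_level: float
    n_positions: int | None = None
    conditions: Mapping[str, int] = field(default_factory=dict)
    counterbalance: tuple[str, ...] = ()
    n_pairs: int | None = None
    max_consecutive_pair: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValidationError("n_trials must be positive")
        if not 0.0 < self.chance_level < 1.0:
            raise ValidationError("chance_level must be in (0, 1)")
        if self.conditions and sum(self.conditions.values()) != self.n_trials:
            raise ValidationError("condition counts must sum to n_trials")

    @property
    def positions(self) -> int:
        return self.n_positions if self.n_positions is not None else self.set_size


def exp1_design() -> ExperimentDesign:
    """24 trials, 3 objects in 3 positions, up to 2 retrieval attempts."""
    return ExperimentDesign(
        experiment="exp1",
        n_trials=24,
        set_size=3,
        max_attempts=2,
        chance_level=0.33,
        counterbalance=("position_balanced",),
    )


def exp2_design() -> ExperimentDesign:
    """24 trials, 2 labelled targets + 2 distracters, 4 objects at request.

    Chance is 0.5 for the primary analysis (two labelled objects). A trial
    where the dog returned no object consumes an attempt slot, so two slots
    are allowed.
    """
    return ExperimentDesign(
        experiment="exp2",
        n_trials=24,
        set_size=4,
        max_attempts=2,
        chance_level=0.5,
        counterbalance=("position_balanced", "pair_balanced", "pair_run_limit"),
        n_pairs=2,
        max_consecutive_pair=2,
    )


def exp3_design() -> ExperimentDesign:
    """28 trials, 2 objects, half with the target occluded during naming."""
    return ExperimentDesign(
        experiment="exp3",
        n_trials=28,
        set_size=2,
        max_attempts=1,
        chance_level=0.5,
        conditions={"target_open": 14, "target_occluded": 14},
        counterbalance=("position_balanced", "condition_balanced"),
    )


DEFAULT_DESIGNS = {
    "exp1": exp1_design,
    "exp2": exp2_design,
    "exp3": exp3_design,
}


def design_for(experiment: str) -> ExperimentDesign:
    try:
        return DEFAULT_DESIGNS[experiment]()
    except KeyError:
        raise ValidationError(f"unknown experiment {experiment!r}") from None


def load_design(source: str | Path | IO[str]) -> ExperimentDesign:
    """Read an :class:`ExperimentDesign` from a YAML mapping.

    Keys mirror the dataclass fields; ``experiment`` is required and
    unspecified fields fall back to the default design for that experiment.
    """
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        data = yaml.safe_load(Path(source).read_text())
    if not isinstance(data, dict) or "experiment" not in data:
        raise ParseError("design YAML must be a mapping with an 'experiment' key")
    base = design_for(data["experiment"])
    known = {k: v for k, v in data.items() if k != "experiment"}
    if "conditions" in known:
        known["conditions"] = dict(known["conditions"])
    if "counterbalance" in known:
        known["counterbalance"] = tuple(known["counterbalance"])
    return replace(base, **known)


# ---------------------------------------------------------------------------
# Tabular I/O — comma-separated, UTF-8, header required; attempts sub-list
# delimited by semicolons; success_attempt empty when the trial failed.
# ---------------------------------------------------------------------------


def _record_from_row(row: Mapping[str, object], rownum: int) -> TrialRecord:
    try:
        attempts_raw = str(row["attempts"]) if not _is_na(row["attempts"]) else ""
        attempts = tuple(a for a in attempts_raw.split(ATTEMPTS_SEP) if a)
        sa = row["success_attempt"]
        success_attempt = None if _is_na(sa) else int(float(sa))
        pair_raw = row.get("pair", "")
        pair = None if _is_na(pair_raw) else int(float(pair_raw))
        return TrialRecord(
            subject_id=str(row["subject_id"]),
            experiment=str(row["experiment"]),
            trial_index=int(row["trial_index"]),
            set_size=int(row["set_size"]),
            condition=str(row["condition"]),
            requested_label=("" if _is_na(row["requested_label"]) else str(row["requested_label"])),
            attempts=attempts,
            success_attempt=success_attempt,
            pair=pair,
        )
    except ValidationError as exc:
        raise ValidationError(f"row {rownum}: {exc}") from exc
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"row {rownum}: malformed trial row ({exc})") from exc


def _is_na(value: object) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value == ""


def read_trials(source: str | Path | IO[str]) -> list[TrialRecord]:
    """Read validated trial records from a CSV stream or path, in file order."""
    try:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read trial table: {exc}") from exc
    # `pair` is optional in input tables (exp2 only); writers always emit it
    missing = [c for c in _CSV_COLUMNS if c != "pair" and c not in frame.columns]
    if missing:
        raise ParseError(f"trial table is missing columns: {', '.join(missing)}")
    return [
        _record_from_row(row, i + 2)  # +2: 1-based, after the header line
        for i, row in enumerate(frame.to_dict("records"))
    ]


def write_trials(records: Sequence[TrialRecord], sink: str | Path | IO[str]) -> None:
    """Write records as CSV; round-trips through :func:`read_trials`."""
    frame = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "experiment": r.experiment,
                "trial_index": r.trial_index,
                "set_size": r.set_size,
                "condition": r.condition,
                "requested_label": r.requested_label,
                "attempts": ATTEMPTS_SEP.join(r.attempts),
                "success_attempt": "" if r.success_attempt is None else r.success_attempt,
                "pair": "" if r.pair is None else r.pair,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )
    frame.to_csv(sink, index=False)


def trials_to_csv(records: Sequence[TrialRecord]) -> str:
    buf = io.StringIO()
    write_trials(records, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Subject-level summarization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectSummary:
    """Aggregate counts for one subject in one experiment run.

    ``first_window_correct`` / ``last_window_correct`` count correct trials
    among trials 1..window and (n-window+1)..n by trial index; with 28 trials
    and a 12-trial window the middle 4 trials belong to neither window.
    ``open_choices`` counts trials where the chosen object was the one in the
    open during naming (exp3 preference analysis).
    """

    subject_id: str
    experiment: str
    n_trials: int
    overall_correct: int
    first_attempt_correct: int
    window: int
    first_window_correct: int
    last_window_correct: int
    per_condition_n: Mapping[str, int]
    per_condition_correct: Mapping[str, int]
    observed_mean_attempts: float | None = None
    open_choices: int | None = None

    def __post_init__(self) -> None:
        if not (
            self.first_attempt_correct <= self.overall_correct <= self.n_trials
        ):
            raise ValidationError(
                "need first_attempt_correct <= overall_correct <= n_trials"
            )


def _chose_open_object(record: TrialRecord) -> bool | None:
    """Whether the first attempt picked the object visible during naming."""
    if record.experiment != "exp3" or not record.attempts:
        return None
    first = record.attempts[0]
    if first == "none":
        return None
    if record.condition == "target_open":
        return first == "target"
    if record.condition == "target_occluded":
        return first != "target"
    return None


def summarize_subject(
    records: Sequence[TrialRecord],
    design: ExperimentDesign | None = None,
    window: int | None = None,
) -> SubjectSummary:
    """Aggregate one subject's records into the counts the analyses use.

    Records may arrive in any order; ``trial_index`` carries trial order.
    ``window`` defaults to 12 trials, shrunk to the run length for short
    runs. Raises on mixed subjects/experiments or duplicated trial indices.
    """
    if not records:
        raise ValidationError("no records to summarize")
    subjects = {r.subject_id for r in records}
    experiments = {r.experiment for r in records}
    if len(subjects) > 1:
        raise ValidationError(f"records mix subjects: {sorted(subjects)}")
    if len(experiments) > 1:
        raise ValidationError(f"records mix experiments: {sorted(experiments)}")
    indices = [r.trial_index for r in records]
    dup = [i for i, c in Counter(indices).items() if c > 1]
    if dup:
        raise ValidationError(f"duplicate trial_index values: {sorted(dup)}")
    n = len(records)
    if window is None:
        window = min(12, n)
    if window > n:
        raise ValidationError("window exceeds number of trials")
    ordered = sorted(records, key=lambda r: r.trial_index)
    lo = ordered[: window]
    hi = ordered[n - window:]
    per_n: Counter[str] = Counter()
    per_c: Counter[str] = Counter()
    for r in ordered:
        per_n[r.condition] += 1
        if r.success:
            per_c[r.condition] += 1
    open_flags = [_chose_open_object(r) for r in ordered]
    known = [f for f in open_flags if f is not None]
    mean_attempts = None
    if design is not None:
        from .chance_null import FailurePolicy, observed_mean_attempts

        mean_attempts = observed_mean_attempts(ordered, design, FailurePolicy())
    return SubjectSummary(
        subject_id=next(iter(subjects)),
        experiment=next(iter(experiments)),
        n_trials=n,
        overall_correct=sum(r.success for r in ordered),
        first_attempt_correct=sum(r.first_attempt_success for r in ordered),
        window=window,
        first_window_correct=sum(r.success for r in lo),
        last_window_correct=sum(r.success for r in hi),
        per_condition_n=dict(per_n),
        per_condition_correct=dict(per_c),
        observed_mean_attempts=mean_attempts,
        open_choices=sum(known) if known else None,
    )


# ---------------------------------------------------------------------------
# Constrained schedule generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialSetting:
    """Per-trial design settings fixed before the subject acts."""

    trial_index: int
    target_position: int  # 1-based position of the target in the array
    condition: str = "default"
    pair: int | None = None  # exp2: which labelled pair is requested (0/1)


def check_schedule(
    schedule: Sequence[TrialSetting], design: ExperimentDesign
) -> list[str]:
    """Return the list of counterbalance-rule violations (empty = valid)."""
    problems: list[str] = []
    if len(schedule) != design.n_trials:
        problems.append(
            f"schedule has {len(schedule)} trials, design wants {design.n_trials}"
        )
    if "position_balanced" in design.counterbalance:
        counts = Counter(s.target_position for s in schedule)
        per = design.n_trials // design.positions
        bad = {p: c for p, c in counts.items() if c != per}
        if len(counts) != design.positions or bad:
            problems.append(f"target positions not balanced: {dict(counts)}")
    if "condition_balanced" in design.counterbalance and design.conditions:
        counts = Counter(s.condition for s in schedule)
        for cond, want in design.conditions.items():
            if counts.get(cond, 0) != want:
                problems.append(
                    f"condition {cond}: {counts.get(cond, 0)} trials, want {want}"
                )
    if "pair_balanced" in design.counterbalance and design.n_pairs:
        counts = Counter(s.pair for s in schedule)
        per = design.n_trials // design.n_pairs
        if any(counts.get(p, 0) != per for p in range(design.n_pairs)):
            problems.append(f"pairs not balanced: {dict(counts)}")
    if "pair_run_limit" in design.counterbalance and design.max_consecutive_pair:
        limit, run, prev = design.max_consecutive_pair, 0, object()
        for s in schedule:
            run = run + 1 if s.pair == prev else 1
            prev = s.pair
            if run > limit:
                problems.append(
                    f"pair {s.pair} appears in more than {limit} consecutive trials"
                )
                break
    return problems


def _balanced_sequence(values: Iterable[object], counts: Iterable[int]) -> list[object]:
    out: list[object] = []
    for v, c in zip(values, counts):
        out.extend([v] * c)
    return out


def generate_schedule(
    design: ExperimentDesign, seed: int, max_tries: int = 1000
) -> list[TrialSetting]:
    """Generate a random schedule satisfying the design's counterbalance rules.

    Deterministic for a fixed seed. Rejection-samples shuffled balanced
    sequences until the constraint checker passes; raises after
    ``max_tries`` attempts (unsatisfiable constraints).
    """
    rng = np.random.default_rng(seed)
    n = design.n_trials
    per_pos = n // design.positions
    if per_pos * design.positions != n and "position_balanced" in design.counterbalance:
        raise ValidationError("n_trials not divisible by number of positions")
    for _ in range(max_tries):
        positions = np.array(
            _balanced_sequence(range(1, design.positions + 1), [per_pos] * design.positions)
        )
        rng.shuffle(positions)
        if design.conditions:
            conditions = np.array(
                _balanced_sequence(design.conditions.keys(), design.conditions.values())
            )
            rng.shuffle(conditions)
        else:
            conditions = np.array(["default"] * n)
        if design.n_pairs:
            per_pair = n // design.n_pairs
            pairs = np.array(
                _balanced_sequence(range(design.n_pairs), [per_pair] * design.n_pairs)
            )
            rng.shuffle(pairs)
            pair_of = lambda i: int(pairs[i])  # noqa: E731
        else:
            pair_of = lambda i: None  # noqa: E731
        schedule = [
            TrialSetting(
                trial_index=i + 1,
                target_position=int(positions[i]),
                condition=str(conditions[i]),
                pair=pair_of(i),
            )
            for i in range(n)
        ]
        if not check_schedule(schedule, design):
            return schedule
    raise ValidationError(
        f"could not satisfy counterbalance constraints in {max_tries} tries"
    )
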