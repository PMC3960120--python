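"""Trial records, CSV round-tripping, summaries and schedule generation."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetchstats import (
    AgentSpec,
    TrialRecord,
    design_for,
    generate_schedule,
    read_trials,
    simulate,
    summarize_subject,
    write_trials,
)
from fetchstats.trial_model import (
    ParseError,
    TrialSetting,
    ValidationError,
    check_schedule,
    load_design,
)

HEADER = "subject_id,experiment,trial_index,set_size,condition,requested_label,attempts,success_attempt"


def make_record(trial_index=1, attempts=("target",), success=1, **kw):
    defaults = dict(
        subject_id="Paddy",
        experiment="exp1",
        trial_index=trial_index,
        set_size=3,
        attempts=tuple(attempts),
        success_attempt=success,
    )
    defaults.update(kw)
    return TrialRecord(**defaults)


class TestRecordInvariants:
    def test_success_attempt_points_at_first_target(self):
        rec = make_record(attempts=("distracter", "target"), success=2)
        assert rec.success and not rec.first_attempt_success

    @pytest.mark.parametrize(
        "attempts,success",
        [
            (("distracter", "target"), 1),  # success index not a target
            (("target", "distracter"), None),  # target present, no success index
            (("target", "target"), 2),  # object roles repeat
            (("distracter",), 5),  # index outside attempts
        ],
    )
    def test_inconsistent_attempt_encoding_rejected(self, attempts, success):
        with pytest.raises(ValidationError):
            make_record(attempts=attempts, success=success)

    def test_none_attempt_consumes_a_slot_but_may_repeat(self):
        rec = make_record(experiment="exp2", set_size=4,
                          attempts=("none", "none"), success=None)
        assert len(rec.attempts) == 2

    def test_conditions_are_exp3_only(self):
        with pytest.raises(ValidationError):
            make_record(condition="target_open")
        rec = make_record(experiment="exp3", set_size=2, condition="target_open",
                          attempts=("target",), success=1)
        assert rec.condition == "target_open"


class TestCsvRoundTrip:
    def test_single_row_field_mapping(self):
        csv = HEADER + '\nPaddy,exp1,1,3,default,Gysi,distracter;target,2\n'
        (rec,) = read_trials(io.StringIO(csv))
        assert rec.requested_label == "Gysi"
        assert rec.attempts == ("distracter", "target")
        assert rec.success_attempt == 2

    def test_header_only_file_gives_empty_list(self):
        assert read_trials(io.StringIO(HEADER + "\n")) == []

    def test_empty_list_writes_header_only(self):
        buf = io.StringIO()
        write_trials([], buf)
        assert buf.getvalue().strip().startswith("subject_id,")
        assert read_trials(io.StringIO(buf.getvalue())) == []

    def test_malformed_row_names_row_number(self):
        csv = HEADER + "\nPaddy,exp1,not_an_int,3,default,Gysi,target,1\n"
        with pytest.raises(ParseError, match="row 2"):
            read_trials(io.StringIO(csv))

    def test_invariant_violation_surfaces_as_validation_error(self):
        csv = HEADER + "\nPaddy,exp1,1,3,default,Gysi,distracter;target,1\n"
        with pytest.raises(ValidationError, match="row 2"):
            read_trials(io.StringIO(csv))

    def test_fixture_round_trips(self, fixture_map):
        records = fixture_map["Paddy", "exp1"]
        buf = io.StringIO()
        write_trials(records, buf)
        assert read_trials(io.StringIO(buf.getvalue())) == records

    @pytest.mark.parametrize("experiment", ["exp1", "exp2", "exp3"])
    def test_simulated_records_round_trip(self, experiment):
        records = []
        for seed in range(30):
            records = simulate(experiment, AgentSpec(kind="random"),
                               design_for(experiment), seed,
                               subject_id=f"dog{seed}") + records
        buf = io.StringIO()
        write_trials(records, buf)
        assert read_trials(io.StringIO(buf.getvalue())) == records


class TestSummaries:
    def test_paddy_exp1_counts(self, fixture_map, exp1_design):
        s = summarize_subject(fixture_map["Paddy", "exp1"], exp1_design)
        assert (s.overall_correct, s.first_attempt_correct) == (22, 12)
        assert s.observed_mean_attempts == pytest.approx(38 / 24)

    def test_paddy_exp3_last_window(self, fixture_map, exp3_design):
        s = summarize_subject(fixture_map["Paddy", "exp3"], exp3_design, window=12)
        assert s.first_window_correct == 6
        assert s.last_window_correct == 10

    def test_all_first_attempt_successes(self):
        records = [make_record(trial_index=i) for i in range(1, 11)]
        s = summarize_subject(records)
        assert s.overall_correct == s.first_attempt_correct == s.n_trials == 10

    def test_order_invariance(self, fixture_map):
        records = list(fixture_map["Betsy", "exp3"])
        assert summarize_subject(records) == summarize_subject(records[::-1])

    def test_mixed_subjects_rejected(self):
        records = [make_record(trial_index=1),
                   make_record(trial_index=2, subject_id="Joey")]
        with pytest.raises(ValidationError, match="mix subjects"):
            summarize_subject(records)

    def test_duplicate_trial_index_rejected(self):
        records = [make_record(trial_index=1), make_record(trial_index=1)]
        with pytest.raises(ValidationError, match="duplicate"):
            summarize_subject(records)


class TestScheduleGeneration:
    def test_exp3_conditions_exactly_balanced(self, exp3_design):
        for seed in range(20):
            schedule = generate_schedule(exp3_design, seed)
            conditions = [s.condition for s in schedule]
            assert conditions.count("target_open") == 14
            assert conditions.count("target_occluded") == 14

    def test_exp2_pair_run_limit(self, exp2_design):
        for seed in range(20):
            schedule = generate_schedule(exp2_design, seed)
            run, prev = 0, None
            for s in schedule:
                run = run + 1 if s.pair == prev else 1
                prev = s.pair
                assert run <= 2

    def test_exp1_positions_counterbalanced(self, exp1_design):
        schedule = generate_schedule(exp1_design, 7)
        positions = [s.target_position for s in schedule]
        assert all(positions.count(p) == 8 for p in (1, 2, 3))

    def test_deterministic_per_seed(self, exp2_design):
        assert generate_schedule(exp2_design, 5) == generate_schedule(exp2_design, 5)

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1),
           experiment=st.sampled_from(["exp1", "exp2", "exp3"]))
    def test_schedules_pass_their_own_checker(self, seed, experiment):
        design = design_for(experiment)
        assert check_schedule(generate_schedule(design, seed), design) == []

    def test_unsatisfiable_constraints_raise(self, exp2_design):
        # a single pair cannot respect the 2-in-a-row limit over 24 trials
        from dataclasses import replace

        broken = replace(exp2_design, n_pairs=1)
        with pytest.raises(ValidationError, match="counterbalance"):
            generate_schedule(broken, 0, max_tries=50)

    def test_checker_flags_bad_schedule(self, exp3_design):
        schedule = [
            TrialSetting(trial_index=i, target_position=1, condition="target_open")
            for i in range(1, 29)
        ]
        assert check_schedule(schedule, exp3_design)


def test_design_yaml_round_trip(tmp_path):
    path = tmp_path / "design.yaml"
    path.write_text("experiment: exp1\nn_trials: 240\n")
    design = load_design(path)
    assert design.n_trials == 240
    assert design.set_size == 3
    assert design.chance_level == 0.33
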