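"""Behavioral metrics: rate arithmetic, bias indices, and the cohort analysis."""

import numpy as np
import pytest

from orientrack.behavior import (
    LaserEffectModel,
    laser_delta_index,
    laser_effect_analysis,
    movement_velocity,
    performance_summary,
    side_preference,
    spontaneous_delta,
    spontaneous_rates,
    SpontaneousRates,
    cohort_trial_table,
)
from orientrack.task import BallTrace, SessionLog, TrialRecord


def _trial(cue, outcome, laser=False, rt=0.4, direction=None):
    if direction is None and outcome != "timeout":
        correct_dir = "pos" if cue == "right" else "neg"
        direction = correct_dir if outcome == "correct" else ("neg" if correct_dir == "pos" else "pos")
    return TrialRecord(
        cue_side=cue,
        laser=laser,
        outcome=outcome,
        response_time_s=None if outcome == "timeout" else rt,
        chosen_direction=None if outcome == "timeout" else direction,
    )


def _session(trials, hemisphere="left", contingency="inward"):
    return SessionLog(mouse_id="m0", hemisphere=hemisphere, contingency=contingency,
                      trials=trials)


def test_performance_summary_hand_count():
    trials = (
        [_trial("right", "correct")] * 6
        + [_trial("right", "incorrect")] * 2
        + [_trial("right", "timeout")] * 2
    )
    rates = performance_summary(_session(trials))
    cell = rates.cells[("right", None)]
    assert cell["timeout_rate"] == pytest.approx(0.2)
    assert cell["incorrect_rate"] == pytest.approx(0.25)
    assert cell["mean_rt"] == pytest.approx(0.4)
    # left hemisphere + inward: right cue instructs the contraversive action
    assert rates.cells[("contra", None)] == cell


def test_degenerate_cells_flagged_not_crashing():
    rates = performance_summary(_session([_trial("right", "timeout")] * 5))
    assert rates.cells[("right", None)]["timeout_rate"] == 1.0
    assert not rates.defined("right", "incorr", None)
    assert not rates.defined("left", "timeout", None)  # no left trials at all


def test_side_preference_values():
    def rates_with(contra_corr, ipsi_corr):
        trials = []
        for _ in range(100):
            trials.append(_trial("right", "correct" if len(trials) % 100 < contra_corr * 100 else "incorrect"))
        t_r = [_trial("right", "correct")] * int(contra_corr * 100) + \
              [_trial("right", "incorrect")] * (100 - int(contra_corr * 100))
        t_l = [_trial("left", "correct")] * int(ipsi_corr * 100) + \
              [_trial("left", "incorrect")] * (100 - int(ipsi_corr * 100))
        return performance_summary(_session(t_r + t_l))

    assert side_preference(rates_with(0.6, 0.6)) == pytest.approx(0.0)
    assert side_preference(rates_with(0.6, 0.0)) == pytest.approx(1.0)
    assert side_preference(rates_with(0.75, 0.25)) == pytest.approx(0.5)


def test_side_preference_flips_with_hemisphere():
    t_r = [_trial("right", "correct")] * 75 + [_trial("right", "incorrect")] * 25
    t_l = [_trial("left", "correct")] * 25 + [_trial("left", "incorrect")] * 75
    left = performance_summary(_session(t_r + t_l, hemisphere="left"))
    right = performance_summary(_session(t_r + t_l, hemisphere="right"))
    assert side_preference(left) == pytest.approx(-side_preference(right))


def _rates_for_index(nl, l):
    """Build sessions realizing given (contra_corr, ipsi_incorr) per laser state."""
    trials = []
    for laser, (pc, qi) in ((False, nl), (True, l)):
        n = 200
        trials += [_trial("right", "correct", laser)] * int(pc * n)
        trials += [_trial("right", "incorrect", laser)] * (n - int(pc * n))
        trials += [_trial("left", "incorrect", laser)] * int(qi * n)
        trials += [_trial("left", "correct", laser)] * (n - int(qi * n))
    return performance_summary(_session(trials))


def test_laser_delta_index_arithmetic():
    assert laser_delta_index(_rates_for_index((0.8, 0.2), (0.8, 0.2)), "contra_action") == pytest.approx(0.0)
    assert laser_delta_index(_rates_for_index((0.8, 0.2), (0.9, 0.3)), "contra_action") == pytest.approx(0.2)
    # doubling both laser terms of a baseline summing to 1 gives an index of 1
    assert laser_delta_index(_rates_for_index((0.5, 0.5), (1.0, 1.0)), "contra_action") == pytest.approx(1.0)
    assert laser_delta_index(_rates_for_index((0.8, 0.2), (0.9, 0.3)), "right_stimulus") == pytest.approx(0.2)


def test_laser_delta_index_sign_flips_when_labels_swap():
    rates_fwd = _rates_for_index((0.8, 0.2), (0.9, 0.3))
    rates_rev = _rates_for_index((0.9, 0.3), (0.8, 0.2))
    d_fwd = laser_delta_index(rates_fwd, "contra_action")
    d_rev = laser_delta_index(rates_rev, "contra_action")
    assert np.sign(d_fwd) == -np.sign(d_rev)


def test_spontaneous_delta_arithmetic_and_errors():
    r = SpontaneousRates(0.3, 0.6, 0.7, 0.4, 100, 200)
    d_contra, d_ipsi = spontaneous_delta(r)
    assert d_contra == pytest.approx(-0.5)
    assert d_ipsi == pytest.approx(0.75)
    assert np.sign(d_contra) == -np.sign(d_ipsi)
    r_same = SpontaneousRates(0.5, 0.5, 0.5, 0.5, 50, 50)
    assert spontaneous_delta(r_same) == (0.0, 0.0)
    with pytest.raises(ValueError):
        spontaneous_delta(SpontaneousRates(0.5, 0.0, 0.5, 1.0, 10, 10))


def test_spontaneous_rates_count_only_attempts():
    trials = [
        TrialRecord("right", False, "correct", 0.5, "pos"),
        TrialRecord("right", False, "incorrect", 0.5, "neg"),
        TrialRecord("right", False, "timeout", None, None),  # no attempt
        TrialRecord("right", True, "correct", 0.5, "neg"),
    ]
    r = spontaneous_rates(_session(trials, contingency="spontaneous"))
    assert r.n_attempts_nl == 2 and r.n_attempts_l == 1
    assert r.contraversive_nl == pytest.approx(0.5)  # pos = contra on the left hemisphere
    assert r.contraversive_l == 0.0


def test_movement_velocity_hand_computations():
    # pure ramp to 15° over 0.5 s
    t = np.arange(0.0, 1.001, 0.01)
    ramp = BallTrace(t, np.clip(t / 0.5, 0, 1) * 15.0)
    assert movement_velocity(ramp) == pytest.approx(30.0, rel=0.05)
    # never crosses 0.5°: undefined
    assert movement_velocity(BallTrace(t, 0.3 * np.sin(t))) is None
    # 6-sample piecewise trace with a pause: mean of per-tick magnitudes
    t6 = np.arange(6) * 0.01
    a6 = np.array([0.0, 1.0, 2.0, 2.0, 5.0, 16.0])
    steps = np.abs(np.diff(a6[1:])) / 0.01  # movement starts at the 1.0° sample
    assert movement_velocity(BallTrace(t6, a6)) == pytest.approx(steps.mean())


def test_cohort_analysis_invariant_to_mouse_order(null_cohort):
    sessions, _ = null_cohort
    res_fwd = laser_effect_analysis(sessions, n_perm=100, seed=5)
    res_rev = laser_effect_analysis(list(reversed(sessions)), n_perm=100, seed=5)
    for k in res_fwd.effects:
        assert res_fwd.effects[k].observed_effect == pytest.approx(
            res_rev.effects[k].observed_effect
        )
        assert res_fwd.effects[k].p_two_sided == res_rev.effects[k].p_two_sided


def test_cohort_analysis_detects_injected_effect(effect_cohort):
    sessions, gt = effect_cohort
    res = laser_effect_analysis(sessions, n_perm=400, seed=6)
    assert res.significant["delta_contra_action"]
    assert res.effects["delta_contra_action"].observed_effect == pytest.approx(
        gt["expected_contra_action_delta"], abs=0.1
    )
    # laser raises incorrect rate on the ipsi-instructing (left) cue and
    # lowers it on the contra-instructing (right) cue
    assert res.effects["delta_incorrect_left"].observed_effect > 0
    assert res.effects["delta_incorrect_right"].observed_effect < 0
    assert res.significant["delta_incorrect_left"] and res.significant["delta_incorrect_right"]


def test_cohort_table_labels(null_cohort):
    sessions, _ = null_cohort
    table = cohort_trial_table(sessions)
    assert set(table["mouse_id"]) == {f"m{i:02d}" for i in range(6)}
    # inward/left-hemisphere: right cue == contra-instructing cue
    assert (table["cue_right"] == table["contra_cued"]).all()
    assert (table["completed"] == ~table["timeout"]).all()


def test_model_requires_two_mice(null_cohort):
    sessions, _ = null_cohort
    one_mouse = [s for s in sessions if s.mouse_id == "m00"]
    with pytest.raises(ValueError, match="2 mice"):
        LaserEffectModel(one_mouse)
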