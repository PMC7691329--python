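"""Trace pipeline: dF/F, detrending, trial tensors, and response statistics."""

import numpy as np
import pandas as pd
import pytest

from orientrack.imaging import (
    RoiTraceSet,
    bouton_visual_stats,
    build_trial_tensor,
    detrend_baseline,
    neuron_condition_stats,
    neuropil_dff,
    preference_fisher_comparison,
    zscore_traces,
)
from orientrack.simulate import CalciumSimParams, simulate_bouton_passive, simulate_calcium_session


def _trace_set(soma, neuropil=None, fr=5.0):
    soma = np.atleast_2d(np.asarray(soma, dtype=float))
    neuropil = np.zeros_like(soma) if neuropil is None else np.atleast_2d(neuropil)
    times = np.arange(soma.shape[1]) / fr
    return RoiTraceSet(soma_raw=soma, neuropil_raw=neuropil, frame_times=times, frame_rate_hz=fr)


def test_constant_trace_gives_zero_dff():
    dff = neuropil_dff(_trace_set(np.full(600, 80.0)))
    assert dff.valid[0]
    assert dff.f0[0] == pytest.approx(80.0, rel=0.02)
    assert np.allclose(dff.dff[0], 0.0, atol=1e-6)


def test_fully_contaminated_roi_flagged_invalid():
    neuropil = np.full(600, 100.0)
    soma = 0.7 * neuropil
    dff = neuropil_dff(_trace_set(soma, neuropil))
    assert not dff.valid[0]
    assert np.all(np.isnan(dff.dff[0]))


def test_two_level_trace_density_mode():
    # 80% of time at 100, 20% at 200: the density mode sits at 100 and the
    # upper level maps to ~100% dF/F
    trace = np.concatenate([np.full(800, 100.0), np.full(200, 200.0)])
    rng = np.random.default_rng(0)
    trace = trace + rng.normal(0, 1.0, trace.size)
    dff = neuropil_dff(_trace_set(trace))
    assert dff.f0[0] == pytest.approx(100.0, abs=2.0)
    assert np.median(dff.dff[0][800:]) == pytest.approx(100.0, abs=5.0)


def test_bouton_mode_skips_neuropil_subtraction():
    soma = np.full(600, 50.0)
    neuropil = np.full(600, 50.0)
    ts = _trace_set(soma, neuropil)
    ts.roi_labels = np.array(["bouton"])
    dff = neuropil_dff(ts)
    assert dff.valid[0] and dff.f0[0] == pytest.approx(50.0, rel=0.02)
    assert dff.neuropil_coefficient == 0.0


def test_detrend_constant_trace_is_zero_and_short_session_errors():
    x = np.full((2, 600), 35.0)
    out = detrend_baseline(x, frame_rate=5.0)
    assert np.allclose(out, 0.0, atol=1e-9)
    with pytest.raises(ValueError, match="shorter"):
        detrend_baseline(np.zeros((1, 100)), frame_rate=5.0)


def _transient_train(n_frames=3000, fr=5.0, seed=1):
    rng = np.random.default_rng(seed)
    x = np.zeros(n_frames)
    kernel = np.exp(-np.arange(0, 8 * fr) / (1.5 * fr)) * 40.0
    for onset in rng.choice(n_frames - 100, 40, replace=False):
        x[onset : onset + kernel.size] += kernel
    return x


def test_detrend_removes_slow_drift_and_preserves_transients():
    fr = 5.0
    x = _transient_train()
    t = np.arange(x.size) / fr
    drift = 20.0 * t / 600.0  # 20% dF/F per 10 minutes
    detr = detrend_baseline((x + drift)[None, :], frame_rate=fr)[0]
    clean = detrend_baseline(x[None, :], frame_rate=fr)[0]
    quiet = x == 0
    assert abs(np.median(detr[quiet])) < 2.0
    # transient peaks preserved within 5% of the drift-free pipeline
    peaks_ref = np.sort(clean)[-20:]
    peaks_detr = np.sort(detr)[-20:]
    assert np.allclose(peaks_detr, peaks_ref, rtol=0.05, atol=1.0)


def test_detrend_is_idempotent_within_tolerance():
    x = (_transient_train(seed=2) + 5.0)[None, :]
    once = detrend_baseline(x, frame_rate=5.0)
    twice = detrend_baseline(once, frame_rate=5.0)
    rms = np.sqrt(np.mean((twice - once) ** 2))
    scale = np.sqrt(np.mean(once**2))
    assert rms < 0.01 * max(scale, 1.0)


def test_zscore_normalizes_each_roi():
    rng = np.random.default_rng(3)
    x = rng.normal(5.0, 3.0, (4, 800))
    z = zscore_traces(x)
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(z.std(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# trial tensor

def test_tensor_counts_match_generator_tallies(imaging_session):
    session, traces, _ = imaging_session
    z = zscore_traces(detrend_baseline(neuropil_dff(traces)))
    tensor = build_trial_tensor(z, traces.frame_times, session)
    manual = {"right-contra": 0, "right-ipsi": 0, "left-contra": 0, "left-ipsi": 0}
    for tr in session.trials:
        if tr.chosen_direction is None:
            continue
        action = "contra" if tr.chosen_direction == "pos" else "ipsi"  # left hemisphere
        manual[f"{tr.cue_side}-{action}"] += 1
    assert tensor.condition_counts() == manual
    assert tensor.activity.shape[1] == sum(manual.values())


def test_tensor_exclusion_rule_below_five_trials(imaging_session):
    session, traces, _ = imaging_session
    z = zscore_traces(neuropil_dff(traces).dff)
    # keep only 4 right-ipsi trials by thinning that condition
    kept = []
    n_ri = 0
    for tr in session.trials:
        if tr.cue_side == "right" and tr.chosen_direction == "neg":
            n_ri += 1
            if n_ri > 4:
                continue
        kept.append(tr)
    thin = type(session)(
        mouse_id=session.mouse_id, hemisphere=session.hemisphere,
        contingency=session.contingency, trials=kept,
    )
    tensor = build_trial_tensor(z, traces.frame_times, thin)
    assert tensor.condition_counts()["right-ipsi"] == 4
    assert not tensor.included


def test_tensor_alignment_shifts_with_onsets(imaging_session):
    session, traces, _ = imaging_session
    z = zscore_traces(neuropil_dff(traces).dff)
    t0 = build_trial_tensor(z, traces.frame_times, session, window=(-1.0, 1.0))
    shifted = type(session)(
        mouse_id=session.mouse_id, hemisphere=session.hemisphere,
        contingency=session.contingency,
        trials=[
            type(tr)(
                cue_side=tr.cue_side, laser=tr.laser, outcome=tr.outcome,
                response_time_s=tr.response_time_s, chosen_direction=tr.chosen_direction,
                start_time_s=tr.start_time_s, stim_time_s=tr.stim_time_s + 0.2,
            )
            for tr in session.trials
        ],
    )
    t1 = build_trial_tensor(z, traces.frame_times, shifted, window=(-1.0, 1.0))
    # a one-frame onset shift moves the slice by exactly one frame
    assert np.allclose(t0.activity[:, :, 1:], t1.activity[:, :, :-1])


# ---------------------------------------------------------------------------
# condition statistics

def test_condition_stats_detect_ipsi_bias(imaging_session):
    session, traces, _ = imaging_session
    z = zscore_traces(detrend_baseline(neuropil_dff(traces)))
    tensor = build_trial_tensor(z, traces.frame_times, session)
    stats = neuron_condition_stats(tensor)
    # the generator gives ipsi actions extra weight: population activity is
    # higher on ipsiversive trials, so the contra-minus-ipsi z is negative
    assert stats.population["contra_vs_ipsi_action"]["z"] < 0
    assert stats.population["contra_vs_ipsi_action"]["p"] < 0.05
    pn = stats.per_neuron
    assert np.allclose(
        pn["mean_right_cue"], (pn["mean_right-contra"] + pn["mean_right-ipsi"]) / 2
    )
    frac = stats.population["frac_action_diff_right"]
    lo, hi = frac["ci95"]
    assert 0 <= lo <= frac["fraction"] <= hi <= 1


def test_condition_stats_velocity_split(imaging_session):
    session, traces, _ = imaging_session
    z = zscore_traces(neuropil_dff(traces).dff)
    tensor = build_trial_tensor(z, traces.frame_times, session)
    rng = np.random.default_rng(4)
    velocities = rng.uniform(10, 60, tensor.activity.shape[1])
    stats = neuron_condition_stats(tensor, velocities=velocities)
    out = stats.population["high_vs_low_velocity"]
    # velocity labels are random, so no systematic difference
    assert out["p"] > 0.001
    assert np.isfinite(out["median_split"])


# ---------------------------------------------------------------------------
# bouton statistics

def test_perfectly_selective_bouton_saturates_preference():
    traces, stim, _ = simulate_bouton_passive(
        n_boutons=10, contra_frac=1.0, effect_size=0.5, n_trials_per_side=12,
        params=CalciumSimParams(noise_sd=0.5), seed=6,
    )
    dff = neuropil_dff(traces)
    bs = bouton_visual_stats(dff.dff, traces.frame_times, stim, n_shuffles=200, seed=7)
    assert bs.n_responsive == 10
    sig = bs.per_bouton["preference_significant"]
    assert sig.all()
    assert (bs.per_bouton.loc[sig, "preference_score"] > 0.9).all()
    assert bs.per_bouton["preference_score"].between(-1, 1).all()


def test_bouton_requires_two_trials_per_side():
    traces, stim, _ = simulate_bouton_passive(
        n_boutons=3, n_trials_per_side=5, seed=8
    )
    dff = neuropil_dff(traces)
    one_sided = stim[stim["side"] == "contra"].iloc[:3]
    with pytest.raises(ValueError, match="2 trials per side"):
        bouton_visual_stats(dff.dff, traces.frame_times, one_sided, n_shuffles=50, seed=9)


def test_population_fisher_comparison_matches_direct_table():
    from orientrack.stats import fisher_exact_two_sided

    assert preference_fisher_comparison(233, 268, 48, 309) == fisher_exact_two_sided(
        [[233, 35], [48, 261]]
    )
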