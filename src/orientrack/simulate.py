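"""Synthetic data generators with known ground truth.

Four modalities mirror the study's data streams: (1) behavioral cohorts of
trackball sessions driven by parameterized stochastic agents, (2) calcium
fluorescence for task sessions (soma + matched neuropil at 5 Hz, GCaMP6s-like
kernel, drift, contamination), (3) Poisson spike trains in laser / non-laser
block schedules, and (4) pose clips of body landmarks during turns. Every
generator is deterministic under a fixed seed and returns a machine-readable
ground-truth record so downstream estimators can be tested for parameter
recovery and null calibration.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._rng import rng_from_seed
from .task import (
    BallTrace,
    SessionLog,
    TaskConfig,
    TrialRecord,
    action_is_contraversive,
    laser_schedule,
    run_session,
)

__all__ = [
    "AgentParams",
    "CalciumSimParams",
    "SpikeSimParams",
    "PoseSimParams",
    "simulate_behavior_cohort",
    "simulate_calcium_session",
    "simulate_bouton_passive",
    "simulate_spike_trains",
    "simulate_pose_clip",
    "make_trace_agent",
    "expected_contra_action_delta",
]

_TICK = 0.010


# ---------------------------------------------------------------------------
# behavior

@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of a stochastic task agent.

    Defaults target an expert mouse: ~80% accuracy, ~12% timeouts, median
    response time ~0.4 s (log-normal, truncated to the response window).
    ``laser_delta_contra`` shifts the probability of the contraversive
    action additively on laser trials (probabilities are clipped to [0, 1];
    clip events are counted in the ground-truth record).
    """

    p_correct_right: float = 0.8
    p_correct_left: float = 0.8
    laser_delta_contra: float = 0.0
    p_timeout: float = 0.12
    rt_mu: float = math.log(0.4)
    rt_sigma: float = 0.35
    velocity_scale: float = 40.0  # deg/s of the threshold approach

    def __post_init__(self) -> None:
        for p in (self.p_correct_right, self.p_correct_left, self.p_timeout):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _p_positive_action(
    agent: AgentParams, cue: str, laser: bool, config: TaskConfig, hemisphere: str
) -> tuple[float, bool]:
    """P(choose the positive rotation | cue, laser); returns (p, clipped)."""
    p_correct = agent.p_correct_right if cue == "right" else agent.p_correct_left
    pos_is_correct = (cue == "right") == (config.contingency == "inward")
    p_pos = p_correct if pos_is_correct else 1.0 - p_correct
    clipped = False
    if laser and agent.laser_delta_contra != 0.0:
        pos_is_contra = hemisphere == "left"
        delta = agent.laser_delta_contra if pos_is_contra else -agent.laser_delta_contra
        raw = p_pos + delta
        p_pos = min(max(raw, 0.0), 1.0)
        clipped = raw != p_pos
    return p_pos, clipped


def _truncated_lognormal_rt(agent: AgentParams, window: float, rng: np.random.Generator) -> float:
    hi = 0.98 * window
    for _ in range(64):
        rt = float(rng.lognormal(agent.rt_mu, agent.rt_sigma))
        if 2 * _TICK < rt <= hi:
            return rt
    return hi


def make_trace_agent(
    agent: AgentParams, config: TaskConfig, hemisphere: str = "left"
):
    """Build an agent policy emitting ball traces consistent with the
    agent's outcome probabilities.

    Completed trials are noiseless piecewise-linear ramps: the ball is
    still until movement start, then approaches threshold at
    ``velocity_scale`` deg/s so the crossing lands exactly at the sampled
    response time. Timeout trials wander below the 0.5° movement-start
    criterion.
    """
    window = config.response_window_s
    times = np.arange(0.0, window + 5 * _TICK, _TICK)

    def policy(cue: str, laser: bool, rng: np.random.Generator) -> BallTrace:
        if rng.random() < agent.p_timeout:
            ang = 0.3 * np.sin(2 * np.pi * times / window)
            return BallTrace(times, ang)
        p_pos, _ = _p_positive_action(agent, cue, laser, config, hemisphere)
        sign = 1.0 if rng.random() < p_pos else -1.0
        rt = _truncated_lognormal_rt(agent, window, rng)
        ramp_dur = min(config.threshold_deg / agent.velocity_scale, rt)
        t0 = rt - ramp_dur
        ang = np.where(
            times < t0,
            0.0,
            np.minimum((times - t0) / ramp_dur, 1.0) * config.threshold_deg,
        )
        return BallTrace(times, sign * ang)

    return policy


def expected_contra_action_delta(
    agent: AgentParams, config: TaskConfig, hemisphere: str = "left"
) -> float:
    """Closed-form expectation of the contra-action laser index.

    Computed from the generative probabilities: with pc = P(contra action |
    contra-cued trial) and qi = P(contra action | ipsi-cued trial), the
    index is ((pc_l + qi_l) − (pc_nl + qi_nl)) / (pc_nl + qi_nl). Timeouts
    are independent of the action draw in the generator, so completed-trial
    rates equal these probabilities.
    """
    pos_is_contra = hemisphere == "left"

    def p_contra(cue: str, laser: bool) -> float:
        p_pos, _ = _p_positive_action(agent, cue, laser, config, hemisphere)
        return p_pos if pos_is_contra else 1.0 - p_pos

    contra_cue = {"inward": "right", "outward": "left"}[config.contingency]
    if hemisphere == "right":
        contra_cue = "left" if contra_cue == "right" else "right"
    ipsi_cue = "left" if contra_cue == "right" else "right"
    base = p_contra(contra_cue, False) + p_contra(ipsi_cue, False)
    las = p_contra(contra_cue, True) + p_contra(ipsi_cue, True)
    return (las - base) / base


def _simulate_session_fast(
    agent: AgentParams,
    config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    mouse_id: str,
    hemisphere: str,
) -> tuple[SessionLog, int]:
    """Vectorized session without ball traces (cues i.i.d.)."""
    lasers = laser_schedule(n_trials, config.laser_fraction, rng)
    cues = np.where(rng.random(n_trials) < 0.5, "right", "left")
    timeouts = rng.random(n_trials) < agent.p_timeout
    p_pos = np.empty(n_trials)
    n_clip = 0
    for cue in ("right", "left"):
        for las in (False, True):
            m = (cues == cue) & (lasers == las)
            p, clipped = _p_positive_action(agent, cue, las, config, hemisphere)
            p_pos[m] = p
            n_clip += int(clipped) * int(m.sum())
    pos = rng.random(n_trials) < p_pos
    z = rng.normal(size=n_trials)
    rts = np.clip(np.exp(agent.rt_mu + agent.rt_sigma * z), 3 * _TICK, 0.98 * config.response_window_s)
    trials = []
    clock = 0.0
    for i in range(n_trials):
        cue = str(cues[i])
        if timeouts[i]:
            outcome, rt, direction = "timeout", None, None
        else:
            direction = "pos" if pos[i] else "neg"
            pos_is_correct = (cue == "right") == (config.contingency == "inward")
            correct = (direction == "pos") == pos_is_correct
            outcome, rt = ("correct" if correct else "incorrect"), float(rts[i])
        stim = clock + config.hold_still_s
        trials.append(
            TrialRecord(
                cue_side=cue,
                laser=bool(lasers[i]),
                outcome=outcome,
                response_time_s=rt,
                chosen_direction=direction,
                start_time_s=clock,
                stim_time_s=stim,
            )
        )
        clock = stim + config.response_window_s + config.iti_s
    log = SessionLog(
        mouse_id=mouse_id,
        hemisphere=hemisphere,
        contingency=config.contingency,
        trials=trials,
        metadata={"n_trials": n_trials, "laser_fraction": config.laser_fraction},
    )
    return log, n_clip


def simulate_behavior_cohort(
    agent: AgentParams,
    task: TaskConfig,
    n_mice: int = 6,
    n_sessions: int = 3,
    trials_per_session: int = 300,
    seed: int | np.random.Generator | None = None,
    hemisphere: Literal["left", "right"] = "left",
    traces: bool = True,
) -> tuple[list[SessionLog], dict]:
    """Simulate a cohort of mice running optogenetic sessions.

    Returns (sessions, ground_truth). Sessions are tagged with mouse ids
    ``m00`` .. so per-animal analyses can regroup them. With
    ``traces=False`` outcomes and response times are drawn directly from
    the agent probabilities (identical distributions, i.i.d. cues, no ball
    traces) — the fast path for large calibration sweeps.

    Ground truth records the agent parameters, the per-condition action
    probabilities, the closed-form contra-action laser index expected under
    the generator, and the number of probability clip events.
    """
    if n_mice <= 0 or n_sessions <= 0 or trials_per_session <= 0:
        raise ValueError("cohort dimensions must be positive")
    rng = rng_from_seed(seed)
    sessions: list[SessionLog] = []
    n_clip = 0
    for m in range(n_mice):
        mouse = f"m{m:02d}"
        for s in range(n_sessions):
            if traces:
                policy = make_trace_agent(agent, task, hemisphere)
                log = run_session(
                    policy,
                    task,
                    trials_per_session,
                    seed=rng,
                    mouse_id=mouse,
                    hemisphere=hemisphere,
                )
            else:
                log, c = _simulate_session_fast(
                    agent, task, trials_per_session, rng, mouse, hemisphere
                )
                n_clip += c
            log.metadata["session"] = s
            sessions.append(log)
    probs = {
        f"p_pos_{cue}_{'l' if las else 'nl'}": _p_positive_action(agent, cue, las, task, hemisphere)[0]
        for cue in ("right", "left")
        for las in (False, True)
    }
    ground_truth = {
        "agent": asdict(agent),
        "contingency": task.contingency,
        "hemisphere": hemisphere,
        "action_probabilities": probs,
        "expected_contra_action_delta": expected_contra_action_delta(agent, task, hemisphere),
        "n_probability_clips": n_clip,
    }
    return sessions, ground_truth


# ---------------------------------------------------------------------------
# calcium imaging

@dataclass(frozen=True)
class CalciumSimParams:
    """Parameters of the two-photon fluorescence generator.

    Underlying activity is a tuning-weighted trial impulse train convolved
    with a GCaMP6s-like rise/decay kernel. Measured soma fluorescence adds
    neuropil contamination with coefficient ``neuropil_coefficient`` (the
    same value the correction assumes, so the subtraction removes it by
    construction; ``contamination_mismatch`` offsets the injected
    coefficient to study sensitivity), multiplicative slow drift (sinusoid
    plus random walk, period >= 100 s so a 60 s min/max baseline filter can
    track it), and white noise.
    """

    n_neurons: int = 100
    frac_labeled: float = 0.3
    cue_weight_scale: float = 0.3  # fractional dF/F per preferred-cue event
    action_weight_scale: float = 0.5
    nonpreferred_weight: float = 0.1  # multiplier on the non-preferred cue/action
    response_reliability: float = 0.7  # per-trial probability of responding
    labeled_action_gain: float = 1.0  # multiplier on action weights of labeled cells
    ipsi_bias: float = 0.0  # shift of P(preferred action = ipsi) away from 0.5
    rise_s: float = 0.2
    decay_s: float = 1.5
    baseline_f: float = 100.0
    drift_amplitude: float = 0.1
    drift_period_s: float = 300.0
    drift_walk_sd: float = 0.002  # per-frame random-walk step (fraction)
    neuropil_coefficient: float = 0.7
    contamination_mismatch: float = 0.0
    noise_sd: float = 2.0  # raw fluorescence units
    frame_rate_hz: float = 5.0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.decay_s > self.rise_s > 0:
            raise ValueError("need decay > rise > 0")
        if not 0.0 <= self.frac_labeled <= 1.0:
            raise ValueError("frac_labeled must lie in [0, 1]")
        if self.drift_period_s < 100.0:
            raise ValueError("drift period must be >= 100 s")


def _gcamp_kernel(params: CalciumSimParams) -> np.ndarray:
    dt = 1.0 / params.frame_rate_hz
    t = np.arange(0.0, 6.0 * params.decay_s, dt)
    k = (1.0 - np.exp(-t / params.rise_s)) * np.exp(-t / params.decay_s)
    return k / k.max()


def _drift(params: CalciumSimParams, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_frames) / params.frame_rate_hz
    sin = params.drift_amplitude * np.sin(2 * np.pi * t / params.drift_period_s)
    walk = np.cumsum(rng.normal(0.0, params.drift_walk_sd, n_frames))
    return sin + walk


def simulate_calcium_session(
    session: SessionLog,
    params: CalciumSimParams,
    seed: int | np.random.Generator | None = None,
):
    """Synthesize soma + neuropil fluorescence for a behavioral session.

    Returns ``(traces, ground_truth)`` where ``traces`` is an
    :class:`~orientrack.imaging.RoiTraceSet` and ``ground_truth`` holds the
    per-neuron tuning table (with contra/ipsi action weights and labeled
    flags) and the noiseless fractional signal each neuron expressed.
    """
    from .imaging import RoiTraceSet  # local import: imaging does not import back

    rng = rng_from_seed(seed)
    if not session.trials:
        raise ValueError("session has no trials")
    fr = params.frame_rate_hz
    t_end = session.trials[-1].stim_time_s + 5.0
    n_frames = int(np.ceil(t_end * fr)) + 1
    frame_times = np.arange(n_frames) / fr

    n = params.n_neurons
    labeled = rng.random(n) < params.frac_labeled
    # selective tuning: each neuron has a preferred cue side and action
    # direction; the non-preferred condition evokes only a weak response
    pref_cue_right = rng.random(n) < 0.5
    p_pref_ipsi = min(max(0.5 + params.ipsi_bias, 0.0), 1.0)
    pref_act_ipsi = rng.random(n) < p_pref_ipsi
    amp_cue = rng.gamma(2.0, params.cue_weight_scale / 2.0, n)
    amp_act = rng.gamma(2.0, params.action_weight_scale / 2.0, n)
    amp_act = amp_act * np.where(labeled, params.labeled_action_gain, 1.0)
    npw = params.nonpreferred_weight
    w_cue_right = amp_cue * np.where(pref_cue_right, 1.0, npw)
    w_cue_left = amp_cue * np.where(pref_cue_right, npw, 1.0)
    w_act_ipsi = amp_act * np.where(pref_act_ipsi, 1.0, npw)
    w_act_contra = amp_act * np.where(pref_act_ipsi, npw, 1.0)

    impulses = np.zeros((n, n_frames))
    for tr in session.trials:
        fi = int(round(tr.stim_time_s * fr))
        if fi >= n_frames:
            raise ValueError("frame budget shorter than session")
        amp = np.where(tr.cue_side == "right", w_cue_right, w_cue_left).astype(float)
        if tr.chosen_direction is not None:
            contra = action_is_contraversive(tr.chosen_direction, session.hemisphere)
            amp = amp + (w_act_contra if contra else w_act_ipsi)
        # trial-to-trial response failures, a hallmark of calcium data
        amp = amp * (rng.random(n) < params.response_reliability)
        impulses[:, fi] += amp

    kernel = _gcamp_kernel(params)
    signal = np.apply_along_axis(lambda x: np.convolve(x, kernel)[:n_frames], 1, impulses)

    neuropil = (
        0.5 * params.baseline_f
        + 0.05 * params.baseline_f * np.sin(2 * np.pi * frame_times / 120.0)[None, :]
        + rng.normal(0.0, params.noise_sd, (n, n_frames))
    )
    drift = np.stack([_drift(params, n_frames, rng) for _ in range(n)])
    r_inject = params.neuropil_coefficient + params.contamination_mismatch
    soma = (
        params.baseline_f * (1.0 + signal) * (1.0 + drift)
        + r_inject * neuropil
        + rng.normal(0.0, params.noise_sd, (n, n_frames))
    )

    traces = RoiTraceSet(
        soma_raw=soma,
        neuropil_raw=neuropil,
        frame_times=frame_times,
        frame_rate_hz=fr,
        roi_labels=np.where(labeled, "labeled", "unlabeled"),
    )
    tuning = pd.DataFrame(
        {
            "neuron": np.arange(n),
            "labeled": labeled,
            "w_cue_right": w_cue_right,
            "w_cue_left": w_cue_left,
            "w_action_contra": w_act_contra,
            "w_action_ipsi": w_act_ipsi,
        }
    )
    ground_truth = {"tuning": tuning, "true_dff_percent": signal * 100.0, "params": asdict(params)}
    return traces, ground_truth


def simulate_bouton_passive(
    n_boutons: int = 200,
    contra_frac: float = 0.87,
    effect_size: float = 0.3,
    n_trials_per_side: int = 30,
    params: CalciumSimParams | None = None,
    seed: int | np.random.Generator | None = None,
):
    """Passive-viewing bouton traces with lateralized 1 s stimuli.

    Each bouton prefers the contralateral side with probability
    ``contra_frac``; its response amplitude to the preferred side exceeds
    the non-preferred side by ``effect_size`` (fractional dF/F, floored at
    0). ``effect_size = 0`` gives equal responses — the null for
    preference-score calibration while remaining visually responsive.

    Returns ``(traces, stimuli, ground_truth)``: an
    :class:`~orientrack.imaging.RoiTraceSet` in bouton mode (neuropil
    unused), a stimulus table (onset_s, side), and the per-bouton truth.
    """
    from .imaging import RoiTraceSet

    if not 0.0 <= contra_frac <= 1.0:
        raise ValueError("contra_frac must lie in [0, 1]")
    params = params or CalciumSimParams()
    rng = rng_from_seed(seed)
    fr = params.frame_rate_hz
    iti = 5.0
    n_trials = 2 * n_trials_per_side
    sides = np.array(["contra"] * n_trials_per_side + ["ipsi"] * n_trials_per_side)
    rng.shuffle(sides)
    onsets = 4.0 + iti * np.arange(n_trials)
    n_frames = int(np.ceil((onsets[-1] + 5.0) * fr)) + 1
    frame_times = np.arange(n_frames) / fr

    prefers_contra = rng.random(n_boutons) < contra_frac
    base_amp = 0.5
    amp_pref = np.full(n_boutons, base_amp)
    amp_nonpref = np.maximum(base_amp - effect_size, 0.0) * np.ones(n_boutons)

    impulses = np.zeros((n_boutons, n_frames))
    trial_gain_sd = 0.15  # trial-to-trial variability of the evoked response
    for onset, side in zip(onsets, sides):
        fi = int(round(onset * fr))
        is_pref = prefers_contra == (side == "contra")
        amp = np.where(is_pref, amp_pref, amp_nonpref)
        impulses[:, fi] += np.maximum(amp + rng.normal(0.0, trial_gain_sd, n_boutons), 0.0)

    kernel = _gcamp_kernel(params)
    signal = np.apply_along_axis(lambda x: np.convolve(x, kernel)[:n_frames], 1, impulses)
    soma = params.baseline_f * (1.0 + signal) + rng.normal(
        0.0, params.noise_sd, (n_boutons, n_frames)
    )
    traces = RoiTraceSet(
        soma_raw=soma,
        neuropil_raw=np.zeros_like(soma),
        frame_times=frame_times,
        frame_rate_hz=fr,
        roi_labels=np.array(["bouton"] * n_boutons),
    )
    stimuli = pd.DataFrame({"onset_s": onsets, "side": sides})
    ground_truth = pd.DataFrame(
        {
            "bouton": np.arange(n_boutons),
            "prefers_contra": prefers_contra,
            "amp_preferred": amp_pref,
            "amp_nonpreferred": amp_nonpref,
        }
    )
    return traces, stimuli, ground_truth


# ---------------------------------------------------------------------------
# electrophysiology

@dataclass(frozen=True)
class SpikeSimParams:
    """Poisson spike-train generator in a laser/non-laser block design.

    Blocks of ``block_s`` seconds separated by ``interblock_s``; laser is
    applied on ``laser_block_fraction`` of blocks (the laser pulse itself
    spans ``laser_s``, bracketing the block). Laser-block rates are solved
    from each unit's target modulation index m: r_laser =
    r_baseline (1+m)/(1−m).
    """

    n_units: int = 20
    baseline_rate_hz: tuple[float, ...] | float = 5.0
    modulation_index: tuple[float, ...] | float = 0.0
    block_s: float = 6.0
    interblock_s: float = 1.0
    laser_block_fraction: float = 0.5
    laser_s: float = 7.0

    def unit_params(self) -> tuple[np.ndarray, np.ndarray]:
        base = np.broadcast_to(np.asarray(self.baseline_rate_hz, float), (self.n_units,)).copy()
        mod = np.broadcast_to(np.asarray(self.modulation_index, float), (self.n_units,)).copy()
        if np.any(base < 0):
            raise ValueError("rates must be non-negative")
        if np.any(np.abs(mod) > 1):
            raise ValueError("|modulation_index| must be <= 1")
        return base, mod


def simulate_spike_trains(
    params: SpikeSimParams,
    n_blocks: int = 40,
    seed: int | np.random.Generator | None = None,
):
    """Homogeneous-Poisson spikes in a randomized laser-block schedule.

    Returns ``(spike_set, ground_truth)`` with a
    :class:`~orientrack.ephys.SpikeTrainSet` and the per-unit true rates.
    """
    from .ephys import SpikeTrainSet

    if n_blocks % 2 != 0:
        raise ValueError("n_blocks must be even (half laser)")
    base, mod = params.unit_params()
    if np.any((mod == -1.0) & (base == 0.0)):
        raise ValueError("index −1 with baseline 0 is undefined")
    if np.any(mod >= 1.0):
        raise ValueError("index +1 requires an infinite laser rate")
    laser_rate = base * (1.0 + mod) / (1.0 - mod)

    rng = rng_from_seed(seed)
    n_laser = int(round(params.laser_block_fraction * n_blocks))
    flags = np.zeros(n_blocks, dtype=bool)
    flags[rng.choice(n_blocks, n_laser, replace=False)] = True
    period = params.block_s + params.interblock_s
    starts = np.arange(n_blocks) * period
    blocks = np.column_stack([starts, starts + params.block_s])
    laser_blocks = [tuple(b) for b in blocks[flags]]
    nonlaser_blocks = [tuple(b) for b in blocks[~flags]]

    spike_times = []
    for u in range(params.n_units):
        spikes = []
        for (s, e), is_laser in zip(blocks, flags):
            rate = laser_rate[u] if is_laser else base[u]
            count = rng.poisson(rate * (e - s))
            spikes.append(np.sort(rng.uniform(s, e, count)))
        spike_times.append(np.concatenate(spikes))
    spike_set = SpikeTrainSet(
        spike_times=spike_times,
        laser_blocks=laser_blocks,
        nonlaser_blocks=nonlaser_blocks,
    )
    ground_truth = pd.DataFrame(
        {
            "unit": np.arange(params.n_units),
            "baseline_rate_hz": base,
            "laser_rate_hz": laser_rate,
            "modulation_index": mod,
        }
    )
    return spike_set, ground_truth


# ---------------------------------------------------------------------------
# pose

@dataclass(frozen=True)
class PoseSimParams:
    """Pose-clip generator: a turning body with laterally offset forepaws.

    ``paw_offset`` is the ground-truth mean paw x-position in the body
    frame (pixels; positive = animal's right). The body axis rotates by
    ``body_angle_drift`` degrees per frame in the turn direction.
    """

    turn_direction: Literal["left", "right"] = "left"
    paw_offset: float = 10.0
    body_angle_drift: float = 1.0
    noise_sd: float = 0.5
    n_frames: int = 60
    frame_rate_hz: float = 30.0
    body_length_px: float = 60.0
    paw_separation_px: float = 16.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


def simulate_pose_clip(
    params: PoseSimParams, seed: int | np.random.Generator | None = None
):
    """Generate one pose clip and its ground truth.

    Returns ``(clip, ground_truth)`` where ``clip`` is a
    :class:`~orientrack.pose.PoseClip` in image coordinates (anchor = tail
    base or headplate) and ground truth records the body-frame paw offset.
    """
    from .pose import PoseClip

    rng = rng_from_seed(seed)
    n = params.n_frames
    # body-frame layout: anchor at origin, nose up the +y body axis
    nose_b = np.array([0.0, params.body_length_px])
    paw_y = 0.6 * params.body_length_px
    left_paw_b = np.array([params.paw_offset - params.paw_separation_px / 2.0, paw_y])
    right_paw_b = np.array([params.paw_offset + params.paw_separation_px / 2.0, paw_y])

    sweep_sign = 1.0 if params.turn_direction == "left" else -1.0
    phis = 90.0 + sweep_sign * params.body_angle_drift * np.arange(n)  # nose bearing, deg
    anchor = np.array([320.0, 240.0])

    def place(p_body: np.ndarray) -> np.ndarray:
        th = np.deg2rad(phis - 90.0)
        rot = np.stack(
            [
                np.cos(th) * p_body[0] - np.sin(th) * p_body[1],
                np.sin(th) * p_body[0] + np.cos(th) * p_body[1],
            ],
            axis=1,
        )
        return anchor + rot + rng.normal(0.0, params.noise_sd, (n, 2))

    clip = PoseClip(
        anchor=np.tile(anchor, (n, 1)) + rng.normal(0.0, params.noise_sd, (n, 2)),
        nose=place(nose_b),
        left_paw=place(left_paw_b),
        right_paw=place(right_paw_b),
        frame_rate_hz=params.frame_rate_hz,
        condition=params.turn_direction,
    )
    ground_truth = {
        "mean_paw_x": params.paw_offset,
        "turn_direction": params.turn_direction,
        "params": asdict(params),
    }
    return clip, ground_truth
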