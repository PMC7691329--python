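"""Closed-loop trackball task engine.

Deterministic state machine for the two-choice visuomotor task: head-fixed
mice report the side of a lateral visual cue by rotating a trackball. Under
the *inward* contingency a 15° rotation in the correct direction brings the
cue to the screen center; under *outward* the mapping is mirrored. The
engine classifies cumulative ball-angle traces into correct / incorrect /
timeout outcomes, schedules cues (with the error-repeat anti-bias rule) and
laser trials (never two in a row), and runs spontaneous no-cue sessions
with the dual anti-bias reward rules.

Sign convention (declared once, used everywhere): positive cumulative angle
is the rotation that moves a right-side stimulus toward the screen center
in the inward task. Relative to the left hemisphere this is the
contraversive action; all downstream contra/ipsi labels derive from this
constant and the session's ``hemisphere`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Literal

import json

import numpy as np
import pandas as pd

from ._rng import rng_from_seed

__all__ = [
    "TaskConfig",
    "BallTrace",
    "TrialRecord",
    "SessionLog",
    "classify_trial",
    "anti_bias_next_cue",
    "laser_schedule",
    "run_session",
    "spontaneous_session",
    "action_is_contraversive",
]

CueSide = Literal["left", "right"]
Outcome = Literal["correct", "incorrect", "timeout"]
Direction = Literal["pos", "neg"]

#: Positive ball angle = rotation bringing a right-side cue to center
#: (inward task) = contraversive action for a left-hemisphere analysis.
POSITIVE_IS_CONTRA_FOR_LEFT_HEMISPHERE = True

_TICK_S = 0.010  # ball polled every 10 ms


@dataclass(frozen=True)
class TaskConfig:
    """Task parameters; defaults are the final-stage training values."""

    contingency: Literal["inward", "outward"] = "inward"
    threshold_deg: float = 15.0
    response_window_s: float = 1.0
    hold_still_s: float = 1.0
    iti_s: float = 2.5
    deg_per_pixel: float = 0.15
    spontaneous_threshold_deg: float = 5.0
    spontaneous_trial_s: float = 2.0
    anti_bias: bool = True
    laser_fraction: float = 0.0
    laser_window: tuple[float, float] = (0.3, 1.0)  # (pre, post) around cue onset

    def __post_init__(self) -> None:
        if self.threshold_deg <= 0 or self.spontaneous_threshold_deg <= 0:
            raise ValueError("thresholds must be positive")
        if self.response_window_s <= 0 or self.spontaneous_trial_s <= 0:
            raise ValueError("windows must be positive")
        if not 0.0 <= self.laser_fraction <= 0.5:
            raise ValueError("laser_fraction must lie in [0, 0.5]")
        if self.contingency not in ("inward", "outward"):
            raise ValueError("contingency must be 'inward' or 'outward'")


@dataclass(frozen=True)
class BallTrace:
    """Cumulative ball angle sampled at ~10 ms ticks from cue onset (t=0)."""

    times: np.ndarray
    cumulative_angle: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.cumulative_angle, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative_angle", a)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and angles must be 1-D and equally long")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "angle_deg": self.cumulative_angle})


@dataclass
class TrialRecord:
    cue_side: CueSide
    laser: bool
    outcome: Outcome
    response_time_s: float | None = None
    chosen_direction: Direction | None = None
    start_time_s: float = 0.0
    stim_time_s: float = 0.0
    trace: BallTrace | None = None
    rewarded: bool | None = None  # spontaneous sessions only

    def __post_init__(self) -> None:
        if (self.outcome == "timeout") != (self.response_time_s is None):
            raise ValueError("response_time must be absent iff outcome is timeout")


@dataclass
class SessionLog:
    """One behavioral session: ordered trials plus provenance metadata."""

    mouse_id: str
    hemisphere: Literal["left", "right"]
    contingency: Literal["inward", "outward", "spontaneous"]
    trials: list[TrialRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial summary (traces omitted)."""
        rows = []
        for i, tr in enumerate(self.trials):
            rows.append(
                {
                    "trial": i,
                    "mouse_id": self.mouse_id,
                    "cue_side": tr.cue_side,
                    "laser": tr.laser,
                    "outcome": tr.outcome,
                    "response_time_s": np.nan if tr.response_time_s is None else tr.response_time_s,
                    "chosen_direction": tr.chosen_direction,
                    "start_time_s": tr.start_time_s,
                    "stim_time_s": tr.stim_time_s,
                    "rewarded": tr.rewarded,
                }
            )
        return pd.DataFrame(rows)

    def to_jsonl(self, path, include_traces: bool = False) -> None:
        """One JSON object per trial, preceded by a header line."""
        with open(path, "w") as fh:
            header = {
                "mouse_id": self.mouse_id,
                "hemisphere": self.hemisphere,
                "contingency": self.contingency,
                "metadata": self.metadata,
            }
            fh.write(json.dumps({"header": header}) + "\n")
            for tr in self.trials:
                rec = asdict(tr)
                trace = rec.pop("trace")
                if include_traces and trace is not None:
                    rec["trace"] = {
                        "time_s": [round(float(v), 4) for v in trace["times"]],
                        "angle_deg": [round(float(v), 4) for v in trace["cumulative_angle"]],
                    }
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "SessionLog":
        with open(path) as fh:
            header = json.loads(fh.readline())["header"]
            trials = []
            for line in fh:
                rec = json.loads(line)
                trace = rec.pop("trace", None)
                if trace is not None:
                    trace = BallTrace(np.asarray(trace["time_s"]), np.asarray(trace["angle_deg"]))
                trials.append(TrialRecord(trace=trace, **rec))
        return cls(trials=trials, **header)


def action_is_contraversive(direction: Direction, hemisphere: str) -> bool:
    """Map a signed rotation direction to contra/ipsi given the hemisphere."""
    pos_is_contra = POSITIVE_IS_CONTRA_FOR_LEFT_HEMISPHERE == (hemisphere == "left")
    return (direction == "pos") == pos_is_contra


def _correct_direction(cue_side: CueSide, contingency: str) -> Direction:
    # inward: right cue -> positive rotation is correct; outward mirrors it
    pos_correct = cue_side == "right"
    if contingency == "outward":
        pos_correct = not pos_correct
    return "pos" if pos_correct else "neg"


def classify_trial(
    trace: BallTrace, cue_side: CueSide, config: TaskConfig
) -> tuple[Outcome, float | None, Direction | None]:
    """Classify one cumulative-angle trace into (outcome, RT, direction).

    The first time the cumulative angle reaches +threshold or −threshold
    within the response window decides the trial; excursions short of
    threshold must be offset, exactly as in the closed-loop stimulus
    coupling. No crossing within the window is a timeout.
    """
    t = trace.times
    ang = trace.cumulative_angle
    in_window = t <= config.response_window_s
    hit_pos = (ang >= config.threshold_deg) & in_window
    hit_neg = (ang <= -config.threshold_deg) & in_window
    hits = np.flatnonzero(hit_pos | hit_neg)
    if hits.size == 0:
        return "timeout", None, None
    i = int(hits[0])
    direction: Direction = "pos" if hit_pos[i] else "neg"
    outcome: Outcome = (
        "correct" if direction == _correct_direction(cue_side, config.contingency) else "incorrect"
    )
    return outcome, float(t[i]), direction


def anti_bias_next_cue(
    prev_cue: CueSide | None,
    prev_outcome: Outcome | None,
    rng: np.random.Generator,
) -> CueSide:
    """Error-repeat rule: repeat the cue after a non-correct trial,
    otherwise draw uniformly (also for the first trial)."""
    if prev_cue is not None and prev_outcome is not None and prev_outcome != "correct":
        return prev_cue
    return "right" if rng.random() < 0.5 else "left"


def laser_schedule(
    n_trials: int, fraction: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Boolean laser flags with no two consecutive laser trials.

    The number of laser trials is ``round(fraction * n_trials)`` and the
    set of positions is drawn uniformly over all subsets with no two
    adjacent indices (via the bijection between such k-subsets of n and
    plain k-subsets of n-k+1), so the hard constraint holds exactly and
    the realized fraction is within rounding of the target.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError("fraction must lie in [0, 0.5]")
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    rng = rng_from_seed(rng)
    k = int(round(fraction * n_trials))
    flags = np.zeros(n_trials, dtype=bool)
    if k == 0:
        return flags
    if k > (n_trials + 1) // 2:
        raise ValueError("cannot place that many non-adjacent laser trials")
    picks = np.sort(rng.choice(n_trials - k + 1, size=k, replace=False))
    flags[picks + np.arange(k)] = True
    return flags


AgentPolicy = Callable[[CueSide, bool, np.random.Generator], BallTrace]


def _check_ticks(trace: BallTrace) -> None:
    if trace.times.size >= 2:
        dt = np.diff(trace.times)
        if np.any(dt > 5 * _TICK_S) or np.any(dt <= 0):
            raise ValueError("agent trace violates the ~10 ms tick spacing")


def run_session(
    agent_policy: AgentPolicy,
    config: TaskConfig,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
    mouse_id: str = "sim",
    hemisphere: Literal["left", "right"] = "left",
    keep_traces: bool = True,
) -> SessionLog:
    """Run a full closed-loop session against an agent policy.

    The agent maps (cue_side, laser, rng) to a :class:`BallTrace` starting
    at cue onset. Hold-to-start and the inter-trial interval are dead time
    and only advance the session clock. Deterministic for a fixed seed.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = rng_from_seed(seed)
    lasers = laser_schedule(n_trials, config.laser_fraction, rng)
    trials: list[TrialRecord] = []
    clock = 0.0
    prev_cue: CueSide | None = None
    prev_outcome: Outcome | None = None
    for i in range(n_trials):
        if config.anti_bias:
            cue = anti_bias_next_cue(prev_cue, prev_outcome, rng)
        else:
            cue = "right" if rng.random() < 0.5 else "left"
        trace = agent_policy(cue, bool(lasers[i]), rng)
        _check_ticks(trace)
        outcome, rt, direction = classify_trial(trace, cue, config)
        start = clock
        stim = start + config.hold_still_s  # cue onset after the hold period
        trials.append(
            TrialRecord(
                cue_side=cue,
                laser=bool(lasers[i]),
                outcome=outcome,
                response_time_s=rt,
                chosen_direction=direction,
                start_time_s=start,
                stim_time_s=stim,
                trace=trace if keep_traces else None,
            )
        )
        clock = stim + config.response_window_s + config.iti_s
        prev_cue, prev_outcome = cue, outcome
    return SessionLog(
        mouse_id=mouse_id,
        hemisphere=hemisphere,
        contingency=config.contingency,
        trials=trials,
        metadata={"n_trials": n_trials, "laser_fraction": config.laser_fraction},
    )


def spontaneous_session(
    agent_policy: Callable[[bool, np.random.Generator], BallTrace],
    config: TaskConfig,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
    mouse_id: str = "sim",
    hemisphere: Literal["left", "right"] = "left",
    keep_traces: bool = False,
) -> SessionLog:
    """No-cue session of back-to-back 2 s "trials".

    Per trial one rotation direction is designated rewarded. A movement
    reaching ±5° within the trial counts as an attempt in its direction and
    is rewarded iff it matches the designation. Two anti-bias rules run
    together: the designated direction repeats after an unrewarded trial
    and switches after a rewarded one. The agent policy maps
    (laser, rng) to a trace; cues play no role.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = rng_from_seed(seed)
    lasers = laser_schedule(n_trials, config.laser_fraction, rng)
    spont_cfg = TaskConfig(
        contingency="inward",
        threshold_deg=config.spontaneous_threshold_deg,
        response_window_s=config.spontaneous_trial_s,
    )
    designated: Direction = "pos" if rng.random() < 0.5 else "neg"
    trials: list[TrialRecord] = []
    clock = 0.0
    for i in range(n_trials):
        trace = agent_policy(bool(lasers[i]), rng)
        _check_ticks(trace)
        # classify against the rewarded direction: a "right" cue makes the
        # positive direction correct under the inward mapping
        cue: CueSide = "right" if designated == "pos" else "left"
        outcome, rt, direction = classify_trial(trace, cue, spont_cfg)
        rewarded = outcome == "correct"
        trials.append(
            TrialRecord(
                cue_side=cue,
                laser=bool(lasers[i]),
                outcome=outcome,
                response_time_s=rt,
                chosen_direction=direction,
                start_time_s=clock,
                stim_time_s=clock,
                trace=trace if keep_traces else None,
                rewarded=rewarded,
            )
        )
        designated = ("neg" if designated == "pos" else "pos") if rewarded else designated
        clock += config.spontaneous_trial_s
    return SessionLog(
        mouse_id=mouse_id,
        hemisphere=hemisphere,
        contingency="spontaneous",
        trials=trials,
        metadata={"n_trials": n_trials, "laser_fraction": config.laser_fraction},
    )
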