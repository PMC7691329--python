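"""Behavioral performance metrics and optogenetic laser-effect analysis.

Implements the trial-outcome rates (timeout rate over all trials of a cue;
incorrect rate over completed trials only), the side-preference index, the
laser-induced contra-action and right-stimulus bias indices, spontaneous
movement deltas, ball-velocity summaries, and the cohort-level
within-animal permutation analysis with Bonferroni control (per-comparison
alpha 0.05/2 = 0.025 for the right/left cue pair).

The cohort analysis follows a model/results pattern:
``LaserEffectModel(sessions).fit(n_perm=1000, seed=0)`` returns a
:class:`LaserEffectResults` whose ``summary()`` tabulates each metric's
pooled observed effect, permutation p, and significance flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import PermutationResult, bonferroni_alpha, permutation_test_laser
from .task import BallTrace, SessionLog, TrialRecord, action_is_contraversive

__all__ = [
    "ConditionRates",
    "SpontaneousRates",
    "LaserEffectModel",
    "LaserEffectResults",
    "performance_summary",
    "side_preference",
    "laser_delta_index",
    "spontaneous_rates",
    "spontaneous_delta",
    "movement_velocity",
    "laser_effect_analysis",
    "cohort_trial_table",
]

MOVEMENT_START_DEG = 0.5


def contra_cue_side(contingency: str, hemisphere: str) -> str:
    """Which cue side instructs the contraversive action."""
    right_is_contra = (contingency == "inward") == (hemisphere == "left")
    return "right" if right_is_contra else "left"


@dataclass(frozen=True)
class ConditionRates:
    """Per cue x laser outcome rates with recorded denominators.

    ``cells`` is indexed by ``(group, laser)`` with group in
    {'right', 'left', 'contra', 'ipsi'} (the latter two are the cue groups
    relabeled by which action they instruct) and laser in
    {True, False, None} (None = all trials). Each cell records n_trials,
    n_timeout, n_completed, n_correct, n_incorrect, the derived rates, and
    the mean response time over complete correct responses. Rates with a
    zero denominator are NaN and flagged via ``defined``.
    """

    cells: Mapping[tuple[str, bool | None], Mapping[str, float]]
    hemisphere: str
    contingency: str

    def rate(self, group: str, kind: str, laser: bool | None) -> float:
        """kind in {'corr', 'incorr', 'timeout', 'rt'}."""
        cell = self.cells[(group, laser)]
        key = {"corr": "correct_rate", "incorr": "incorrect_rate",
               "timeout": "timeout_rate", "rt": "mean_rt"}[kind]
        return cell[key]

    def defined(self, group: str, kind: str, laser: bool | None) -> bool:
        return bool(np.isfinite(self.rate(group, kind, laser)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (group, laser), cell in self.cells.items():
            rows.append({"group": group, "laser": laser, **cell})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SpontaneousRates:
    """Attempt proportions by direction and laser condition.

    Within each laser condition the contraversive and ipsiversive
    proportions sum to 1 over attempted movements (>= 5 deg crossings).
    """

    contraversive_l: float
    contraversive_nl: float
    ipsiversive_l: float
    ipsiversive_nl: float
    n_attempts_l: int
    n_attempts_nl: int


def _trials_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        rows.append(
            {
                "cue_side": tr.cue_side,
                "laser": tr.laser,
                "outcome": tr.outcome,
                "response_time_s": np.nan if tr.response_time_s is None else tr.response_time_s,
                "chosen_direction": tr.chosen_direction,
            }
        )
    return pd.DataFrame(rows)


def _cell(df: pd.DataFrame) -> dict[str, float]:
    n = len(df)
    n_timeout = int((df["outcome"] == "timeout").sum())
    completed = df[df["outcome"] != "timeout"]
    n_completed = len(completed)
    n_correct = int((completed["outcome"] == "correct").sum())
    n_incorrect = n_completed - n_correct
    rt = completed.loc[completed["outcome"] == "correct", "response_time_s"]
    return {
        "n_trials": n,
        "n_timeout": n_timeout,
        "n_completed": n_completed,
        "n_correct": n_correct,
        "n_incorrect": n_incorrect,
        "timeout_rate": n_timeout / n if n else np.nan,
        "incorrect_rate": n_incorrect / n_completed if n_completed else np.nan,
        "correct_rate": n_correct / n_completed if n_completed else np.nan,
        "mean_rt": float(rt.mean()) if len(rt) else np.nan,
    }


def performance_summary(
    session: SessionLog | Sequence[SessionLog],
    hemisphere: str | None = None,
    contingency: str | None = None,
) -> ConditionRates:
    """Outcome rates per cue (and per cued action) split by laser flag.

    Timeout-rate denominators are all trials of the cue; incorrect-rate
    denominators are completed trials only; response time is averaged over
    complete correct responses. Contra/ipsi groups relabel the cue groups
    by the action each cue instructs given hemisphere and contingency.
    """
    sessions = [session] if isinstance(session, SessionLog) else list(session)
    hemisphere = hemisphere or sessions[0].hemisphere
    contingency = contingency or sessions[0].contingency
    df = pd.concat([_trials_frame(s.trials) for s in sessions], ignore_index=True)
    c_cue = contra_cue_side(contingency, hemisphere)
    cells: dict[tuple[str, bool | None], dict[str, float]] = {}
    for group in ("right", "left", "contra", "ipsi"):
        if group in ("right", "left"):
            sub = df[df["cue_side"] == group]
        else:
            side = c_cue if group == "contra" else ("left" if c_cue == "right" else "right")
            sub = df[df["cue_side"] == side]
        for laser in (False, True, None):
            cell_df = sub if laser is None else sub[sub["laser"] == laser]
            cells[(group, laser)] = _cell(cell_df)
    return ConditionRates(cells=cells, hemisphere=hemisphere, contingency=contingency)


def side_preference(rates: ConditionRates, laser: bool | None = None) -> float:
    """Side-preference index (contra − ipsi)/(contra + ipsi).

    contra and ipsi are the proportions of completed trials on which each
    action was correctly selected (timeouts excluded). Both zero is
    undefined (NaN).
    """
    contra = rates.rate("contra", "corr", laser)
    ipsi = rates.rate("ipsi", "corr", laser)
    if not (np.isfinite(contra) and np.isfinite(ipsi)):
        raise ValueError("correct-selection proportions undefined for a side")
    if contra + ipsi == 0:
        return np.nan
    return (contra - ipsi) / (contra + ipsi)


def laser_delta_index(
    rates: ConditionRates, mode: Literal["contra_action", "right_stimulus"]
) -> float:
    """Laser-induced response-bias index.

    ``contra_action``: ((contra_corr,l + ipsi_incorr,l) −
    (contra_corr,nl + ipsi_incorr,nl)) / (contra_corr,nl + ipsi_incorr,nl);
    both constituent rates are probabilities of selecting the contraversive
    action. ``right_stimulus`` uses right_corr and left_incorr instead —
    probabilities of selecting the response the right cue instructs. The
    cue-to-action mapping resolves per contingency, so the same form works
    for inward and outward sessions.
    """
    if mode == "contra_action":
        g1, g2 = "contra", "ipsi"
    elif mode == "right_stimulus":
        g1, g2 = "right", "left"
    else:
        raise ValueError("mode must be 'contra_action' or 'right_stimulus'")
    terms = {}
    for laser in (True, False):
        a = rates.rate(g1, "corr", laser)
        b = rates.rate(g2, "incorr", laser)
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError("constituent rate undefined")
        terms[laser] = a + b
    if terms[False] == 0:
        raise ValueError("zero non-laser denominator")
    return (terms[True] - terms[False]) / terms[False]


def spontaneous_rates(
    session: SessionLog | Sequence[SessionLog], hemisphere: str | None = None
) -> SpontaneousRates:
    """Directional attempt proportions for spontaneous (no-cue) sessions.

    Only attempted movements (threshold crossings) count, regardless of
    reward; directions map to contra/ipsi via the hemisphere.
    """
    sessions = [session] if isinstance(session, SessionLog) else list(session)
    hemisphere = hemisphere or sessions[0].hemisphere
    trials = [t for s in sessions for t in s.trials if t.chosen_direction is not None]
    vals = {}
    ns = {}
    for laser in (True, False):
        sub = [t for t in trials if t.laser == laser]
        ns[laser] = len(sub)
        if not sub:
            vals[laser] = np.nan
            continue
        contra = sum(action_is_contraversive(t.chosen_direction, hemisphere) for t in sub)
        vals[laser] = contra / len(sub)
    return SpontaneousRates(
        contraversive_l=vals[True],
        contraversive_nl=vals[False],
        ipsiversive_l=1.0 - vals[True] if np.isfinite(vals[True]) else np.nan,
        ipsiversive_nl=1.0 - vals[False] if np.isfinite(vals[False]) else np.nan,
        n_attempts_l=ns[True],
        n_attempts_nl=ns[False],
    )


def spontaneous_delta(rates: SpontaneousRates) -> tuple[float, float]:
    """Laser-induced fractional change per direction: (x_l − x_nl)/x_nl."""
    out = []
    for x_l, x_nl in (
        (rates.contraversive_l, rates.contraversive_nl),
        (rates.ipsiversive_l, rates.ipsiversive_nl),
    ):
        if not np.isfinite(x_nl) or x_nl == 0:
            raise ValueError("non-laser proportion must be positive")
        out.append((x_l - x_nl) / x_nl)
    return out[0], out[1]


def movement_velocity(
    trace: BallTrace,
    threshold_deg: float = 15.0,
    start_deg: float = MOVEMENT_START_DEG,
) -> float | None:
    """Mean instantaneous ball speed (deg/s) during the response movement.

    Averaged per-tick \\|Δangle\\|/Δt from movement start (first sample with
    cumulative \\|angle\\| > ``start_deg``) until the first threshold
    crossing (or the end of the trace when the threshold is never
    reached). Returns None when the movement-start criterion is never met.
    """
    ang = trace.cumulative_angle
    t = trace.times
    started = np.flatnonzero(np.abs(ang) > start_deg)
    if started.size == 0:
        return None
    i0 = int(started[0])
    crossed = np.flatnonzero(np.abs(ang) >= threshold_deg)
    i1 = int(crossed[0]) if crossed.size else ang.size - 1
    if i1 <= i0:
        i1 = min(i0 + 1, ang.size - 1)
    if i1 == i0:
        return None
    steps = np.abs(np.diff(ang[i0 : i1 + 1])) / np.diff(t[i0 : i1 + 1])
    return float(np.mean(steps))


# ---------------------------------------------------------------------------
# cohort-level permutation analysis

_OUTCOME_CODE = {"correct": 0, "incorrect": 1, "timeout": 2}


def cohort_trial_table(sessions: Sequence[SessionLog]) -> pd.DataFrame:
    """Flatten sessions into one trial table with derived labels.

    Columns: mouse_id, laser, cue_right, contra_cued, completed, correct,
    incorrect, timeout, rt.
    """
    rows = []
    for s in sessions:
        c_cue = contra_cue_side(s.contingency, s.hemisphere)
        for tr in s.trials:
            code = _OUTCOME_CODE[tr.outcome]
            rows.append(
                (
                    s.mouse_id,
                    tr.laser,
                    tr.cue_side == "right",
                    tr.cue_side == c_cue,
                    code != 2,
                    code == 0,
                    code == 1,
                    code == 2,
                    np.nan if tr.response_time_s is None else tr.response_time_s,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id", "laser", "cue_right", "contra_cued",
            "completed", "correct", "incorrect", "timeout", "rt",
        ],
    )


def _rate(num: np.ndarray, den: np.ndarray) -> float:
    d = den.sum()
    return num.sum() / d if d else np.nan


def _metric_delta_incorrect(cue_right: bool):
    def metric(cols: Mapping[str, np.ndarray], laser: np.ndarray) -> float:
        m = (cols["cue_right"] == cue_right) & cols["completed"]
        return _rate(cols["incorrect"] & m & laser, m & laser) - _rate(
            cols["incorrect"] & m & ~laser, m & ~laser
        )

    return metric


def _metric_delta_timeout(cue_right: bool):
    def metric(cols: Mapping[str, np.ndarray], laser: np.ndarray) -> float:
        m = cols["cue_right"] == cue_right
        return _rate(cols["timeout"] & m & laser, m & laser) - _rate(
            cols["timeout"] & m & ~laser, m & ~laser
        )

    return metric


def _metric_delta_rt(cue_right: bool):
    def metric(cols: Mapping[str, np.ndarray], laser: np.ndarray) -> float:
        m = (cols["cue_right"] == cue_right) & cols["correct"]
        rt = cols["rt"]
        a, b = rt[m & laser], rt[m & ~laser]
        if a.size == 0 or b.size == 0:
            return np.nan
        return float(a.mean() - b.mean())

    return metric


def _bias_index(sel_flag: str):
    """Eq-style bias index: sel_flag 'contra_cued' -> contra-action index,
    'cue_right' -> right-stimulus index."""

    def metric(cols: Mapping[str, np.ndarray], laser: np.ndarray) -> float:
        grp = cols[sel_flag]
        comp = cols["completed"]
        terms = {}
        for las_val in (True, False):
            las = laser if las_val else ~laser
            corr = _rate(cols["correct"] & grp & comp & las, grp & comp & las)
            incorr = _rate(cols["incorrect"] & ~grp & comp & las, ~grp & comp & las)
            terms[las_val] = corr + incorr
        if not np.isfinite(terms[False]) or terms[False] == 0:
            return np.nan
        return (terms[True] - terms[False]) / terms[False]

    return metric


_METRICS = {
    "delta_incorrect_right": _metric_delta_incorrect(True),
    "delta_incorrect_left": _metric_delta_incorrect(False),
    "delta_timeout_right": _metric_delta_timeout(True),
    "delta_timeout_left": _metric_delta_timeout(False),
    "delta_rt_right": _metric_delta_rt(True),
    "delta_rt_left": _metric_delta_rt(False),
    "delta_contra_action": _bias_index("contra_cued"),
    "delta_right_stimulus": _bias_index("cue_right"),
}


@dataclass
class LaserEffectResults:
    """Cohort laser-effect estimates with permutation p-values."""

    effects: dict[str, PermutationResult]
    per_animal: pd.DataFrame
    alpha: float
    n_mice: int

    @property
    def significant(self) -> dict[str, bool]:
        return {k: r.p_two_sided < self.alpha for k, r in self.effects.items()}

    def summary(self) -> pd.DataFrame:
        sig = self.significant
        rows = []
        for name, res in self.effects.items():
            animal_means = self.per_animal[name]
            rows.append(
                {
                    "metric": name,
                    "observed_pooled": res.observed_effect,
                    "per_animal_mean": float(animal_means.mean()),
                    "p_permutation": res.p_two_sided,
                    "significant": sig[name],
                    "n_permutations": res.n_permutations,
                }
            )
        return pd.DataFrame(rows)

    def to_json_record(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_mice": self.n_mice,
            "effects": {k: r.to_json_record() for k, r in self.effects.items()},
            "significant": self.significant,
        }


class LaserEffectModel:
    """Cohort-level optogenetic effect analysis.

    Groups sessions by mouse (data from multiple sessions are combined per
    animal), computes each laser-effect metric on the pooled trial table,
    and assesses significance with the within-animal label-permutation
    test. The observed statistic is the same pooled quantity each
    permutation round recomputes; equal-weight per-animal means are
    reported alongside as a diagnostic.
    """

    def __init__(self, sessions: Sequence[SessionLog], metrics: Sequence[str] | None = None):
        if not sessions:
            raise ValueError("no sessions")
        self.sessions = list(sessions)
        table = cohort_trial_table(self.sessions)
        self.mice = sorted(table["mouse_id"].unique())
        if len(self.mice) < 2:
            raise ValueError("need at least 2 mice")
        self.metric_names = list(metrics) if metrics is not None else list(_METRICS)
        unknown = set(self.metric_names) - set(_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        # canonical per-animal trial order: results are exactly invariant to
        # the order sessions (and mice) are supplied in
        sort_cols = ["laser", "cue_right", "contra_cued", "correct", "incorrect", "timeout", "rt"]
        self._per_animal_tables = [
            table[table["mouse_id"] == m]
            .drop(columns="mouse_id")
            .sort_values(sort_cols, kind="mergesort", na_position="last")
            .reset_index(drop=True)
            for m in self.mice
        ]

    def fit(
        self,
        n_perm: int = 1000,
        seed: int | np.random.Generator | None = None,
        alpha: float = bonferroni_alpha(0.05, 2),
    ) -> LaserEffectResults:
        effects: dict[str, PermutationResult] = {}
        from ._rng import rng_from_seed, spawn

        rngs = spawn(rng_from_seed(seed), len(self.metric_names))
        for name, rng in zip(self.metric_names, rngs):
            effects[name] = permutation_test_laser(
                self._per_animal_tables, _METRICS[name], n_perm=n_perm, seed=rng
            )
        per_animal = pd.DataFrame(
            {
                name: [
                    _METRICS[name](
                        {k: t[k].to_numpy() for k in t.columns if k != "laser"},
                        t["laser"].to_numpy(),
                    )
                    for t in self._per_animal_tables
                ]
                for name in self.metric_names
            },
            index=pd.Index(self.mice, name="mouse_id"),
        )
        return LaserEffectResults(
            effects=effects, per_animal=per_animal, alpha=alpha, n_mice=len(self.mice)
        )


def laser_effect_analysis(
    cohort: Sequence[SessionLog],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = bonferroni_alpha(0.05, 2),
    metrics: Sequence[str] | None = None,
) -> LaserEffectResults:
    """Functional wrapper over :class:`LaserEffectModel`."""
    return LaserEffectModel(cohort, metrics=metrics).fit(n_perm=n_perm, seed=seed, alpha=alpha)
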