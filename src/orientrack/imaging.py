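"""Fluorescence trace pipeline and task/passive response statistics.

The trace pipeline follows the standard somatic-imaging order: neuropil
subtraction F = F_soma − r·F_neuropil (r = 0.7; skipped for axonal
boutons), ΔF/F in percent against the highest-density fluorescence value
F0, slow-baseline removal with a Gaussian → minimum → maximum filter
cascade (1 s Gaussian, 60 s windows), then per-ROI z-scoring. Trial
tensors align z-scored traces to stimulus onset or response time with
four-way cue × action condition labels, and the statistics mirror the
study's task analyses (1 s post-stimulus means, contra-vs-ipsi contrasts,
velocity median splits) and passive bouton analyses (signed-rank
responsiveness, AUROC preference score with a label-shuffle null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import rng_from_seed
from .stats import (
    ShuffleNullResult,
    auroc,
    binomial_ci,
    fisher_exact_two_sided,
    rank_tests,
    shuffle_significance,
)
from .task import SessionLog, action_is_contraversive

__all__ = [
    "RoiTraceSet",
    "DffTraces",
    "TrialTensor",
    "neuropil_dff",
    "detrend_baseline",
    "zscore_traces",
    "build_trial_tensor",
    "neuron_condition_stats",
    "bouton_visual_stats",
    "preference_fisher_comparison",
]

NEUROPIL_COEFFICIENT = 0.7
CONDITIONS = ("right-contra", "right-ipsi", "left-contra", "left-ipsi")


@dataclass
class RoiTraceSet:
    """Raw soma and matched neuropil fluorescence (rois × frames)."""

    soma_raw: np.ndarray
    neuropil_raw: np.ndarray
    frame_times: np.ndarray
    frame_rate_hz: float = 5.0
    roi_labels: np.ndarray | None = None  # 'labeled' | 'unlabeled' | 'bouton'

    def __post_init__(self) -> None:
        self.soma_raw = np.asarray(self.soma_raw, dtype=float)
        self.neuropil_raw = np.asarray(self.neuropil_raw, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.soma_raw.shape != self.neuropil_raw.shape:
            raise ValueError("soma and neuropil matrices must share a shape")
        if self.frame_times.size != self.soma_raw.shape[1]:
            raise ValueError("frame_times length must equal the frame count")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        if self.roi_labels is None:
            self.roi_labels = np.array(["unlabeled"] * self.soma_raw.shape[0])
        else:
            self.roi_labels = np.asarray(self.roi_labels)

    @property
    def n_rois(self) -> int:
        return self.soma_raw.shape[0]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("soma_raw", data=self.soma_raw)
            f.create_dataset("neuropil_raw", data=self.neuropil_raw)
            f.create_dataset("frame_times", data=self.frame_times)
            f.create_dataset("labels", data=np.asarray(self.roi_labels, dtype="S"))
            f.attrs["frame_rate_hz"] = self.frame_rate_hz

    @classmethod
    def from_hdf5(cls, path) -> "RoiTraceSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                soma_raw=f["soma_raw"][()],
                neuropil_raw=f["neuropil_raw"][()],
                frame_times=f["frame_times"][()],
                frame_rate_hz=float(f.attrs["frame_rate_hz"]),
                roi_labels=f["labels"][()].astype(str),
            )


@dataclass
class DffTraces:
    """ΔF/F traces (percent) with F0 provenance and validity flags."""

    dff: np.ndarray
    f0: np.ndarray
    valid: np.ndarray
    frame_times: np.ndarray
    frame_rate_hz: float
    neuropil_coefficient: float
    detrended: bool = False
    roi_labels: np.ndarray | None = None


def _density_mode(x: np.ndarray, n_grid: int = 512) -> float:
    """Location of the maximum of a Gaussian KDE of ``x``.

    Binned implementation: histogram on a grid spanning the 1st–99th
    percentile, smoothed with a Gaussian of Silverman's bandwidth.
    """
    lo, hi = np.percentile(x, [1.0, 99.0])
    if not hi > lo:
        return float(np.median(x))
    grid_w = (hi - lo) / n_grid
    counts, edges = np.histogram(x, bins=n_grid, range=(lo, hi))
    sd = np.std(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        return float(np.median(x))
    bw = 0.9 * spread * x.size ** (-0.2)
    smoothed = ndimage.gaussian_filter1d(counts.astype(float), sigma=max(bw / grid_w, 1e-6))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(centers[np.argmax(smoothed)])


def neuropil_dff(
    traces: RoiTraceSet,
    r: float = NEUROPIL_COEFFICIENT,
    mode: Literal["auto", "soma", "bouton"] = "auto",
) -> DffTraces:
    """Neuropil-corrected ΔF/F in percent.

    F = F_soma − r·F_neuropil for somatic ROIs; bouton traces skip the
    subtraction. F0 is the fluorescence value of highest density over the
    session (Gaussian KDE mode), and DFF = (F − F0)/F0 × 100. ROIs with
    F0 <= 0 are flagged invalid and carry NaN traces.
    """
    if mode == "auto":
        mode = "bouton" if np.all(traces.roi_labels == "bouton") else "soma"
    f = traces.soma_raw if mode == "bouton" else traces.soma_raw - r * traces.neuropil_raw
    f0 = np.array([_density_mode(row) for row in f])
    valid = np.isfinite(f0) & (f0 > 0)
    dff = np.full_like(f, np.nan)
    dff[valid] = (f[valid] - f0[valid, None]) / f0[valid, None] * 100.0
    return DffTraces(
        dff=dff,
        f0=f0,
        valid=valid,
        frame_times=traces.frame_times,
        frame_rate_hz=traces.frame_rate_hz,
        neuropil_coefficient=0.0 if mode == "bouton" else r,
        roi_labels=traces.roi_labels,
    )


def detrend_baseline(
    dff: DffTraces | np.ndarray,
    frame_rate: float | None = None,
    gauss_width_s: float = 1.0,
    window_s: float = 60.0,
) -> DffTraces | np.ndarray:
    """Remove slow baseline drift from ΔF/F traces.

    The moving baseline is a Gaussian smooth (σ = ``gauss_width_s``)
    followed by a minimum filter then a maximum filter, both with centered
    windows of ``window_s`` (constant edge handling); it is subtracted
    from the trace. Run before z-scoring.
    """
    if isinstance(dff, DffTraces):
        out = detrend_baseline(dff.dff, dff.frame_rate_hz, gauss_width_s, window_s)
        return DffTraces(
            dff=out,
            f0=dff.f0,
            valid=dff.valid,
            frame_times=dff.frame_times,
            frame_rate_hz=dff.frame_rate_hz,
            neuropil_coefficient=dff.neuropil_coefficient,
            detrended=True,
            roi_labels=dff.roi_labels,
        )
    if frame_rate is None:
        raise ValueError("frame_rate required for bare arrays")
    x = np.asarray(dff, dtype=float)
    n_frames = x.shape[-1]
    win = int(round(window_s * frame_rate))
    win += 1 - win % 2  # centered (odd) window
    if n_frames < win:
        raise ValueError("session shorter than the baseline window")
    smooth = ndimage.gaussian_filter1d(x, sigma=gauss_width_s * frame_rate, axis=-1, mode="nearest")
    base = ndimage.minimum_filter1d(smooth, size=win, axis=-1, mode="nearest")
    base = ndimage.maximum_filter1d(base, size=win, axis=-1, mode="nearest")
    return x - base


def zscore_traces(dff: DffTraces | np.ndarray) -> np.ndarray:
    """Per-ROI z-score over the full session."""
    x = dff.dff if isinstance(dff, DffTraces) else np.asarray(dff, dtype=float)
    mu = np.nanmean(x, axis=-1, keepdims=True)
    sd = np.nanstd(x, axis=-1, keepdims=True)
    sd = np.where(sd > 0, sd, np.nan)
    return (x - mu) / sd


@dataclass
class TrialTensor:
    """ROIs × trials × frames aligned to an anchor, with condition labels."""

    activity: np.ndarray
    rel_times: np.ndarray
    condition: np.ndarray  # e.g. 'right-contra'
    cue: np.ndarray  # 'right' | 'left'
    action: np.ndarray  # 'contra' | 'ipsi'
    anchor: Literal["stimulus", "response"]
    included: bool
    dropped_trials: list = field(default_factory=list)
    trial_index: np.ndarray | None = None
    roi_labels: np.ndarray | None = None

    def condition_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.condition == c)) for c in CONDITIONS}


def build_trial_tensor(
    dff_z: np.ndarray,
    frame_times: np.ndarray,
    session: SessionLog,
    anchor: Literal["stimulus", "response"] = "stimulus",
    window: tuple[float, float] = (-1.0, 2.0),
    min_trials_per_condition: int = 5,
    roi_labels: np.ndarray | None = None,
) -> TrialTensor:
    """Slice z-scored traces around each completed trial's anchor.

    Timeout trials carry no action label and are excluded from the 4-way
    cue × action conditions. Trials whose window falls outside the
    recording are dropped with a log entry. Sessions with fewer than
    ``min_trials_per_condition`` trials in any condition are marked
    excluded (``included=False``) but the tensor is still returned.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    fr = 1.0 / np.median(np.diff(frame_times))
    n0 = int(round(window[0] * fr))
    n1 = int(round(window[1] * fr))
    rel = np.arange(n0, n1 + 1) / fr
    slices, conds, cues, actions, kept, dropped = [], [], [], [], [], []
    for i, tr in enumerate(session.trials):
        if tr.outcome == "timeout" or tr.chosen_direction is None:
            continue
        t_anchor = tr.stim_time_s if anchor == "stimulus" else tr.stim_time_s + tr.response_time_s
        # half-up rounding onto the frame grid: consistent under time shifts
        # (unlike nearest-value argmin, which breaks equidistant ties by index)
        ci = int(np.floor((t_anchor - frame_times[0]) * fr + 0.5))
        lo, hi = ci + n0, ci + n1
        if lo < 0 or hi >= frame_times.size:
            dropped.append((i, "window outside recording"))
            continue
        action = "contra" if action_is_contraversive(tr.chosen_direction, session.hemisphere) else "ipsi"
        slices.append(dff_z[:, lo : hi + 1])
        conds.append(f"{tr.cue_side}-{action}")
        cues.append(tr.cue_side)
        actions.append(action)
        kept.append(i)
    if not slices:
        raise ValueError("no usable trials")
    activity = np.stack(slices, axis=1)
    condition = np.array(conds)
    counts = {c: int(np.sum(condition == c)) for c in CONDITIONS}
    included = all(v >= min_trials_per_condition for v in counts.values())
    return TrialTensor(
        activity=activity,
        rel_times=rel,
        condition=condition,
        cue=np.array(cues),
        action=np.array(actions),
        anchor=anchor,
        included=included,
        dropped_trials=dropped,
        trial_index=np.array(kept),
        roi_labels=roi_labels,
    )


def _post_stim_mean(tensor: TrialTensor, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Per-trial response: activity averaged over the window [lo, hi] s."""
    m = (tensor.rel_times >= lo) & (tensor.rel_times <= hi)
    return np.nanmean(tensor.activity[:, :, m], axis=2)  # rois × trials


@dataclass
class NeuronTaskStats:
    """Per-neuron condition means and population contrasts."""

    per_neuron: pd.DataFrame
    population: dict
    condition_means: pd.DataFrame


def neuron_condition_stats(
    tensor: TrialTensor,
    velocities: np.ndarray | None = None,
    alpha: float = 0.05,
) -> NeuronTaskStats:
    """Task-condition statistics on a stimulus-aligned tensor.

    Per neuron: mean z-scored response in the 1 s post-stimulus window for
    each cue × action condition and the cue/action marginals (each
    marginal is the average of its two constituent condition means).
    Population: paired signed-rank contrasts of contra vs ipsi within each
    cue, right vs left cue, and contra vs ipsi marginals, plus the
    fraction of neurons with a significant across-trial action difference
    per cue (rank-sum at ``alpha``) with exact binomial CI. If per-trial
    ball ``velocities`` are provided, a session-wide median split
    compares high- vs low-velocity responses.
    """
    if tensor.anchor != "stimulus":
        raise ValueError("condition stats require a stimulus-aligned tensor")
    resp = _post_stim_mean(tensor)  # rois × trials
    n_rois = resp.shape[0]
    cond_means = {}
    for c in CONDITIONS:
        m = tensor.condition == c
        cond_means[c] = np.nanmean(resp[:, m], axis=1) if m.any() else np.full(n_rois, np.nan)
    per_neuron = pd.DataFrame({f"mean_{c}": v for c, v in cond_means.items()})
    per_neuron["mean_right_cue"] = (cond_means["right-contra"] + cond_means["right-ipsi"]) / 2
    per_neuron["mean_left_cue"] = (cond_means["left-contra"] + cond_means["left-ipsi"]) / 2
    per_neuron["mean_contra"] = (cond_means["right-contra"] + cond_means["left-contra"]) / 2
    per_neuron["mean_ipsi"] = (cond_means["right-ipsi"] + cond_means["left-ipsi"]) / 2

    def _paired(a: str, b: str) -> dict:
        x, y = per_neuron[a].to_numpy(), per_neuron[b].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        try:
            p, z = rank_tests(x[ok], y[ok], paired=True)
        except ValueError:
            p, z = np.nan, np.nan
        return {"p": p, "z": z, "n": int(ok.sum())}

    population = {
        "right_cue_contra_vs_ipsi": _paired("mean_right-contra", "mean_right-ipsi"),
        "left_cue_contra_vs_ipsi": _paired("mean_left-contra", "mean_left-ipsi"),
        "right_vs_left_cue": _paired("mean_right_cue", "mean_left_cue"),
        "contra_vs_ipsi_action": _paired("mean_contra", "mean_ipsi"),
    }

    # per-neuron across-trial action difference, per cue
    for cue in ("right", "left"):
        sig = np.zeros(n_rois, dtype=bool)
        testable = np.zeros(n_rois, dtype=bool)
        m_contra = (tensor.cue == cue) & (tensor.action == "contra")
        m_ipsi = (tensor.cue == cue) & (tensor.action == "ipsi")
        if m_contra.sum() >= 2 and m_ipsi.sum() >= 2:
            for r_i in range(n_rois):
                try:
                    p, _ = rank_tests(resp[r_i, m_contra], resp[r_i, m_ipsi], paired=False)
                except ValueError:
                    continue
                testable[r_i] = True
                sig[r_i] = p < alpha
        per_neuron[f"sig_action_diff_{cue}"] = sig
        n_testable = int(testable.sum())
        frac = sig.sum() / n_testable if n_testable else np.nan
        ci = binomial_ci(int(sig.sum()), n_testable) if n_testable else (np.nan, np.nan)
        population[f"frac_action_diff_{cue}"] = {
            "fraction": frac, "n_significant": int(sig.sum()),
            "n_neurons": n_testable, "ci95": ci,
        }

    if velocities is not None:
        v = np.asarray(velocities, dtype=float)
        if v.size != resp.shape[1]:
            raise ValueError("velocities must align with tensor trials")
        ok = np.isfinite(v)
        med = np.median(v[ok])
        hi_m = ok & (v > med)
        lo_m = ok & (v <= med)
        hi_resp = np.nanmean(resp[:, hi_m], axis=1)
        lo_resp = np.nanmean(resp[:, lo_m], axis=1)
        per_neuron["mean_high_velocity"] = hi_resp
        per_neuron["mean_low_velocity"] = lo_resp
        fin = np.isfinite(hi_resp) & np.isfinite(lo_resp)
        try:
            p, z = rank_tests(hi_resp[fin], lo_resp[fin], paired=True)
        except ValueError:
            p, z = np.nan, np.nan
        population["high_vs_low_velocity"] = {"p": p, "z": z, "median_split": float(med)}

    condition_means = pd.DataFrame(
        {c: np.nanmean(v) for c, v in cond_means.items()}, index=["population_mean"]
    )
    return NeuronTaskStats(per_neuron=per_neuron, population=population, condition_means=condition_means)


@dataclass
class BoutonVisualStats:
    """Per-bouton responsiveness and stimulus-preference table + counts."""

    per_bouton: pd.DataFrame
    n_responsive: int
    n_contra_preferring: int
    n_ipsi_preferring: int

    @property
    def n_boutons(self) -> int:
        return len(self.per_bouton)


def bouton_visual_stats(
    dff: np.ndarray,
    frame_times: np.ndarray,
    stimuli: pd.DataFrame,
    n_shuffles: int = 1000,
    alpha_responsive: float = 0.01,
    seed: int | np.random.Generator | None = None,
    response_window: tuple[float, float] = (0.6, 1.2),
    pre_window_s: float = 1.0,
) -> BoutonVisualStats:
    """Passive-viewing bouton analysis.

    Responsiveness: two-sided signed-rank of pre-stimulus means (1 s) vs
    post-stimulus means (0.6–1.2 s after onset) across trials at
    ``alpha_responsive``. For responsive boutons the AUROC over
    contralateral vs ipsilateral trial responses gives the preference
    score 2(AUROC − 0.5) (+1 = complete contra preference), whose
    significance comes from a 1000-fold trial-label shuffle (outside the
    central 95%). Boutons with fewer than 2 trials per side are excluded.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    rng = rng_from_seed(seed)
    onsets = stimuli["onset_s"].to_numpy(dtype=float)
    sides = stimuli["side"].to_numpy()
    pre = np.zeros((dff.shape[0], onsets.size))
    post = np.zeros_like(pre)
    for j, t0 in enumerate(onsets):
        m_pre = (frame_times >= t0 - pre_window_s) & (frame_times < t0)
        m_post = (frame_times >= t0 + response_window[0]) & (frame_times <= t0 + response_window[1])
        if not m_pre.any() or not m_post.any():
            raise ValueError("stimulus window outside recording")
        pre[:, j] = np.nanmean(dff[:, m_pre], axis=1)
        post[:, j] = np.nanmean(dff[:, m_post], axis=1)

    is_contra = sides == "contra"
    if is_contra.sum() < 2 or (~is_contra).sum() < 2:
        raise ValueError("need at least 2 trials per side")
    score = lambda a, b: 2.0 * (auroc(a, b) - 0.5)
    rows = []
    for b in range(dff.shape[0]):
        try:
            p_resp, _ = rank_tests(post[b], pre[b], paired=True)
        except ValueError:
            p_resp = 1.0
        responsive = p_resp < alpha_responsive
        rec = {
            "bouton": b,
            "p_responsive": p_resp,
            "responsive": responsive,
            "auroc": np.nan,
            "preference_score": np.nan,
            "preference_significant": False,
        }
        if responsive:
            resp_contra = post[b, is_contra]
            resp_ipsi = post[b, ~is_contra]
            res: ShuffleNullResult = shuffle_significance(
                resp_contra, resp_ipsi, score, n_shuffles=n_shuffles, seed=rng
            )
            rec["auroc"] = (res.observed / 2.0) + 0.5
            rec["preference_score"] = res.observed
            rec["preference_significant"] = res.significant
        rows.append(rec)
    per_bouton = pd.DataFrame(rows)
    sig = per_bouton["preference_significant"]
    return BoutonVisualStats(
        per_bouton=per_bouton,
        n_responsive=int(per_bouton["responsive"].sum()),
        n_contra_preferring=int((sig & (per_bouton["preference_score"] > 0)).sum()),
        n_ipsi_preferring=int((sig & (per_bouton["preference_score"] < 0)).sum()),
    )


def preference_fisher_comparison(
    count_a: int, n_a: int, count_b: int, n_b: int
) -> float:
    """log10 p of a two-sided Fisher test comparing preferring fractions
    between two bouton populations (e.g. VC vs callosal axons)."""
    return fisher_exact_two_sided([[count_a, n_a - count_a], [count_b, n_b - count_b]])
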