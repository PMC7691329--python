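"""Linear population decoding of selected actions.

Two procedures mirror the study's analyses: (1) cross-session pseudotrial
decoding, where same-condition trials from separately recorded sessions
are randomly paired into composite population vectors and a soft-margin
linear SVM (C = 1e-4, the heavily regularized value of the original
LIBSVM setup) is cross-validated over balanced subsamples, with chance
estimated by shuffling test labels; and (2) within-session comparison of
projection-labeled neurons against size-matched random subsamples of
unlabeled neurons.

``PseudotrialDecoder(sessions, config).fit(seed)`` returns a
:class:`DecodingResult`; features are built with
:func:`response_features` from response-aligned trial tensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._rng import rng_from_seed
from .imaging import TrialTensor
from .stats import rank_tests

__all__ = [
    "DecoderConfig",
    "DecodingResult",
    "SessionFeatures",
    "response_features",
    "PseudotrialDecoder",
    "decode_pseudotrials",
    "decode_within_session",
]

CONDITIONS = ("right-contra", "right-ipsi", "left-contra", "left-ipsi")


@dataclass(frozen=True)
class DecoderConfig:
    """Decoding procedure parameters."""

    C: float = 1e-4
    window: tuple[float, float] = (-0.2, 0.4)
    folds: int = 10
    iterations: int = 1000
    trials_per_condition: int = 5
    central: float = 0.95

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.folds < 2 or self.iterations < 1 or self.trials_per_condition < 1:
            raise ValueError("invalid fold/iteration/subsample counts")


@dataclass(frozen=True)
class DecodingResult:
    """Accuracy of the action decoder against its shuffle null."""

    mean_accuracy: float
    sd_across_iterations: float
    null_mean: float
    null_central_interval: tuple[float, float]
    significant: bool
    n_iterations: int

    def to_json_record(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_across_iterations": self.sd_across_iterations,
            "null_mean": self.null_mean,
            "null_central_interval": list(self.null_central_interval),
            "significant": self.significant,
            "n_iterations": self.n_iterations,
        }


@dataclass
class SessionFeatures:
    """Per-trial population features with action and cue labels."""

    X: np.ndarray  # trials × rois
    action: np.ndarray  # 'contra' | 'ipsi'
    cue: np.ndarray  # 'right' | 'left'
    roi_labels: np.ndarray | None = None
    name: str = "session"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.action) or self.X.shape[0] != len(self.cue):
            raise ValueError("label lengths must match the trial count")

    @property
    def condition(self) -> np.ndarray:
        return np.array([f"{c}-{a}" for c, a in zip(self.cue, self.action)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"roi{j}" for j in range(self.X.shape[1])])
        df.insert(0, "cue", self.cue)
        df.insert(0, "action", self.action)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "session") -> "SessionFeatures":
        roi_cols = [c for c in df.columns if c not in ("action", "cue")]
        return cls(
            X=df[roi_cols].to_numpy(dtype=float),
            action=df["action"].to_numpy(),
            cue=df["cue"].to_numpy(),
            name=name,
        )


def response_features(
    tensor: TrialTensor, window: tuple[float, float] = (-0.2, 0.4)
) -> SessionFeatures:
    """One scalar per ROI per trial: activity averaged over the
    response-aligned window (−0.2 s to +0.4 s around the response)."""
    if tensor.anchor != "response":
        raise ValueError("features require a response-aligned tensor")
    m = (tensor.rel_times >= window[0] - 1e-9) & (tensor.rel_times <= window[1] + 1e-9)
    if not m.any():
        raise ValueError("window outside the tensor slice")
    X = np.nanmean(tensor.activity[:, :, m], axis=2).T  # trials × rois
    return SessionFeatures(X=X, action=tensor.action, cue=tensor.cue, roi_labels=tensor.roi_labels)


def _sample_condition_trials(
    sess: SessionFeatures, k: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Sample k trial indices per cue × action condition, shuffled
    independently so cross-session pairing is re-randomized."""
    out = {}
    cond = sess.condition
    for c in CONDITIONS:
        idx = np.flatnonzero(cond == c)
        if idx.size < k:
            raise ValueError(f"session '{sess.name}' lacks {k} trials of condition {c}")
        out[c] = rng.choice(idx, size=k, replace=False)
    return out


def _assemble_pseudotrials(
    sessions: Sequence[SessionFeatures], k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """k trials per condition per session, concatenated across sessions
    into pseudotrial feature vectors. Returns (X, y) with y in
    {'contra', 'ipsi'}; each action label contains equal numbers of
    right- and left-cue trials by construction."""
    blocks = []
    for sess in sessions:
        picks = _sample_condition_trials(sess, k, rng)
        rows = np.concatenate([picks[c] for c in CONDITIONS])
        blocks.append(sess.X[rows])
    X = np.concatenate(blocks, axis=1)
    y = np.concatenate([[c.split("-")[1]] * k for c in CONDITIONS])
    return X, y


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    config: DecoderConfig,
    rng: np.random.Generator,
    shuffle_test: bool,
) -> float:
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    accs = []
    for train, test in skf.split(X, y):
        clf = SVC(kernel="linear", C=config.C)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        truth = y[test].copy()
        if shuffle_test:
            truth = rng.permutation(truth)
        accs.append(float(np.mean(pred == truth)))
    return float(np.mean(accs))


class PseudotrialDecoder:
    """Cross-session pseudotrial action decoder.

    Each iteration draws ``trials_per_condition`` trials from every
    cue × action condition in every session, pairs them randomly across
    sessions into concatenated population vectors, and cross-validates a
    linear SVM over the balanced set (stratified folds). The chance
    distribution repeats the procedure with shuffled test labels;
    significance is the observed mean falling outside the central 95% of
    the shuffled iteration means. A single session degenerates to
    within-session decoding under the identical pipeline.
    """

    def __init__(self, sessions: Sequence[SessionFeatures], config: DecoderConfig | None = None):
        if not sessions:
            raise ValueError("need at least one session")
        self.sessions = list(sessions)
        self.config = config or DecoderConfig()
        k = self.config.trials_per_condition
        for sess in self.sessions:
            _sample_condition_trials(sess, k, rng_from_seed(0))  # validation only

    def fit(self, seed: int | np.random.Generator | None = None) -> DecodingResult:
        cfg = self.config
        rng = rng_from_seed(seed)
        acc = np.empty(cfg.iterations)
        null = np.empty(cfg.iterations)
        for it in range(cfg.iterations):
            X, y = _assemble_pseudotrials(self.sessions, cfg.trials_per_condition, rng)
            acc[it] = _cv_accuracy(X, y, cfg, rng, shuffle_test=False)
            Xn, yn = _assemble_pseudotrials(self.sessions, cfg.trials_per_condition, rng)
            null[it] = _cv_accuracy(Xn, yn, cfg, rng, shuffle_test=True)
        tail = (1.0 - cfg.central) / 2.0 * 100.0
        lo, hi = np.percentile(null, [tail, 100.0 - tail])
        mean_acc = float(acc.mean())
        return DecodingResult(
            mean_accuracy=mean_acc,
            sd_across_iterations=float(acc.std(ddof=0)),
            null_mean=float(null.mean()),
            null_central_interval=(float(lo), float(hi)),
            significant=bool(mean_acc < lo or mean_acc > hi),
            n_iterations=cfg.iterations,
        )


def decode_pseudotrials(
    sessions: Sequence[SessionFeatures],
    config: DecoderConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> DecodingResult:
    """Functional wrapper over :class:`PseudotrialDecoder`."""
    return PseudotrialDecoder(sessions, config).fit(seed)


def decode_within_session(
    session: SessionFeatures,
    config: DecoderConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Labeled vs size-matched unlabeled decoding within one session.

    Each iteration subsamples the unlabeled ROIs down to the labeled count
    (used whole when the counts match) and runs the identical balanced-CV
    procedure for both populations on the same trial subsample. Returns
    (labeled_accuracy, unlabeled_accuracy), each averaged over
    iterations.
    """
    cfg = config or DecoderConfig()
    if session.roi_labels is None:
        raise ValueError("session lacks roi labels")
    labels = np.asarray(session.roi_labels)
    lab_idx = np.flatnonzero(labels == "labeled")
    unl_idx = np.flatnonzero(labels == "unlabeled")
    if lab_idx.size == 0:
        raise ValueError("no labeled rois")
    if lab_idx.size > unl_idx.size:
        raise ValueError("labeled count exceeds unlabeled count")
    rng = rng_from_seed(seed)
    acc_lab = np.empty(cfg.iterations)
    acc_unl = np.empty(cfg.iterations)
    for it in range(cfg.iterations):
        picks = _sample_condition_trials(session, cfg.trials_per_condition, rng)
        rows = np.concatenate([picks[c] for c in CONDITIONS])
        y = np.concatenate([[c.split("-")[1]] * cfg.trials_per_condition for c in CONDITIONS])
        sub = unl_idx if unl_idx.size == lab_idx.size else rng.choice(
            unl_idx, size=lab_idx.size, replace=False
        )
        fold_seed = rng.integers(2**31)
        acc_lab[it] = _cv_accuracy(
            session.X[np.ix_(rows, lab_idx)], y, cfg, rng_from_seed(int(fold_seed)), False
        )
        acc_unl[it] = _cv_accuracy(
            session.X[np.ix_(rows, sub)], y, cfg, rng_from_seed(int(fold_seed)), False
        )
    return float(acc_lab.mean()), float(acc_unl.mean())


def compare_population_accuracies(
    paired_accuracies: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Cohort-level paired signed-rank test of labeled vs unlabeled
    decoding accuracy across sessions. Returns (p, z)."""
    lab = [a for a, _ in paired_accuracies]
    unl = [b for _, b in paired_accuracies]
    return rank_tests(lab, unl, paired=True)
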