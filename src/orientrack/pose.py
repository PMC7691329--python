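"""Body-axis pose transform and forepaw position summaries.

Tracked landmark coordinates (forepaws, nose, and an anchor — tail base in
freely moving mice, headplate when head-fixed) are rotated frame-by-frame
into a body-centered frame: the anchor sits at the origin and the nose
lies on the +y axis. The transform is rigid (translation + rotation), so
all pairwise distances are preserved and the result is equivariant to
global rigid motions of the input. The clip summary is the mean x-position
of both paws (positive = animal's right).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = [
    "PoseClip",
    "BodyFrameClip",
    "body_frame_transform",
    "paw_summary",
]

PARTS = ("anchor", "nose", "left_paw", "right_paw")


@dataclass
class PoseClip:
    """Per-frame landmark coordinates (pixels); NaN rows mark missing parts."""

    anchor: np.ndarray
    nose: np.ndarray
    left_paw: np.ndarray
    right_paw: np.ndarray
    frame_rate_hz: float = 30.0
    condition: str | None = None  # turn / rotation direction tag

    def __post_init__(self) -> None:
        n = None
        for part in PARTS:
            arr = np.asarray(getattr(self, part), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{part} must be an (n_frames, 2) array")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("all parts must cover the same frames")
            setattr(self, part, arr)

    @property
    def n_frames(self) -> int:
        return self.anchor.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for part in PARTS:
            arr = getattr(self, part)
            for i in range(self.n_frames):
                rows.append({"frame": i, "part": part, "x": arr[i, 0], "y": arr[i, 1]})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate_hz: float = 30.0,
                   condition: str | None = None) -> "PoseClip":
        n = int(df["frame"].max()) + 1
        parts = {}
        for part in PARTS:
            arr = np.full((n, 2), np.nan)
            sub = df[df["part"] == part]
            arr[sub["frame"].to_numpy(int)] = sub[["x", "y"]].to_numpy(float)
            parts[part] = arr
        return cls(frame_rate_hz=frame_rate_hz, condition=condition, **parts)


@dataclass
class BodyFrameClip:
    """Pose clip in body coordinates: anchor at origin, nose on +y."""

    nose: np.ndarray
    left_paw: np.ndarray
    right_paw: np.ndarray
    valid: np.ndarray
    frame_rate_hz: float = 30.0
    condition: str | None = None
    n_skipped: int = 0


def body_frame_transform(clip: PoseClip) -> BodyFrameClip:
    """Rotate each frame so the nose lies 90° (on +y) from the anchor.

    Per frame: translate the anchor to the origin, compute the nose
    bearing θ = atan2(nose_y, nose_x), and rotate every part by
    (90° − θ). Frames missing the anchor or nose are skipped (marked
    invalid, coordinates NaN).
    """
    n = clip.n_frames
    nose = clip.nose - clip.anchor
    lp = clip.left_paw - clip.anchor
    rp = clip.right_paw - clip.anchor
    valid = np.all(np.isfinite(clip.anchor), axis=1) & np.all(np.isfinite(clip.nose), axis=1)
    valid &= np.hypot(nose[:, 0], nose[:, 1]) > 0
    theta = np.arctan2(nose[:, 1], nose[:, 0])
    rot = np.pi / 2.0 - theta
    c, s = np.cos(rot), np.sin(rot)

    def apply(p: np.ndarray) -> np.ndarray:
        out = np.column_stack([c * p[:, 0] - s * p[:, 1], s * p[:, 0] + c * p[:, 1]])
        out[~valid] = np.nan
        return out

    return BodyFrameClip(
        nose=apply(nose),
        left_paw=apply(lp),
        right_paw=apply(rp),
        valid=valid,
        frame_rate_hz=clip.frame_rate_hz,
        condition=clip.condition,
        n_skipped=int((~valid).sum()),
    )


def paw_summary(body_clip: BodyFrameClip) -> float:
    """Mean x-position of both paws over all valid frames of the clip."""
    v = body_clip.valid
    if not v.any():
        raise ValueError("no valid frames")
    xs = np.concatenate([body_clip.left_paw[v, 0], body_clip.right_paw[v, 0]])
    xs = xs[np.isfinite(xs)]
    if xs.size == 0:
        raise ValueError("no valid paw coordinates")
    return float(np.mean(xs))
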