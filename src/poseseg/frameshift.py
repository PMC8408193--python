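"""Frameshift prediction: full-frame-rate labels from 10 fps predictions.

Behavior is predicted on 100 ms feature bins (10 fps) for signal-to-noise,
but the camera runs F = fps/10 times faster. The frameshift paradigm runs
the binning-and-prediction path F times, each pass offset by one native
frame, and interleaves the F downsampled label streams g_f into a native-
rate label series G with G[f::F] = g_f. A 200 fps video therefore gets 20
offset passes of one 5 ms frame each. Bouts are maximal constant-label
runs of G; runs shorter than a minimum number of samples (default 3,
<50 ms at 60 fps) are treated as spurious jitter events and excluded from
the bout list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import BehaviorClassifier, predict
from .errors import ParameterError, PosesegError
from .features import BIN_RATE, pose_to_features
from .pose_io import PoseSeries

__all__ = [
    "LabelSeries",
    "Bout",
    "frameshift_predict",
    "coherence",
    "extract_bouts",
    "overlap_above_baseline",
    "spurious_repeat_probability",
]


@dataclass
class LabelSeries:
    """Per-native-frame labels G assembled from F offset streams g_f."""

    G: np.ndarray  # (T,) int labels
    fps: float
    per_offset: list[np.ndarray] = field(default_factory=list)
    model_id: str = ""

    @property
    def F(self) -> int:
        return round(self.fps / BIN_RATE)

    @property
    def n_frames(self) -> int:
        return len(self.G)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.G)), "label": self.G})


@dataclass
class Bout:
    """A maximal run of one behavior label, half-open in native frames."""

    label: int
    start_frame: int
    end_frame: int
    fps: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_frames / self.fps


def frameshift_predict(
    p: PoseSeries,
    model: BehaviorClassifier,
    signed_angles: bool = False,
    model_id: str = "",
) -> LabelSeries:
    """Predict per-offset 10 fps streams and interleave them at native rate.

    Native frames beyond the last complete 100 ms bin of their offset
    stream inherit that stream's final label, so every frame is labelled.
    """
    if p.fps < BIN_RATE:
        raise ParameterError(
            f"frame rate {p.fps} Hz below {BIN_RATE} Hz is unsupported"
        )
    f_count = round(p.fps / BIN_RATE)
    t_native = p.n_frames
    g = np.empty(t_native, dtype=int)
    per_offset: list[np.ndarray] = []
    for f in range(f_count):
        fm = pose_to_features(p, offset=f, signed_angles=signed_angles)
        g_f = predict(model, fm)
        need = len(range(f, t_native, f_count))
        if len(g_f) == 0:
            raise PosesegError("session too short for a single complete bin")
        if len(g_f) < need:  # tail frames inherit the last emitted label
            g_f = np.concatenate([g_f, np.full(need - len(g_f), g_f[-1])])
        g_f = g_f[:need]
        g[f::f_count] = g_f
        per_offset.append(g_f)
    return LabelSeries(g, p.fps, per_offset, model_id=model_id)


def coherence(ls: LabelSeries, reference_offset: int = 0) -> dict:
    """Per-group % agreement between G and the upsampled reference stream.

    The non-frameshifted stream (offset ``reference_offset``, default 0) is
    upsampled by repeating each label F times; for every group the percent
    of G-frames of that group on which the two streams agree is reported,
    together with the median across groups.
    """
    if not ls.per_offset:
        raise ParameterError("LabelSeries carries no per-offset streams")
    g0 = ls.per_offset[reference_offset]
    up = np.repeat(g0, ls.F)[: ls.n_frames]
    if len(up) < ls.n_frames:
        up = np.concatenate([up, np.full(ls.n_frames - len(up), g0[-1])])
    per_group: dict[int, float] = {}
    for grp in np.unique(ls.G):
        mask = ls.G == grp
        if not mask.any():
            warnings.warn(f"group {grp} empty; skipped", stacklevel=2)
            continue
        per_group[int(grp)] = float(100.0 * (up[mask] == grp).mean())
    return dict(
        per_group=per_group,
        median=float(np.median(list(per_group.values()))),
    )


def _runs(g: np.ndarray) -> list[tuple[int, int, int]]:
    """(label, start, end) runs of a label array, half-open."""
    g = np.asarray(g)
    if g.size == 0:
        return []
    change = np.flatnonzero(np.diff(g)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(g)]])
    return [(int(g[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def extract_bouts(ls: LabelSeries, min_samples: int = 3) -> list[Bout]:
    """Run-length encode G and keep runs of >= ``min_samples`` frames.

    Shorter runs are plausibly spurious jitter (for an independent uniform
    label over K groups a 3-repeat occurs with probability (1/K)^2) and are
    excluded from the bout list; the frame labels themselves are untouched.
    """
    if ls.n_frames == 0:
        raise ParameterError("empty label series")
    return [
        Bout(lab, s, e, ls.fps)
        for lab, s, e in _runs(ls.G)
        if e - s >= min_samples
    ]


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [b.label for b in bouts],
            "start_frame": [b.start_frame for b in bouts],
            "end_frame": [b.end_frame for b in bouts],
            "start_s": [b.start_frame / b.fps for b in bouts],
            "end_s": [b.end_frame / b.fps for b in bouts],
            "duration_ms": [b.duration_ms for b in bouts],
        }
    )


def spurious_repeat_probability(n_groups: int, n_samples: int = 3) -> float:
    """Percent probability that an independent uniform label over
    ``n_groups`` repeats across ``n_samples`` consecutive samples."""
    if n_groups < 2 or n_samples < 2:
        raise ParameterError("need n_groups >= 2 and n_samples >= 2")
    return 100.0 * (1.0 / n_groups) ** (n_samples - 1)


def overlap_above_baseline(
    reference: LabelSeries, target: LabelSeries
) -> pd.DataFrame:
    """Frame-wise enrichment of target groups within each reference group.

    Entry (r, j) is ``100 * (P(target=j | ref=r) - P(target=j)) / P(target=j)``
    — the percent by which group j is over-represented among frames the
    reference view calls r, relative to j's session-wide baseline. Negative
    entries (depletion) are reported as-is.
    """
    if reference.n_frames != target.n_frames:
        raise ParameterError(
            f"label series are not frame-aligned: "
            f"{reference.n_frames} vs {target.n_frames} frames"
        )
    ref, tgt = reference.G, target.G
    ref_groups = np.unique(ref)
    tgt_groups = np.unique(tgt)
    baseline = np.array([(tgt == j).mean() for j in tgt_groups])
    out = np.empty((len(ref_groups), len(tgt_groups)))
    for i, r in enumerate(ref_groups):
        mask = ref == r
        cond = np.array([(tgt[mask] == j).mean() for j in tgt_groups])
        out[i] = 100.0 * (cond - baseline) / baseline
    return pd.DataFrame(out, index=ref_groups, columns=tgt_groups)
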