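"""Stroke/stride kinematics from limb speed within behavior bouts.

A bout of grooming or locomotion decomposes into repeated limb movements
(strokes or strides). Peaks of the smoothed limb speed mark individual
movements, with the speed troughs on either side serving as each movement's
start and stop. Per stroke the peak and mean speed, traveled path length,
net Euclidean displacement and duration are recorded; cohort comparisons
use the two-sample two-tailed Kolmogorov-Smirnov test throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import ks_2samp

from .errors import PosesegError
from .features import SMOOTH_HALF_S, _boxcar
from .frameshift import Bout
from .pose_io import PoseSeries

__all__ = ["StrokeSet", "limb_speed", "segment_strokes", "compare_distributions"]


@dataclass
class StrokeSet:
    """Trough-delimited strokes of one bout."""

    bout: Bout
    boundaries: np.ndarray  # native-frame indices, strictly increasing
    strokes: pd.DataFrame  # peak_speed, mean_speed, path_distance,
    # displacement, duration_ms, start_frame, end_frame

    @property
    def n_strokes(self) -> int:
        return len(self.strokes)


def limb_speed(p: PoseSeries, part: str) -> np.ndarray:
    """Per-frame speed (px/frame) of one part, 60 ms boxcar smoothed.

    Element t is the displacement over the transition t -> t+1, so the
    stream has length T-1 and shares the indexing of the feature streams.
    """
    if part not in p.bodyparts:
        raise PosesegError(
            f"unknown body part {part!r}; session has {p.bodyparts}"
        )
    j = p.bodyparts.index(part)
    disp = np.linalg.norm(np.diff(p.coords[:, j, :], axis=0), axis=1)
    half = round(SMOOTH_HALF_S * p.fps)
    return _boxcar(disp[:, None], half)[:, 0]


def segment_strokes(
    p: PoseSeries,
    part: str,
    bouts: list[Bout],
    prominence_factor: float = 0.5,
) -> list[StrokeSet]:
    """Decompose each bout into trough-delimited strokes of one limb.

    Within a bout, local maxima of the limb speed are detected with a
    prominence threshold of ``prominence_factor`` times the bout's median
    speed; each stroke spans trough-to-trough around one peak. Bouts
    shorter than 3 frames are skipped with a notice, as is any bout whose
    speed has no detectable peak (e.g. a stationary limb).
    """
    speed = limb_speed(p, part)
    j = p.bodyparts.index(part)
    raw_disp = np.linalg.norm(np.diff(p.coords[:, j, :], axis=0), axis=1)
    out: list[StrokeSet] = []
    for bout in bouts:
        stop = min(bout.end_frame, len(speed))
        seg = speed[bout.start_frame : stop]
        if len(seg) < 3:
            warnings.warn(
                f"bout at frame {bout.start_frame} shorter than 3 frames; skipped",
                stacklevel=2,
            )
            continue
        prominence = max(prominence_factor * float(np.median(seg)), 1e-12)
        peaks, _ = find_peaks(seg, prominence=prominence)
        if len(peaks) == 0:
            out.append(
                StrokeSet(bout, np.empty(0, int), _empty_stroke_frame())
            )
            continue
        # troughs: speed minimum before the first / after the last / between peaks
        bounds = [int(np.argmin(seg[: peaks[0] + 1]))]
        for a, b in zip(peaks[:-1], peaks[1:]):
            bounds.append(a + int(np.argmin(seg[a : b + 1])))
        bounds.append(peaks[-1] + int(np.argmin(seg[peaks[-1] :])))
        bounds = np.asarray(bounds) + bout.start_frame

        rows = []
        for k, peak in enumerate(peaks):
            s, e = int(bounds[k]), int(bounds[k + 1])
            if e <= s:
                continue
            path = float(raw_disp[s:e].sum())
            displacement = float(
                np.linalg.norm(p.coords[e, j, :] - p.coords[s, j, :])
            )
            rows.append(
                dict(
                    start_frame=s,
                    end_frame=e,
                    peak_speed=float(speed[bout.start_frame + peak]),
                    mean_speed=float(speed[s:e].mean()),
                    path_distance=path,
                    displacement=min(displacement, path),
                    duration_ms=1000.0 * (e - s) / p.fps,
                )
            )
        out.append(StrokeSet(bout, bounds, pd.DataFrame(rows)))
    return out


def _empty_stroke_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "start_frame",
            "end_frame",
            "peak_speed",
            "mean_speed",
            "path_distance",
            "displacement",
            "duration_ms",
        ]
    )


def strokes_to_frame(stroke_sets: list[StrokeSet]) -> pd.DataFrame:
    """Flatten StrokeSets to one per-stroke table with bout provenance."""
    frames = []
    for ss in stroke_sets:
        if ss.n_strokes == 0:
            continue
        df = ss.strokes.copy()
        df["bout_label"] = ss.bout.label
        df["bout_start_frame"] = ss.bout.start_frame
        frames.append(df)
    if not frames:
        return _empty_stroke_frame()
    return pd.concat(frames, ignore_index=True)


def compare_distributions(a, b) -> dict:
    """Two-sample, two-tailed Kolmogorov-Smirnov comparison.

    Returns the KS statistic, p-value and the pooled grid with both
    empirical CDFs for cumulative-histogram plots.
    """
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if min(a.size, b.size) < 5:
        warnings.warn(
            "fewer than 5 samples on one side; KS p-value unreliable",
            stacklevel=2,
        )
    res = ks_2samp(a, b, alternative="two-sided")
    grid = np.union1d(a, b)
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return dict(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        grid=grid,
        cdf_a=cdf_a,
        cdf_b=cdf_b,
    )
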