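"""Spatiotemporal feature extraction from pose series.

For N tracked parts the feature set comprises, per frame transition:

* ``L`` — Euclidean length of every unordered inter-part vector
  (N(N-1)/2 pairwise distances, px),
* ``Θ`` — angular change of each inter-part vector between consecutive
  frames (N(N-1)/2 values, degrees; unsigned magnitude by default),
* ``D`` — per-part Euclidean displacement between consecutive frames
  (N values, px),

for N² features in total (36 for the canonical 6-part rodent model).
Features are smoothed with a centered ~60 ms boxcar and aggregated into
non-overlapping 100 ms (10 fps) bins — displacements and angular changes
are summed within a bin, distances averaged — which trades frame-level
jitter for a robust movement signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import h5py
import numpy as np
import pandas as pd

from .errors import ParameterError
from .pose_io import PoseSeries

__all__ = [
    "RawFeatures",
    "FeatureMatrix",
    "raw_features",
    "smooth_features",
    "bin_features",
    "pose_to_features",
]

#: native bin rate of the aggregated features, Hz
BIN_RATE = 10.0
#: smoothing half-window, seconds on each side of the frame of interest
SMOOTH_HALF_S = 0.03


def pair_names(bodyparts: list[str]) -> list[str]:
    return [f"{a}-{b}" for a, b in combinations(bodyparts, 2)]


@dataclass
class RawFeatures:
    """Per-frame-transition feature streams, each of length T-1."""

    distances: np.ndarray  # (T-1, M) px
    angles: np.ndarray  # (T-1, M) degrees
    displacements: np.ndarray  # (T-1, N) px
    bodyparts: list[str]
    fps: float

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]

    def feature_names(self) -> list[str]:
        pairs = pair_names(self.bodyparts)
        return (
            [f"dist:{p}" for p in pairs]
            + [f"ang:{p}" for p in pairs]
            + [f"disp:{b}" for b in self.bodyparts]
        )


@dataclass
class FeatureMatrix:
    """Binned feature matrix: one row per 100 ms window."""

    values: np.ndarray  # (B, P)
    feature_names: list[str]
    bin_rate: float
    source_fps: float
    offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values shape inconsistent with feature_names")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaNs")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.index.name = "bin"
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, bin_rate=BIN_RATE, source_fps=None, offset=0):
        df = pd.read_csv(path, index_col=0)
        return cls(
            df.to_numpy(float),
            list(df.columns),
            bin_rate=bin_rate,
            source_fps=source_fps if source_fps is not None else bin_rate,
            offset=offset,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset(
                "feature_names",
                data=np.array(self.feature_names, dtype=h5py.string_dtype()),
            )
            f.attrs["bin_rate"] = self.bin_rate
            f.attrs["source_fps"] = self.source_fps
            f.attrs["offset"] = self.offset

    @classmethod
    def from_hdf5(cls, path):
        with h5py.File(path, "r") as f:
            return cls(
                f["values"][()],
                [s.decode() if isinstance(s, bytes) else s for s in f["feature_names"][()]],
                bin_rate=float(f.attrs["bin_rate"]),
                source_fps=float(f.attrs["source_fps"]),
                offset=int(f.attrs["offset"]),
            )


def raw_features(p: PoseSeries, signed_angles: bool = False) -> RawFeatures:
    """Compute per-frame L, Θ, D streams from a (preprocessed) pose series.

    The angular change of a pair vector is the unsigned angle between its
    orientation at frame t and at t+1, ``|atan2(cross, dot)|`` in degrees
    (equivalently the arccos of the normalized dot product); pass
    ``signed_angles=True`` to keep the turning direction instead. Unsigned
    is the default because signed angular changes cancel when summed over
    the 100 ms bins: oscillatory limb movement then contributes sign
    ripples locked to the binning grid instead of a movement magnitude.
    A zero-length pair vector (coincident points) yields an angular change
    of 0 for that transition rather than NaN.
    Distances are reported from the second frame on, so all three streams
    share length T-1 and index t refers to the transition t -> t+1.
    """
    c = p.coords
    idx_a, idx_b = zip(*combinations(range(p.n_parts), 2))
    vec = c[:, list(idx_b), :] - c[:, list(idx_a), :]  # (T, M, 2)
    dist = np.linalg.norm(vec, axis=2)[1:]  # (T-1, M)

    v0, v1 = vec[:-1], vec[1:]
    dot = np.sum(v0 * v1, axis=2)
    cross = v0[:, :, 0] * v1[:, :, 1] - v0[:, :, 1] * v1[:, :, 0]
    ang = np.degrees(np.arctan2(cross, dot))  # atan2(0, 0) == 0 by convention
    if not signed_angles:
        ang = np.abs(ang)

    disp = np.linalg.norm(np.diff(c, axis=0), axis=2)  # (T-1, N)
    return RawFeatures(dist, ang, disp, list(p.bodyparts), p.fps)


def _boxcar(x: np.ndarray, half: int) -> np.ndarray:
    if half <= 0:
        return x.copy()
    return (
        pd.DataFrame(x)
        .rolling(window=2 * half + 1, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def smooth_features(raw: RawFeatures) -> RawFeatures:
    """Centered boxcar mean over ~60 ms (30 ms either side of the frame).

    Half-width is ``round(0.03 * fps)`` frames; windows are truncated at
    the stream boundaries. At frame rates below ~17 fps the half-width
    rounds to zero and the streams pass through unchanged.
    """
    half = round(SMOOTH_HALF_S * raw.fps)
    return RawFeatures(
        _boxcar(raw.distances, half),
        _boxcar(raw.angles, half),
        _boxcar(raw.displacements, half),
        list(raw.bodyparts),
        raw.fps,
    )


def bin_features(raw: RawFeatures, offset: int = 0) -> FeatureMatrix:
    """Aggregate per-frame streams into non-overlapping 100 ms windows.

    Frames are partitioned into consecutive windows of ``w = round(fps/10)``
    frames starting at native-frame ``offset``; within a window the
    displacement and angular-change streams are summed and the distance
    stream is averaged. A trailing incomplete window is dropped.
    """
    if raw.fps < BIN_RATE:
        raise ParameterError(
            f"frame rate {raw.fps} Hz below the {BIN_RATE} Hz bin rate is unsupported"
        )
    w = round(raw.fps / BIN_RATE)
    if not 0 <= offset < w:
        raise ParameterError(f"offset must lie in [0, {w}); got {offset}")
    n = (raw.n_frames - offset) // w
    if n < 1:
        raise ParameterError("stream too short for a single complete bin")

    def seg(x):
        return x[offset : offset + n * w].reshape(n, w, -1)

    dist = seg(raw.distances).mean(axis=1)
    ang = seg(raw.angles).sum(axis=1)
    disp = seg(raw.displacements).sum(axis=1)
    values = np.hstack([dist, ang, disp])
    return FeatureMatrix(
        values,
        raw.feature_names(),
        bin_rate=raw.fps / w,
        source_fps=raw.fps,
        offset=offset,
    )


def pose_to_features(
    p: PoseSeries, offset: int = 0, signed_angles: bool = False
) -> FeatureMatrix:
    """Full feature path: raw streams -> 60 ms smoothing -> 100 ms bins."""
    return bin_features(smooth_features(raw_features(p, signed_angles)), offset)
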