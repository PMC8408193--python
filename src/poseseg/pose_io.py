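"""Reading, writing and confidence-gating of 2D pose-estimation tables.

Pose-estimation software (DeepLabCut and compatible tools) emits one
(x, y, likelihood) triple per tracked body part per video frame, in a CSV
(or HDF5) table with a three-row header: scorer / bodyparts / coords.
This module ingests and emits that dialect, and implements the
session-wise low-confidence handling used by the segmentation pipeline:
the empirical likelihood distribution is bimodal (confident vs. occluded
or mistracked points), the two modes are split at the histogram elbow,
and sub-threshold frames inherit the most recent high-confidence
coordinate so that a low-confidence point contributes zero displacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import FormatError, PosesegError

__all__ = [
    "PoseSeries",
    "ConfidenceReport",
    "read_pose_table",
    "write_pose_table",
    "elbow_threshold",
    "substitute_low_confidence",
]

#: header level names of the pose-table dialect, in file order
HEADER_LEVELS = ("scorer", "bodyparts", "coords")


@dataclass
class PoseSeries:
    """Per-frame 2D coordinates and likelihoods for N body parts.

    Attributes
    ----------
    bodyparts : list of str
        Part names in file order.
    coords : ndarray, shape (T, N, 2)
        Pixel coordinates (x, y) per frame and part.
    likelihood : ndarray, shape (T, N)
        Tracking confidence in [0, 1].
    fps : float
        Camera frame rate in Hz.
    session_id : str
        Free-text session identifier.
    """

    bodyparts: list[str]
    coords: np.ndarray
    likelihood: np.ndarray
    fps: float
    session_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        t, n = self.likelihood.shape
        if self.coords.shape != (t, n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"likelihood shape {self.likelihood.shape}"
            )
        if t < 2:
            raise ValueError("a pose series needs at least 2 frames")
        if n < 2 or len(self.bodyparts) != n:
            raise ValueError("need >= 2 body parts matching the coords array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.nanmin(self.likelihood) < 0 or np.nanmax(self.likelihood) > 1:
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_parts(self) -> int:
        return self.coords.shape[1]


@dataclass
class ConfidenceReport:
    """Per-part elbow thresholds and replacement fractions."""

    bodyparts: list[str]
    threshold_per_part: np.ndarray
    fraction_replaced_per_part: np.ndarray

    def __post_init__(self) -> None:
        self.threshold_per_part = np.asarray(self.threshold_per_part, float)
        self.fraction_replaced_per_part = np.asarray(
            self.fraction_replaced_per_part, float
        )
        for arr in (self.threshold_per_part, self.fraction_replaced_per_part):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("report values must lie in [0, 1]")


def _to_frame(p: PoseSeries, scorer: str) -> pd.DataFrame:
    cols = pd.MultiIndex.from_tuples(
        [
            (scorer, part, coord)
            for part in p.bodyparts
            for coord in ("x", "y", "likelihood")
        ],
        names=list(HEADER_LEVELS),
    )
    data = np.empty((p.n_frames, 3 * p.n_parts))
    data[:, 0::3] = p.coords[:, :, 0]
    data[:, 1::3] = p.coords[:, :, 1]
    data[:, 2::3] = p.likelihood
    return pd.DataFrame(data, columns=cols)


def write_pose_table(p: PoseSeries, path, scorer: str = "poseseg") -> None:
    """Write ``p`` in the three-header-row CSV (or HDF5) pose dialect."""
    df = _to_frame(p, scorer)
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        df.to_hdf(path, key="poses", mode="w")
    else:
        df.to_csv(path)


def read_pose_table(path, fps: float, session_id: str | None = None) -> PoseSeries:
    """Read a pose table (CSV or HDF5) into a :class:`PoseSeries`.

    Parameters
    ----------
    path : path-like
        Table with a 3-row header (scorer / bodyparts / coords) and
        x, y, likelihood columns for every part.
    fps : float
        Frame rate of the source video; the table itself does not carry it.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        df = pd.read_hdf(path)
    else:
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise FormatError(f"cannot parse pose table {path!r}: {exc}") from exc
    if df.columns.nlevels != 3:
        raise FormatError(
            f"pose table {path!r} must have 3 header rows "
            f"({'/'.join(HEADER_LEVELS)}); found {df.columns.nlevels}"
        )
    names = [str(n).lower() for n in df.columns.names]
    for expected in HEADER_LEVELS:
        if expected not in names:
            raise FormatError(
                f"pose table {path!r} is missing the {expected!r} header level"
            )
    # part order as first encountered in the header
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    scorer = df.columns.get_level_values(0)[0]
    for part in bodyparts:
        for coord in ("x", "y", "likelihood"):
            if (scorer, part, coord) not in df.columns:
                raise FormatError(
                    f"pose table {path!r} is missing the {coord!r} column "
                    f"for body part {part!r}"
                )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any() and not df.isna().to_numpy().any():
        row = int(np.where(numeric.isna().any(axis=1))[0][0])
        raise FormatError(f"non-numeric cell in pose table {path!r} at row {row}")
    t = len(numeric)
    n = len(bodyparts)
    coords = np.empty((t, n, 2))
    lik = np.empty((t, n))
    for j, part in enumerate(bodyparts):
        coords[:, j, 0] = numeric[(scorer, part, "x")]
        coords[:, j, 1] = numeric[(scorer, part, "y")]
        lik[:, j] = numeric[(scorer, part, "likelihood")]
    if session_id is None:
        session_id = path
    return PoseSeries(bodyparts, coords, lik, fps=fps, session_id=session_id)


def elbow_threshold(
    likelihoods, n_bins: int = 50, floor: float = 0.1
) -> float:
    """Split a bimodal likelihood sample at the histogram elbow.

    A fixed-width histogram on [0, 1] is scanned from the low end; the
    threshold is the left edge of the first bin at which the adjacent-bin
    count difference turns positive after the descent out of the low mode
    (i.e. where the high-confidence mode starts rising). Counts are
    lightly smoothed (3-bin moving average) and the turn must happen in a
    genuine inter-mode valley — below half the running count maximum — so
    that sampling noise inside a single mode does not produce a spurious
    elbow. If the counts never turn back up, ``floor`` is returned; this
    covers unimodal sessions, uniformly confident or uniformly poor.
    """
    x = np.asarray(likelihoods, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty likelihood sample")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("likelihoods must lie in [0, 1]")
    if x.size < 100:
        warnings.warn(
            "elbow_threshold on < 100 samples is unreliable", stacklevel=2
        )
    counts, edges = np.histogram(x, bins=n_bins, range=(0.0, 1.0))
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    diffs = np.diff(smooth)
    descending = False
    peak = smooth[0]
    for i, d in enumerate(diffs):
        peak = max(peak, smooth[i])
        if d < 0:
            descending = True
        elif descending and d > 0 and smooth[i] < 0.5 * peak:
            return float(edges[i + 1])
    return float(floor)


def substitute_low_confidence(
    p: PoseSeries,
    per_part: bool = True,
    floor: float = 0.1,
    n_bins: int = 50,
) -> tuple[PoseSeries, ConfidenceReport]:
    """Replace low-confidence points with the last high-confidence position.

    For each body part the elbow threshold is computed within the session
    (per part by default; ``per_part=False`` pools all parts). Frames whose
    likelihood falls below the threshold take the most recent coordinate at
    or above it, so their inter-frame displacement downstream is exactly
    zero; leading low-confidence frames are back-filled from the first
    high-confidence frame. Raw likelihoods are preserved, which makes the
    operation idempotent.
    """
    if per_part:
        thresholds = np.array(
            [
                elbow_threshold(p.likelihood[:, j], n_bins=n_bins, floor=floor)
                for j in range(p.n_parts)
            ]
        )
    else:
        thr = elbow_threshold(p.likelihood, n_bins=n_bins, floor=floor)
        thresholds = np.full(p.n_parts, thr)

    coords = p.coords.copy()
    fractions = np.zeros(p.n_parts)
    t = p.n_frames
    for j, part in enumerate(p.bodyparts):
        good = p.likelihood[:, j] >= thresholds[j]
        if not good.any():
            raise PosesegError(
                f"body part {part!r} has no frame at or above its confidence "
                f"threshold {thresholds[j]:.3f}; session unusable for this part"
            )
        fractions[j] = 1.0 - good.mean()
        # forward-fill index of the last good frame; leading frames backfilled
        idx = np.where(good, np.arange(t), -1)
        idx = np.maximum.accumulate(idx)
        first_good = int(np.argmax(good))
        idx[idx < 0] = first_good
        coords[:, j, :] = p.coords[idx, j, :]

    cleaned = replace(p, coords=coords)
    report = ConfidenceReport(list(p.bodyparts), thresholds, fractions)
    return cleaned, report
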