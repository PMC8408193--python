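"""Segmentation-quality validation: motion energy and neural alignment.

Two independent lines of evidence that discovered groups are real:

* **Motion energy (ME).** The ME of a bout is the mean absolute difference
  of consecutive (pose-registered) video frames — a picture of where
  movement happened. If a group is a real behavior, the ME images of its
  bouts resemble each other more than bouts from other groups, so the
  pairwise image MSE is smaller in-group than out-group. Each MSE row is
  normalized to its in-group mean, in- vs out-group values are compared
  with a KS test, and a shuffled-group control verifies the effect
  vanishes without structure.

* **Neural alignment.** Spike trains aligned to behavior onsets are binned
  at 10 ms over -1..2 s, trial-averaged, z-scored per neuron over that
  window and smoothed with a boxcar of semi-width 3 bins. Sharper (higher
  frame rate) onset estimates concentrate genuinely locked activity, so
  the magnitude of the z-scored response around onset grows with temporal
  resolution; the per-bin difference of magnitudes quantifies that gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, ttest_1samp

from .errors import ParameterError, PosesegError
from .frameshift import Bout
from .pose_io import PoseSeries

__all__ = [
    "MEImage",
    "PETH",
    "motion_energy_image",
    "eligible_bouts",
    "me_mse_matrix",
    "align_spikes",
    "rank_order",
    "signal_magnitude_difference",
]

#: PETH bin width (s) and window (s relative to onset)
PETH_BIN = 0.010
PETH_WINDOW = (-1.0, 2.0)
BOXCAR_SEMIWIDTH = 3


# ---------------------------------------------------------------------------
# motion energy


@dataclass
class MEImage:
    """Bout-averaged motion-energy image (pose-registered)."""

    pixels: np.ndarray  # (H, W), >= 0
    bout: Bout
    n_diff_frames: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, float)
        if self.n_diff_frames < 1:
            raise ValueError("need at least one consecutive-frame difference")
        if self.pixels.min() < 0:
            raise ValueError("motion energy is nonnegative by construction")


def _translate(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill (no wraparound)."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys0, ys1 = max(0, -dy), min(h, h - dy)
    xs0, xs1 = max(0, -dx), min(w, w - dx)
    if ys0 >= ys1 or xs0 >= xs1:
        return out
    out[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx] = img[ys0:ys1, xs0:xs1]
    return out


def motion_energy_image(
    frames: np.ndarray,
    bout: Bout,
    pose: PoseSeries,
    cap_ms: float = 600.0,
) -> MEImage:
    """Mean |frame_{t+1} - frame_t| over a bout, registered to starting pose.

    The animal moves through the arena, so frames are translated such that
    the pose centroid at bout start sits at the image center before
    differencing; the average runs over at most ``cap_ms`` of the bout.
    """
    t_video = frames.shape[0]
    if bout.start_frame < 0 or bout.start_frame >= t_video:
        raise PosesegError(
            f"bout starting at frame {bout.start_frame} lies outside the "
            f"{t_video}-frame video"
        )
    n_max = int(round(cap_ms / 1000.0 * pose.fps))
    stop = min(bout.end_frame, bout.start_frame + n_max, t_video)
    if stop - bout.start_frame < 2:
        raise PosesegError("bout too short for a frame difference")
    h, w = frames.shape[1:]
    cx, cy = pose.coords[bout.start_frame].mean(axis=0)
    dy, dx = int(round(h / 2 - cy)), int(round(w / 2 - cx))
    seg = np.stack(
        [_translate(frames[t], dy, dx) for t in range(bout.start_frame, stop)]
    )
    me = np.abs(np.diff(seg, axis=0)).mean(axis=0)
    return MEImage(me, bout, n_diff_frames=len(seg) - 1)


def eligible_bouts(
    bouts: list[Bout], min_ms: float = 300.0, max_ms: float = 600.0
) -> list[Bout]:
    """Bouts inside the duration window used for ME comparisons."""
    return [b for b in bouts if min_ms <= b.duration_ms <= max_ms]


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.mean(d * d))


@dataclass
class MEComparison:
    """All-pairs ME-image MSE analysis with shuffled-group control."""

    mse: np.ndarray  # (n, n) raw, symmetric, zero diagonal
    normalized: np.ndarray  # (n, n) each row / its in-group mean
    group_of_row: np.ndarray  # (n,) group id per image
    in_group: np.ndarray  # off-diagonal same-group normalized values
    out_group: np.ndarray  # cross-group normalized values
    ks_statistic: float
    ks_pvalue: float
    shuffled_in: np.ndarray = field(default_factory=lambda: np.empty(0))
    shuffled_out: np.ndarray = field(default_factory=lambda: np.empty(0))
    shuffled_ks_statistic: float = np.nan
    shuffled_ks_pvalue: float = np.nan


def _normalize_and_split(mse: np.ndarray, groups: np.ndarray):
    n = mse.shape[0]
    normalized = np.zeros_like(mse)
    for i in range(n):
        same = (groups == groups[i]) & (np.arange(n) != i)
        row_mean = mse[i, same].mean()
        normalized[i] = mse[i] / row_mean if row_mean > 0 else 0.0
    same_mat = groups[:, None] == groups[None, :]
    off_diag = ~np.eye(n, dtype=bool)
    in_vals = normalized[same_mat & off_diag]
    out_vals = normalized[~same_mat]
    return normalized, in_vals, out_vals


def me_mse_matrix(
    images_by_group: dict[int, list[MEImage]],
    max_per_group: int = 20,
    seed: int | None = None,
) -> MEComparison:
    """Pairwise ME-image MSE, row-normalized to the in-group mean.

    Up to ``max_per_group`` bouts per group enter (sampled with the seeded
    RNG when more are available); groups with fewer than two images are
    dropped with a notice. In-group vs out-group normalized values are
    compared with a two-sided KS test, and the same images shuffled into
    random groups of identical sizes provide the structureless control.
    """
    rng = np.random.default_rng(seed)
    images: list[MEImage] = []
    groups: list[int] = []
    for gid in sorted(images_by_group):
        imgs = images_by_group[gid]
        if len(imgs) < 2:
            warnings.warn(
                f"group {gid} has {len(imgs)} eligible bout(s); dropped",
                stacklevel=2,
            )
            continue
        if len(imgs) > max_per_group:
            idx = rng.choice(len(imgs), size=max_per_group, replace=False)
            imgs = [imgs[i] for i in sorted(idx)]
        images.extend(imgs)
        groups.extend([gid] * len(imgs))
    if len(set(groups)) < 2:
        raise ParameterError("need >= 2 groups with >= 2 eligible bouts each")
    groups = np.asarray(groups)
    n = len(images)
    mse = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mse[i, j] = mse[j, i] = _mse(images[i].pixels, images[j].pixels)

    normalized, in_vals, out_vals = _normalize_and_split(mse, groups)
    if in_vals.std() == 0 and out_vals.std() == 0 and in_vals.mean() == out_vals.mean():
        ks_stat, ks_p = 0.0, 1.0
    else:
        res = ks_2samp(in_vals, out_vals)
        ks_stat, ks_p = float(res.statistic), float(res.pvalue)

    shuffled = rng.permutation(groups)
    _, sh_in, sh_out = _normalize_and_split(mse, shuffled)
    if sh_in.std() == 0 and sh_out.std() == 0 and sh_in.mean() == sh_out.mean():
        sh_stat, sh_p = 0.0, 1.0
    else:
        res = ks_2samp(sh_in, sh_out)
        sh_stat, sh_p = float(res.statistic), float(res.pvalue)

    return MEComparison(
        mse,
        normalized,
        groups,
        in_vals,
        out_vals,
        ks_stat,
        ks_p,
        sh_in,
        sh_out,
        sh_stat,
        sh_p,
    )


# ---------------------------------------------------------------------------
# neural alignment


@dataclass
class PETH:
    """Peri-event time histograms: neurons x 10 ms bins over -1..2 s."""

    rate: np.ndarray  # (n_neurons, n_bins) trial-averaged rate, Hz
    z: np.ndarray  # z-scored per neuron over the window (pre-smoothing)
    z_smooth: np.ndarray  # boxcar (semi-width 3 bins) smoothed z
    edges: np.ndarray  # (n_bins + 1,) s relative to onset
    n_bouts: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self, which: str = "z_smooth") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, columns=np.round(self.centers, 4))


def align_spikes(
    spike_trains,
    onsets,
    bin_s: float = PETH_BIN,
    window: tuple[float, float] = PETH_WINDOW,
    boxcar_semiwidth: int = BOXCAR_SEMIWIDTH,
) -> PETH:
    """Trial-averaged, z-scored, boxcar-smoothed PETHs.

    ``spike_trains`` is a sequence of per-neuron spike-time arrays (s);
    an empty train yields a row of zeros with a notice. Z-scoring uses the
    mean and SD of each neuron's trial-averaged rate across the whole
    window, before smoothing.
    """
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ParameterError("need at least one onset")
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    n_bins = len(edges) - 1
    rate = np.zeros((len(spike_trains), n_bins))
    for i, train in enumerate(spike_trains):
        train = np.asarray(train, float)
        if train.size == 0:
            warnings.warn(f"neuron {i} has no spikes; zero row", stacklevel=2)
            continue
        counts = np.zeros(n_bins)
        for on in onsets:
            counts += np.histogram(train - on, bins=edges)[0]
        rate[i] = counts / (len(onsets) * bin_s)
    mu = rate.mean(axis=1, keepdims=True)
    sd = rate.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (rate - mu) / sd
    z_smooth = (
        pd.DataFrame(z.T)
        .rolling(2 * boxcar_semiwidth + 1, center=True, min_periods=1)
        .mean()
        .to_numpy()
        .T
    )
    return PETH(rate, z, z_smooth, edges, n_bouts=len(onsets))


def rank_order(peth: PETH, window: tuple[float, float] = (-0.2, 0.0)) -> np.ndarray:
    """Neuron ordering by mean activity in a pre-onset window (descending).

    Display convention: rows of a high-resolution PETH are ordered by the
    average low-resolution activity during the 200 ms prior to alignment,
    computed here from whichever PETH is passed as reference.
    """
    c = peth.centers
    mask = (c >= window[0]) & (c < window[1])
    return np.argsort(-peth.z_smooth[:, mask].mean(axis=1), kind="stable")


@dataclass
class SignalDifference:
    """Per-bin difference of response magnitudes, high minus low resolution."""

    per_neuron: np.ndarray  # (n_neurons, n_bins) |z_high| - |z_low|
    summed: np.ndarray  # (n_bins,) summed across neurons
    mean: np.ndarray  # (n_bins,) mean across neurons
    sem: np.ndarray  # (n_bins,)
    pvalues: np.ndarray  # (n_bins,) two-tailed t-test across neurons
    significant: np.ndarray  # (n_bins,) bool at alpha
    alpha: float
    centers: np.ndarray


def signal_magnitude_difference(
    high: PETH, low: PETH, alpha: float = 0.01
) -> SignalDifference:
    """|z_high| - |z_low| per neuron and bin, summed/averaged across neurons.

    Positive values mean the higher-resolution alignment carries the
    stronger signal. Tuned neurons contribute systematically; untuned
    neurons contribute noise with zero net effect. Per-bin two-tailed
    one-sample t-tests across neurons flag bins where the population
    difference departs from zero.
    """
    if high.z_smooth.shape != low.z_smooth.shape or not np.allclose(
        high.edges, low.edges
    ):
        raise ParameterError("PETHs must share neurons and bin grid")
    d = np.abs(high.z_smooth) - np.abs(low.z_smooth)
    n_neurons, n_bins = d.shape
    mean = d.mean(axis=0)
    if n_neurons > 1:
        sem_v = d.std(axis=0, ddof=1) / np.sqrt(n_neurons)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = ttest_1samp(d, 0.0, axis=0)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    else:
        warnings.warn("single neuron: per-bin t-test undefined", stacklevel=2)
        sem_v = np.zeros(n_bins)
        pvals = np.ones(n_bins)
    return SignalDifference(
        per_neuron=d,
        summed=d.sum(axis=0),
        mean=mean,
        sem=sem_v,
        pvalues=pvals,
        significant=pvals < alpha,
        alpha=alpha,
        centers=high.centers,
    )
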