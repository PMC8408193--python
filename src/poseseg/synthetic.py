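"""Ground-truth-labeled synthetic pose sessions, raster video and spike trains.

The generator emulates the statistical structure the segmentation pipeline
assumes: an animal switching among a small repertoire of stereotyped movement
motifs (Markov switching with geometric dwell times), each motif expressed as
per-part oscillation patterns on a rigid skeleton plus whole-body drift;
tracking noise as i.i.d. Gaussian coordinate jitter; and tracking confidence
as a bimodal likelihood distribution where dropout frames draw from the low
mode. A companion inhomogeneous-Poisson neuron produces spike trains whose
rate steps up before each motif onset, for the neural-alignment analyses.

Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pose_io import PoseSeries

__all__ = [
    "MotifSpec",
    "SyntheticSession",
    "SimulatedNeuron",
    "default_motifs",
    "simulate_pose",
    "simulate_poisson_neuron",
    "render_blob_video",
    "bin_labels",
    "save_spike_times",
    "load_spike_times",
]

#: canonical 6-part bottom-up rodent skeleton, offsets in px from body center
SKELETON = {
    "snout": (0.0, -30.0),
    "forepaw_l": (-12.0, -10.0),
    "forepaw_r": (12.0, -10.0),
    "hindpaw_l": (-14.0, 15.0),
    "hindpaw_r": (14.0, 15.0),
    "tailbase": (0.0, 30.0),
}


@dataclass
class MotifSpec:
    """One stereotyped movement motif.

    Per part: a linear (back-and-forth) oscillation with amplitude (px),
    frequency (Hz), phase (rad) and stroke direction (rad), around a mean
    posture offset (px from body center); per motif: a drift velocity
    (px/s) of the body center. Limb strokes are modelled as linear rather
    than circular movements, matching stepping and grooming kinematics.
    """

    motif_id: int
    amplitudes: np.ndarray  # (N,)
    frequencies: np.ndarray  # (N,)
    phases: np.ndarray  # (N,)
    offsets: np.ndarray  # (N, 2)
    drift: np.ndarray = field(default_factory=lambda: np.zeros(2))  # (2,) px/s
    directions: np.ndarray | None = None  # (N,) stroke direction, rad
    name: str = ""

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, float)
        self.frequencies = np.asarray(self.frequencies, float)
        self.phases = np.asarray(self.phases, float)
        self.offsets = np.asarray(self.offsets, float)
        self.drift = np.asarray(self.drift, float)
        if self.directions is None:
            self.directions = np.zeros_like(self.amplitudes)
        self.directions = np.asarray(self.directions, float)
        if (self.amplitudes < 0).any() or (self.frequencies < 0).any():
            raise ValueError("amplitudes and frequencies must be >= 0")


@dataclass
class SyntheticSession:
    """A simulated pose session with frame-level motif ground truth."""

    pose: PoseSeries
    true_labels: np.ndarray  # (T,) motif ids
    transition_matrix: np.ndarray  # (K, K) row-stochastic switch matrix
    jitter_sd: float
    dropout_rate: float
    mean_dwell: float
    specs: list[MotifSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, float)
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        self.transition_matrix = tm


def _base_offsets(bodyparts) -> np.ndarray:
    return np.array([SKELETON[b] for b in bodyparts])


def default_motifs(bodyparts=None) -> list[MotifSpec]:
    """The four canonical motifs: idle, locomote, groom, rear.

    Motifs differ in the statistics the pipeline's features measure —
    oscillation frequency and amplitude of the limbs (displacement and
    angular change), posture geometry (inter-part distances), and body
    drift — so they are separable without hand-coded labels.
    """
    if bodyparts is None:
        bodyparts = list(SKELETON)
    n = len(bodyparts)
    base = _base_offsets(bodyparts)
    fore = [i for i, b in enumerate(bodyparts) if b.startswith("forepaw")]
    hind = [i for i, b in enumerate(bodyparts) if b.startswith("hindpaw")]

    # Movement rhythms (step, stroke and tremor rates) are multiples of
    # 2.5 Hz, so every 100 ms feature bin covers an integer number of
    # oscillation half-periods: binned statistics are then stationary
    # within a motif — the property real behavior has at this timescale —
    # rather than depending on oscillator phase at the bin boundary.

    # idle: micro-tremor on a resting posture
    idle = MotifSpec(
        0,
        np.full(n, 0.5),
        np.full(n, 10.0),
        np.linspace(0, np.pi, n),
        base.copy(),
        np.zeros(2),
        directions=np.linspace(0.0, np.pi, n),
        name="idle",
    )

    # locomote: alternating-gait limb oscillation plus steady drift;
    amp = np.full(n, 2.0)
    amp[fore] = 7.0
    amp[hind] = 7.0
    freq = np.full(n, 10.0)  # fast-trot stride rate
    phase = np.zeros(n)
    if len(fore) == 2:
        phase[fore[1]] = np.pi
    if len(hind) == 2:
        phase[hind[0]] = np.pi
    # strokes along the axis of travel
    locomote = MotifSpec(
        1, amp, freq, phase, base.copy(), np.array([40.0, 0.0]),
        directions=np.zeros(n), name="locomote",
    )

    # groom: fast large-amplitude forepaw strokes near the snout
    amp = np.full(n, 0.8)
    amp[fore] = 9.0
    amp[0] = 3.0
    off = base.copy()
    for i in fore:
        off[i] = (np.sign(base[i, 0]) * 6.0, -18.0)
    freq = np.full(n, 7.5)
    phase = np.zeros(n)
    if len(fore) == 2:
        phase[fore[1]] = np.pi
    # strokes run along the body axis, toward and away from the snout
    groom = MotifSpec(
        2, amp, freq, phase, off, np.zeros(2),
        directions=np.full(n, np.pi / 2), name="groom",
    )

    # rear: compressed (foreshortened) skeleton with moderate body sway
    off = base.copy()
    off[:, 1] *= 0.45
    phase = np.where(np.arange(n) % 2 == 0, 0.0, np.pi)
    rear = MotifSpec(
        3, np.full(n, 3.0), np.full(n, 5.0), phase, off, np.zeros(2),
        directions=np.zeros(n), name="rear",
    )
    return [idle, locomote, groom, rear]


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect a free path into [lo, hi] (specular arena walls)."""
    period = 2.0 * (hi - lo)
    y = np.mod(x - lo, period)
    return lo + np.minimum(y, period - y)


def simulate_pose(
    specs: list[MotifSpec] | None = None,
    transition_matrix: np.ndarray | None = None,
    duration: float = 600.0,
    fps: float = 60.0,
    jitter_sd: float = 1.0,
    dropout_rate: float = 0.02,
    mean_dwell: float = 0.45,
    seed: int | None = None,
    arena: tuple[float, float] = (400.0, 400.0),
    scale: float = 1.0,
    bout_phase_jitter: bool = True,
    amp_cv: float = 0.15,
    amp_tau: float = 0.3,
    move_noise_sd: float = 0.5,
    initial_state: int | None = None,
    bodyparts=None,
    session_id: str = "synthetic",
) -> SyntheticSession:
    """Simulate a Markov-switching multi-body-part pose session.

    At every frame the motif switches with probability ``1/(mean_dwell*fps)``
    (geometric dwell with the stated mean); the successor is drawn from
    ``transition_matrix`` with the diagonal removed and renormalized, so the
    matrix controls which motif follows which while ``mean_dwell`` controls
    dwell. Part positions are body center + posture offset + sinusoidal
    oscillation, all scaled by ``scale`` (an animal-size factor), plus
    i.i.d. Gaussian jitter. Dropout frames draw likelihood from the low
    Beta(1, 20) mode, all others from the high Beta(20, 1) mode.

    Execution variability emulates the fact that two strokes of the same
    behavior are never identical: each bout draws a common phase offset
    (``bout_phase_jitter``); movement amplitude is modulated by a smooth
    lognormal AR(1) process with coefficient of variation ``amp_cv`` and
    correlation time ``amp_tau`` seconds (stroke-to-stroke vigor
    variation); and every part carries white movement noise of
    ``move_noise_sd`` px — the animal itself wiggles, independently of the
    tracking noise ``jitter_sd`` models. Zero all of these for strictly
    stereotyped (periodic) motif executions.
    """
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = default_motifs(bodyparts)
    k = len(specs)
    if k < 2:
        raise ValueError("need at least 2 motifs")
    if transition_matrix is None:
        transition_matrix = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(transition_matrix, 0.0)
    tm = np.asarray(transition_matrix, float)
    if tm.shape != (k, k):
        raise ValueError(
            f"transition matrix shape {tm.shape} does not match {k} motifs"
        )
    switch = tm.copy()
    np.fill_diagonal(switch, 0.0)
    rowsum = switch.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("every motif needs at least one allowed successor")
    switch /= rowsum
    if mean_dwell < 1.0 / fps:
        raise ValueError("mean_dwell must be at least one frame")

    t_total = int(round(duration * fps))
    p_switch = 1.0 / (mean_dwell * fps)

    # motif sequence: geometric dwells + Markov successors; a per-bout
    # phase offset decouples executions from the global clock
    states = np.empty(t_total, dtype=int)
    bout_phase = np.zeros(t_total)
    s = int(rng.integers(k)) if initial_state is None else int(initial_state)
    if not 0 <= s < k:
        raise ValueError(f"initial_state must lie in [0, {k})")
    t = 0
    while t < t_total:
        dwell = int(rng.geometric(p_switch))
        states[t : t + dwell] = s
        if bout_phase_jitter:
            bout_phase[t : t + dwell] = rng.uniform(0.0, 2 * np.pi)
        t += dwell
        s = int(rng.choice(k, p=switch[s]))

    # movement vigor: stationary lognormal AR(1), mean 1, CV amp_cv
    amp_factor = np.ones(t_total)
    if amp_cv > 0:
        sigma = np.sqrt(np.log1p(amp_cv**2))
        rho = np.exp(-1.0 / (amp_tau * fps))
        x = np.empty(t_total)
        x[0] = rng.normal(0.0, sigma)
        eps = rng.normal(0.0, sigma * np.sqrt(1 - rho**2), t_total - 1)
        for i in range(1, t_total):
            x[i] = rho * x[i - 1] + eps[i - 1]
        amp_factor = np.exp(x - 0.5 * sigma**2)

    if bodyparts is None:
        bodyparts = list(SKELETON)
    n = len(bodyparts)
    amps = np.stack([sp.amplitudes for sp in specs])  # (K, N)
    freqs = np.stack([sp.frequencies for sp in specs])
    phases = np.stack([sp.phases for sp in specs])
    offsets = np.stack([sp.offsets for sp in specs])  # (K, N, 2)
    drifts = np.stack([sp.drift for sp in specs])  # (K, 2)
    if (freqs >= fps / 2).any():
        raise ValueError("motif frequencies must stay below fps/2")

    # body-center path: per-frame drift integrated, reflected at the walls
    vel = drifts[states] / fps  # (T, 2)
    free = np.cumsum(vel, axis=0)
    margin = 60.0 * scale
    center = np.empty((t_total, 2))
    center[:, 0] = _fold(arena[0] / 2 + free[:, 0], margin, arena[0] - margin)
    center[:, 1] = _fold(arena[1] / 2 + free[:, 1], margin, arena[1] - margin)

    directions = np.stack([sp.directions for sp in specs])  # (K, N)

    tt = (np.arange(t_total) / fps)[:, None]  # (T, 1)
    a = amps[states] * amp_factor[:, None]
    f = freqs[states]
    ph = phases[states] + bout_phase[:, None]
    osc = a * np.sin(2 * np.pi * f * tt + ph)  # linear stroke
    psi = directions[states]
    osc_x = osc * np.cos(psi)
    osc_y = osc * np.sin(psi)
    coords = np.empty((t_total, n, 2))
    coords[:, :, 0] = center[:, 0:1] + scale * (offsets[states][:, :, 0] + osc_x)
    coords[:, :, 1] = center[:, 1:2] + scale * (offsets[states][:, :, 1] + osc_y)
    if move_noise_sd > 0:
        coords += scale * rng.normal(0.0, move_noise_sd, coords.shape)
    if jitter_sd > 0:
        coords += rng.normal(0.0, jitter_sd, coords.shape)

    dropped = rng.random((t_total, n)) < dropout_rate
    lik = rng.beta(20.0, 1.0, (t_total, n))
    if dropped.any():
        lik[dropped] = rng.beta(1.0, 20.0, int(dropped.sum()))

    pose = PoseSeries(list(bodyparts), coords, lik, fps=fps, session_id=session_id)
    return SyntheticSession(
        pose, states, tm, jitter_sd, dropout_rate, mean_dwell, list(specs)
    )


def bin_labels(
    true_labels: np.ndarray, fps: float, offset: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Majority motif id and purity per 100 ms feature bin.

    Mirrors the binning grid of :func:`poseseg.features.bin_features` (which
    operates on T-1 frame transitions), so the returned arrays align with
    FeatureMatrix rows. Purity is the fraction of frames in the bin that
    carry the majority label; bins straddling a motif switch have purity
    below 1 and an ambiguous ground truth.
    """
    labels = np.asarray(true_labels)
    w = round(fps / 10.0)
    b = (len(labels) - 1 - offset) // w
    maj = np.empty(b, dtype=int)
    purity = np.empty(b)
    for i in range(b):
        seg = labels[offset + i * w : offset + (i + 1) * w + 1]
        vals, counts = np.unique(seg, return_counts=True)
        j = int(np.argmax(counts))
        maj[i] = vals[j]
        purity[i] = counts[j] / len(seg)
    return maj, purity


@dataclass
class SimulatedNeuron:
    """Spike train of an inhomogeneous-Poisson neuron locked to motif onsets."""

    spike_times: np.ndarray  # s, sorted
    true_onsets: np.ndarray  # s
    reported_onsets: np.ndarray  # s (= true onsets + alignment jitter)
    baseline: float
    elevated: float
    mod_duration: float  # s
    mod_lead: float  # s
    session_duration: float  # s


def simulate_poisson_neuron(
    baseline: float = 5.0,
    elevated: float = 15.0,
    mod_duration_ms: float = 100.0,
    mod_lead_ms: float = 130.0,
    n_trials: int = 500,
    jitter_fps: float | None = None,
    trial_interval: float = 3.0,
    seed: int | None = None,
) -> SimulatedNeuron:
    """Poisson neuron whose rate steps from baseline to ``elevated``
    for ``mod_duration_ms`` starting ``mod_lead_ms`` before each onset.

    ``jitter_fps`` emulates the alignment error of frame-quantized behavior
    onsets: reported onsets are perturbed by uniform jitter of +/- half the
    inter-frame interval at that rate (None = perfect alignment).
    """
    if baseline < 0 or elevated < baseline:
        raise ValueError("need elevated >= baseline >= 0")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    onsets = 2.0 + np.arange(n_trials) * trial_interval
    end = float(onsets[-1] + 2.5)
    dur = mod_duration_ms / 1000.0
    lead = mod_lead_ms / 1000.0

    # baseline process over the whole session ...
    n_base = rng.poisson(baseline * end)
    spikes = [rng.uniform(0.0, end, n_base)]
    # ... plus the rate increment inside each modulation window
    extra_rate = elevated - baseline
    if extra_rate > 0:
        for on in onsets:
            m = rng.poisson(extra_rate * dur)
            spikes.append(on - lead + rng.uniform(0.0, dur, m))
    spike_times = np.sort(np.concatenate(spikes))

    if jitter_fps is not None:
        reported = onsets + rng.uniform(-0.5, 0.5, n_trials) / jitter_fps
    else:
        reported = onsets.copy()
    return SimulatedNeuron(
        spike_times, onsets, reported, baseline, elevated, dur, lead, end
    )


def render_blob_video(
    p: PoseSeries,
    shape: tuple[int, int] = (96, 96),
    sigma: float = 2.5,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Rasterize a pose series as grayscale frames of Gaussian blobs.

    Each body part becomes an isotropic Gaussian of the given sigma at its
    pixel position; intensities of overlapping parts add. This synthetic
    raster stands in for real video in the motion-energy analyses — it is
    labelled synthetic and reproduces the geometry of movement, not the
    appearance of an animal.
    """
    h, w = shape
    frames = np.zeros((p.n_frames, h, w), dtype=np.float32)
    r = int(np.ceil(3 * sigma))
    span = np.arange(-r, r + 1)
    kernel_1d = np.exp(-(span**2) / (2 * sigma**2))
    for t in range(p.n_frames):
        for j in range(p.n_parts):
            cx, cy = p.coords[t, j]
            ix, iy = int(round(cx)), int(round(cy))
            x0, x1 = max(0, ix - r), min(w, ix + r + 1)
            y0, y1 = max(0, iy - r), min(h, iy + r + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            kx = kernel_1d[x0 - (ix - r) : x1 - (ix - r)]
            ky = kernel_1d[y0 - (iy - r) : y1 - (iy - r)]
            frames[t, y0:y1, x0:x1] += amplitude * np.outer(ky, kx)
    return frames


def save_spike_times(path, spike_times) -> None:
    """Write spike times (s) as a plain-text list, one per line."""
    np.savetxt(path, np.asarray(spike_times, float), fmt="%.6f")


def load_spike_times(path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path, dtype=float))
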