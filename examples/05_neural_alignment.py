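"""Why onset resolution matters for neural alignment.

A Poisson neuron fires at 5 Hz and steps to 15 Hz for 100 ms beginning
130 ms before each behavior onset. Aligning its spikes at the true onsets
recovers the step; quantizing the onsets to a 10 fps behavioral
segmentation (+/- 50 ms jitter) flattens and smears it, while 60 fps
jitter (+/- 8 ms) barely hurts. The per-bin magnitude difference between
the two alignments quantifies the information gained by frameshifting.
"""

import numpy as np

import poseseg as ps
from poseseg.validation import PETH


def peth_at(jitter_fps, seed):
    sim = ps.simulate_poisson_neuron(
        baseline=5.0,
        elevated=15.0,
        mod_duration_ms=100.0,
        mod_lead_ms=130.0,
        n_trials=500,
        jitter_fps=jitter_fps,
        seed=seed,
    )
    return ps.align_spikes([sim.spike_times], sim.reported_onsets)


def plateau(peth):
    c = peth.centers
    return peth.rate[0, (c >= -0.130) & (c < -0.030)].mean()


for tag, fps in [("zero jitter", None), ("60 fps", 60.0), ("10 fps", 10.0)]:
    print(f"{tag:>11}: plateau rate {plateau(peth_at(fps, seed=1)):.2f} Hz "
          "(ground truth 15 Hz)")

# population-level magnitude difference, high (60 fps) minus low (10 fps)
highs, lows = [], []
for i in range(6):
    highs.append(peth_at(60.0, seed=100 + i))
    lows.append(peth_at(10.0, seed=100 + i))
stack = lambda ps_, attr: np.vstack([getattr(p, attr) for p in ps_])
high = PETH(stack(highs, "rate"), stack(highs, "z"), stack(highs, "z_smooth"),
            highs[0].edges, 500)
low = PETH(stack(lows, "rate"), stack(lows, "z"), stack(lows, "z_smooth"),
           lows[0].edges, 500)
diff = ps.signal_magnitude_difference(high, low)
c = diff.centers
pre = (c >= -0.13) & (c < -0.03)
post = (c >= -0.01) & (c < 0.07)
print(
    f"signal magnitude difference (|z60| - |z10|), mean across 6 neurons: "
    f"{diff.mean[pre].mean():+.2f} in the modulation window, "
    f"{diff.mean[post].mean():+.2f} just after it"
)
print(
    f"{diff.significant.sum()} of {len(diff.significant)} bins significant "
    f"at p < {diff.alpha} (two-tailed t-test)"
)
# Positive before onset, negative after: the low-resolution alignment both
# weakens the true pre-onset signal and displaces it later in time.
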