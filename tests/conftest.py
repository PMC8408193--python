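"""Shared fixtures: synthetic sessions and fitted models reused across tests.

The expensive objects (UMAP fits, trained forests) are session-scoped and
derive from two canonical synthetic sessions:

* ``default_session`` — 150 s at 30 fps with the generator's default noise,
  the ordinary working condition;
* ``noiseless_session`` — 180 s at 30 fps with tracking jitter and dropout
  off and long (2 s) dwells, the clean condition for cluster-recovery
  checks (long dwells keep 100 ms bins from straddling motif switches,
  where the ground-truth label is ambiguous).
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poseseg as ps

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SEED = 11
NOISELESS_SEED = 7


@pytest.fixture(scope="session")
def default_session():
    return ps.simulate_pose(duration=150.0, fps=30.0, seed=SEED)


@pytest.fixture(scope="session")
def default_features(default_session):
    clean, _ = ps.substitute_low_confidence(default_session.pose)
    return ps.pose_to_features(clean)


@pytest.fixture(scope="session")
def default_seg(default_features):
    return ps.fit_segmentation(default_features, seed=SEED)


@pytest.fixture(scope="session")
def default_clf(default_features, default_seg):
    return ps.train(
        default_features, default_seg.cluster_labels, holdout=0.2, seed=SEED
    )


@pytest.fixture(scope="session")
def noiseless_session():
    return ps.simulate_pose(
        duration=180.0,
        fps=30.0,
        jitter_sd=0.0,
        dropout_rate=0.0,
        mean_dwell=2.0,
        seed=NOISELESS_SEED,
    )


@pytest.fixture(scope="session")
def noiseless_seg(noiseless_session):
    fm = ps.pose_to_features(noiseless_session.pose)
    return ps.fit_segmentation(fm, seed=NOISELESS_SEED)


@pytest.fixture(scope="session")
def session_200fps():
    return ps.simulate_pose(duration=30.0, fps=200.0, seed=42)


@pytest.fixture(scope="session")
def labels_200fps(session_200fps, default_clf):
    clean, _ = ps.substitute_low_confidence(session_200fps.pose)
    return ps.frameshift_predict(clean, default_clf), clean


@pytest.fixture()
def static_pose():
    """A pose series in which nothing moves."""
    coords = np.tile(
        np.array([[10.0, 20.0], [30.0, 40.0], [50.0, 10.0]]), (50, 1, 1)
    )
    lik = np.full((50, 3), 0.99)
    return ps.PoseSeries(["a", "b", "c"], coords, lik, fps=60.0)


def random_walk_pose(n_parts=3, t=50, fps=60.0, seed=0, step=2.0):
    rng = np.random.default_rng(seed)
    coords = np.cumsum(rng.normal(0, step, (t, n_parts, 2)), axis=0) + 100.0
    lik = np.full((t, n_parts), 0.99)
    names = [f"p{i}" for i in range(n_parts)]
    return ps.PoseSeries(names, coords, lik, fps=fps)
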