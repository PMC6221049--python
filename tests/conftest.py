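import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tmsfmri as tf

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quiet_spec():
    """Small noiseless phantom spec for geometric tests."""
    return tf.PhantomSpec(
        grid_shape=(16, 16, 16), n_dynamics=8, noise_sd=0.0,
        drift_amplitude=0.0, effect_pct=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def quiet_phantom(quiet_spec):
    return tf.generate_phantom(quiet_spec)


def make_blob_series(true_translation, shape=(12, 12, 12), vs=4.0, seed=2):
    """Two-volume series from an analytic Gaussian-blob scene.

    Volume 1 is the scene evaluated at rigidly shifted world coordinates,
    so the moved volume carries no resampling error — the registration
    cost is a clean single-interpolation objective for oracle comparisons.
    """
    from tmsfmri.core import RigidTransform, VolumeSeries

    A = np.diag([vs, vs, vs, 1.0])
    A[:3, 3] = -vs * (np.array(shape) - 1) / 2.0
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    world = (A[:3, :3] @ idx + A[:3, 3:4]).T
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-12, 12, (6, 3))
    amps = rng.uniform(400, 1000, 6)
    sig = 8.0

    def scene(pts):
        out = np.zeros(len(pts))
        for c, a in zip(centers, amps):
            out += a * np.exp(-np.sum((pts - c) ** 2, axis=1) / (2 * sig * sig))
        return out

    T = RigidTransform(np.eye(3), np.asarray(true_translation, dtype=float))
    ref = scene(world).reshape(shape)
    mov = scene(T.inverse().apply(world)).reshape(shape)  # mov(x) = ref(T^-1 x)
    return VolumeSeries(np.stack([ref, mov], axis=-1), A, 2.0)


def translation_grid_search(series, center_translation, step=0.25, span=1.0):
    """Exhaustive translation-only registration of volume 1 to volume 0."""
    from tmsfmri.core import RigidTransform, resample_volume

    ref = series.data[..., 0].astype(float)
    mov = series.data[..., 1].astype(float)
    interior = np.zeros(series.grid_shape, dtype=bool)
    interior[2:-2, 2:-2, 2:-2] = True
    axes = [np.arange(t - span, t + span + 1e-9, step) for t in center_translation]
    best, best_cost = None, np.inf
    for tx in axes[0]:
        for ty in axes[1]:
            for tz in axes[2]:
                G = RigidTransform(np.eye(3), np.array([tx, ty, tz]))
                warped, ok = resample_volume(mov, series.affine, G)
                m = interior & ok
                c = np.mean((warped[m] - ref[m]) ** 2)
                if c < best_cost:
                    best_cost, best = c, np.array([tx, ty, tz])
    return best


@pytest.fixture(scope="session")
def default_phantom():
    """One protocol-scale phantom (500 dynamics) shared across tests."""
    spec = tf.PhantomSpec(seed=3)
    return spec, tf.generate_phantom(spec)
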