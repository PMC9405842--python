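import numpy as np
import pytest

from oculodex import BinocularRecording, SimConfig, simulate_cohort


def make_recording(
    left, right, rate=200.0, t=None, label="unknown", **meta
) -> BinocularRecording:
    left = np.asarray(left, float)
    if t is None:
        t = np.arange(left.size) / rate
    return BinocularRecording(
        t=np.asarray(t, float),
        left_x=left,
        right_x=np.asarray(right, float),
        nominal_rate=rate,
        label=label,
        **meta,
    )


def flat_recording(n=600, rate=200.0, d0=0.5) -> BinocularRecording:
    """Still gaze with a constant vergence offset d0 (left - right)."""
    t = np.arange(n) / rate
    return BinocularRecording(
        t=t, left_x=np.full(n, d0 / 2), right_x=np.full(n, -d0 / 2), nominal_rate=rate
    )


def random_recording(rng: np.random.Generator, n=None) -> BinocularRecording:
    """Random-walk binocular trace exercising all sign patterns of D and DV."""
    if n is None:
        n = int(rng.integers(2, 201))
    t = np.cumsum(rng.uniform(0.003, 0.008, n))
    step = 10.0 ** rng.uniform(-3, -1)
    left = np.cumsum(rng.choice([-step, 0.0, step], n))
    right = np.cumsum(rng.choice([-step, 0.0, step], n))
    return BinocularRecording(t=t, left_x=left, right_x=right)


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects/group x 2 paintings — fast stand-in for the full design."""
    cfg = SimConfig(n_per_group=8, paintings=2, seed=7)
    manifest, recordings, truth = simulate_cohort(cfg)
    return cfg, manifest, recordings, truth
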