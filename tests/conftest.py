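import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_audio_factory():
    """Synthetic transmitter audio with ground truth, cached per parameters."""
    from cardiomet import synthetic as syn
    from cardiomet.trajectory import RateTrajectory

    cache = {}

    def make(bpm=300.0, duration=30.0, noise_sd=0.02, seed=0, carrier=1500.0):
        key = (bpm, duration, noise_sd, seed, carrier)
        if key not in cache:
            spec = syn.SignalSpec(carrier_freq=carrier, noise_sd=noise_sd, seed=seed)
            traj = RateTrajectory.constant(bpm, duration)
            cache[key] = syn.synthesize_transmitter_audio(spec, traj)
        return cache[key]

    return make


def match_events(detected: np.ndarray, truth: np.ndarray, tol: float = 0.02):
    """Greedy nearest matching of detected to true beat times.

    Returns (true positives, false positives, false negatives).
    """
    detected = np.sort(np.asarray(detected))
    truth = np.sort(np.asarray(truth))
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for t in detected:
        i = np.searchsorted(truth, t)
        best, best_d = -1, np.inf
        for j in (i - 1, i):
            if 0 <= j < truth.size and not used[j] and abs(truth[j] - t) < best_d:
                best, best_d = j, abs(truth[j] - t)
        if best >= 0 and best_d <= tol:
            used[best] = True
            tp += 1
    return tp, detected.size - tp, truth.size - tp
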