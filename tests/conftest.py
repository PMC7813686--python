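import numpy as np
import pytest

from ecgbeats import dataset as ds
from ecgbeats.synthetic import MILD_NOISE, NO_NOISE, generate_balanced_dataset, generate_record


@pytest.fixture(scope="session")
def noiseless_nor_train():
    """30 noiseless normal beats at ~75 bpm with ground-truth R indices."""
    return generate_record(["NOR"] * 30, noise=NO_NOISE, seed=2)


@pytest.fixture(scope="session")
def noisy_nor_train():
    """30 normal beats with mild powerline + white contamination."""
    return generate_record(["NOR"] * 30, noise=MILD_NOISE, seed=7)


@pytest.fixture(scope="session")
def small_balanced_segments():
    """Z-scored beat segments from a small 5-class balanced synthetic set."""
    pairs = generate_balanced_dataset(20, noise=NO_NOISE, seed=3)
    segs = [s for rec, _ in pairs for s in ds.segment_beats(rec).segments]
    return segs


def nearest_centroid_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    """Training accuracy of a nearest-centroid classifier (separability oracle)."""
    centroids = np.stack([X[y == c].mean(axis=0) for c in np.unique(y)])
    d = ((X[:, None, :] - centroids[None]) ** 2).sum(axis=2)
    return float((np.unique(y)[d.argmin(axis=1)] == y).mean())
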