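import numpy as np
import pytest

from cytostrat.preprocess import EventMatrix
from cytostrat.synthetic import CohortDesign, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-effect cohort shared by read-only tests."""
    design = CohortDesign(n_controls=8, n_per_group=8, cells_per_sample=250,
                          n_batches=2, seed=11)
    return simulate_cohort(design)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_events(values, markers, sample_id="s0", panel="T", batch="b0",
                scale="transformed"):
    return EventMatrix(np.asarray(values, dtype=float), list(markers),
                       sample_id=sample_id, panel=panel, batch=batch, scale=scale)


@pytest.fixture
def gaussian_mixture_samples():
    """Factory: per-sample Gaussian-mixture events with known composition."""

    def make(n_samples, cells, weights, centers, sd=0.4, seed=0, batch_of=None,
             shift_of=None):
        rng = np.random.default_rng(seed)
        centers = np.asarray(centers, dtype=float)
        k, d = centers.shape
        markers = [f"m{i}" for i in range(d)]
        out, labels = {}, {}
        for i in range(n_samples):
            sid = f"s{i:03d}"
            w = np.asarray(weights(i) if callable(weights) else weights, dtype=float)
            comp = rng.choice(k, size=cells, p=w / w.sum())
            X = rng.normal(centers[comp], sd)
            if shift_of is not None:
                X = X + shift_of(i)
            out[sid] = EventMatrix(
                X, markers, sample_id=sid, panel="T",
                batch=batch_of(i) if batch_of else "b0", scale="transformed")
            labels[sid] = comp
        return out, labels

    return make
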