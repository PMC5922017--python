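import numpy as np
import pytest

from mirlag.de import NormalizedMatrix
from mirlag.io_model import TIMEPOINTS, CountMatrix, Sample


def make_samples(n_per_group=6, rins=None):
    """Full 2x5 design; constant RIN 8.0 unless a vector is supplied."""
    out = []
    k = 0
    for t in TIMEPOINTS:
        for trt in ("control", "treated"):
            for _ in range(n_per_group):
                k += 1
                rin = 8.0 if rins is None else float(rins[k - 1])
                out.append(Sample(f"S{k:03d}", f"A{k:03d}", trt, t, rin))
    return out


def unit_normalized(counts, samples):
    """NormalizedMatrix with unit scale factors (offsets all zero)."""
    counts = np.asarray(counts)
    cm = CountMatrix([f"e{i}" for i in range(counts.shape[0])], samples, counts)
    return NormalizedMatrix(cm, np.ones(len(samples)), counts.astype(float))


def group_mean_counts(samples, treated_means, control_means, n_entities=1,
                      rng=None, phi=0.0):
    """Counts whose group means follow the given per-time-point targets."""
    t_index = {t: j for j, t in enumerate(TIMEPOINTS)}
    cols = []
    for s in samples:
        mu = (treated_means if s.treatment == "treated" else control_means)
        cols.append(mu[t_index[s.time_h]])
    mu = np.tile(np.asarray(cols, dtype=float), (n_entities, 1))
    if rng is None:
        return np.round(mu).astype(np.int64)
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / phi, mu * phi)
    return rng.poisson(lam)


@pytest.fixture(scope="session")
def full_design_samples():
    return make_samples()


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset shared by io/pipeline-level tests."""
    from mirlag.simulate import SimConfig, generate_dataset

    cfg = SimConfig(seed=123, n_mirna=40, n_mrna=80, frac_de=0.25,
                    n_true_pairs=5, n_decoy_pairs=20)
    return generate_dataset(cfg)
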