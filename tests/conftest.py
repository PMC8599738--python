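import numpy as np
import pandas as pd
import pytest

from enhancerkit import PWM, SignalTable, SimulationConfig, simulate_landscape

CHROM_SIZES = {"chr1": 1_000_000, "chr2": 800_000}


@pytest.fixture
def chrom_sizes():
    return dict(CHROM_SIZES)


@pytest.fixture
def small_config():
    """A small but complete landscape used across module tests."""
    return SimulationConfig(
        seed=7,
        n_class_i=50,
        n_class_ii=100,
        n_class_iii=10,
        n_unbound=20,
        n_inactive=300,
        n_proximal=50,
        n_shared_gene_pairs=10,
        n_se_clusters=5,
        n_extra_tf_peaks=50,
    )


@pytest.fixture(scope="session")
def small_landscape():
    config = SimulationConfig(
        seed=7,
        n_class_i=50,
        n_class_ii=100,
        n_class_iii=10,
        n_unbound=20,
        n_inactive=300,
        n_proximal=50,
        n_shared_gene_pairs=10,
        n_se_clusters=5,
        n_extra_tf_peaks=50,
    )
    return simulate_landscape(config)


def random_pwm(width: int, rng: np.random.Generator, background=None) -> PWM:
    """Dirichlet-random PWM for oracle comparisons."""
    probs = rng.dirichlet(np.full(4, 0.5), size=width)
    probs = np.maximum(probs, 1e-4)
    probs /= probs.sum(axis=1, keepdims=True)
    bg = np.full(4, 0.25) if background is None else background
    return PWM(f"RAND_w{width}", probs, bg)


def nb_counts(rng, mean, dispersion, size):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.asarray(mean, dtype=float)), size=size)


def two_group_table(counts: np.ndarray, stages=("GT", "PP2")) -> SignalTable:
    """Counts (n_regions, 2k) -> SignalTable with k replicates per stage."""
    n, m = counts.shape
    k = m // 2
    samples = [f"{stages[0]}_r{i}" for i in range(k)] + [
        f"{stages[1]}_r{i}" for i in range(k)
    ]
    design = pd.DataFrame(
        {
            "stage": [stages[0]] * k + [stages[1]] * k,
            "condition": ["ctrl"] * m,
            "replicate": list(range(k)) * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    frame = pd.DataFrame(
        counts, columns=samples, index=[f"r{i}" for i in range(n)]
    )
    return SignalTable(frame, design)
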