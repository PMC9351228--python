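import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracle

from methylsem import run_pipeline, synth


def make_exact_fixture(seed, n_sites=400, genome_length=30000):
    """Singleton-universe, noise-free, binary-methylation fixture.

    Every populated SEM cell equals the planted effect exactly.
    """
    truth = synth.demo_exact_truth(seed)
    parts = synth.build_fixture(
        truth,
        n_sites=n_sites,
        genome_length=genome_length,
        seed=seed,
        mode="cycle",
        forbidden_radius=1,
    )
    return truth, parts


def make_noisy_fixture(seed, n_sites=500, genome_length=42000):
    """Hamming<=1-universe fixture with lognormal noise and Beta methylation."""
    truth = synth.demo_noisy_truth(seed)
    parts = synth.build_fixture(
        truth,
        n_sites=n_sites,
        genome_length=genome_length,
        seed=seed,
        mode="random",
        n_subs_probs=(0.05, 0.15, 0.80),
        forbidden_radius=2,
    )
    return truth, parts


def run_on_fixture(parts, seed, **kwargs):
    genome, sites, peaks, signal, meth, motif = parts
    return run_pipeline(genome, peaks, signal, meth, motif, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def exact_run():
    truth, parts = make_exact_fixture(0)
    return truth, parts, run_on_fixture(parts, 0)


@pytest.fixture(scope="session")
def noisy_run():
    truth, parts = make_noisy_fixture(0)
    return truth, parts, run_on_fixture(parts, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
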