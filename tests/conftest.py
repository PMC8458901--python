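"""Shared fixtures: small random PWMs, genomes, weight tables, and a
module-scope simulated study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motifimpact.gkm import KmerWeightTable
from motifimpact.pwm import PWM
from motifimpact.simulate import SimulationConfig, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASES = "ACGT"


def random_pwm(rng: np.random.Generator, length: int, motif_id: str = "test") -> PWM:
    return PWM(rng.dirichlet(np.ones(4), size=length), motif_id=motif_id)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def random_weight_table(rng: np.random.Generator, l: int, collapse: bool = False) -> KmerWeightTable:
    return KmerWeightTable(l, rng.normal(size=4**l), collapse_revcomp=collapse)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def study():
    """One default-configuration synthetic study shared across modules."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast I/O and CLI tests."""
    cfg = SimulationConfig(
        seed=5,
        genome_length=20_000,
        n_peaks=12,
        n_background_snvs=20,
        n_motif_snvs=20,
        n_index_snvs=3,
    )
    return simulate_study(cfg)
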