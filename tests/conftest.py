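"""Shared fixtures: EBS configurations and a small seeded simulation."""

import pytest

from retrosplice import EBSConfig
from retrosplice.simulate import GeneratorConfig, simulate_reads

# EBS2 is a free configuration choice (5 nt); an arbitrary mixed-composition
# 5-mer is used throughout the tests.
EBS2_TEST = "CGUGA"


@pytest.fixture(scope="session")
def ebs_wt() -> EBSConfig:
    """Wild-type-like configuration: G/U-rich EBS1 with many wobble partners."""
    return EBSConfig(name="wt", ebs1="GUUGUG", ebs2=EBS2_TEST)


@pytest.fixture(scope="session")
def ebs_mut() -> EBSConfig:
    """Stringent EBS1 variant built from A and C (a single perfect partner)."""
    return EBSConfig(name="mut", ebs1="CAACAC", ebs2=EBS2_TEST)


def small_config(**overrides) -> GeneratorConfig:
    """A fast, reduced-scale generator configuration for unit tests."""
    base = dict(
        seed=7,
        n_genes=10,
        gene_len_range=(600, 900),
        n_planted_sites=6,
        n_perfect_circles=2,
        n_inserted_circles=2,
        insert_len_range=(20, 80),
        n_rs_events=4,
        n_e1_chimeras=2,
        n_mrna_chimeras=2,
        n_background_reads=40,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_sim(ebs_wt):
    """Reduced-scale simulation shared by caller tests (read-only)."""
    return simulate_reads(small_config(), ebs_wt)
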