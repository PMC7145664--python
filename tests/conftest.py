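import pytest

from plastidhap.references import RegionSet, build_references
from plastidhap.simulate import SimConfig, simulate_dataset


def _random_seq(n, seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_regions() -> RegionSet:
    """Small deterministic plastome: LSC 5000, IR 2000, SSC 3000 (G = 12000)."""
    return RegionSet(
        lsc=_random_seq(5000, 1),
        ssc=_random_seq(3000, 2),
        ir=_random_seq(2000, 3),
    )


@pytest.fixture(scope="session")
def toy_refs(toy_regions):
    return build_references(toy_regions)


def scaled_config(**overrides) -> SimConfig:
    """Desk-scale study conditions shared by the end-to-end tests: a
    reduced plastome (LSC 9 kb, SSC 4 kb, IR 2.5 kb, G = 18 kb) keeping
    the real geometry's proportions, reads log-normal around 7 kb so a
    realistic fraction spans IR + 1 kb flanks."""
    defaults = dict(
        lsc_len=9000,
        ssc_len=4000,
        ir_len=2500,
        n_reads=600,
        read_median=7000,
        read_sigma=0.3,
        read_min=2000,
        read_max=18000,
        seed=42,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_5050():
    """600 reads from an equal A/B isomer mixture, with its references."""
    sim = simulate_dataset(scaled_config())
    return sim, build_references(sim.regions)


@pytest.fixture(scope="session")
def sim_inline():
    """400 reads from a genome whose repeat copies are in-line (haplotype C)."""
    sim = simulate_dataset(scaled_config(mixture={"C": 1.0}, n_reads=400, seed=7))
    return sim, build_references(sim.regions)
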