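"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from pigpan import simulate as sim

SMALL_RATES = {
    "absence": 60,
    "presence": 40,
    "inversion": 10,
    "translocation_intra": 5,
    "translocation_inter": 5,
}


@pytest.fixture(scope="session")
def occupancy_small():
    return sim.simulate_occupancy(n_genomes=8, n_families=300, seed=11)


@pytest.fixture(scope="session")
def callsets_small():
    return sim.simulate_sv_callsets(
        n_genomes=4, rates=SMALL_RATES, redundancy=0.5, jitter=10, seed=7
    )


@pytest.fixture(scope="session")
def genotypes_small():
    return sim.simulate_population_genotypes(
        n_per_pop=(20, 20), n_loci=500, differentiated_fraction=0.02,
        divergence=0.8, missing_rate=0.02, seed=5,
    )


@pytest.fixture(scope="session")
def numt_landscape_small():
    return sim.simulate_numt_landscape(
        n_assemblies=5,
        insertions=[(0.5, 600), (2.0, 800), (5.0, 700), (8.0, 900), (9.7, 650)],
        seed=13,
    )


@pytest.fixture(scope="session")
def features_null():
    return sim.simulate_features(n_svs=800, seed=17)
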