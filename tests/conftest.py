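import warnings

import numpy as np
import pytest

from breeddiv.pedigree import AnimalRecord, Pedigree, select_reference_population
from breeddiv.simulate import BreedSimConfig, simulate_breed


@pytest.fixture(scope="session")
def breed_sim():
    """Default desk-scale synthetic breed shared across tests (seeded)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim, statuses = simulate_breed(BreedSimConfig(seed=1))
    return sim, statuses


@pytest.fixture(scope="session")
def breed_refpop(breed_sim):
    sim, _ = breed_sim
    return select_reference_population(sim.pedigree, 2005, 2015)


@pytest.fixture
def trio_pedigree():
    """Founder couple and one offspring."""
    return Pedigree(
        [
            AnimalRecord(id="s", sex="male", birth_year=1990),
            AnimalRecord(id="d", sex="female", birth_year=1992),
            AnimalRecord(id="o", sire="s", dam="d", birth_year=1996),
        ]
    )


@pytest.fixture
def fullsib_offspring_pedigree():
    """Two founders, two full sibs, and an offspring of the sib mating."""
    return Pedigree(
        [
            AnimalRecord(id="p1", sex="male"),
            AnimalRecord(id="p2", sex="female"),
            AnimalRecord(id="s1", sire="p1", dam="p2", sex="male"),
            AnimalRecord(id="s2", sire="p1", dam="p2", sex="female"),
            AnimalRecord(id="x", sire="s1", dam="s2"),
        ]
    )


@pytest.fixture
def bottleneck_pedigree():
    """Ten animals: four founders funneled through one couple to four members.

    Every member descends from the couple (A, B); hand-worked gene-origin
    values: founder contributions 1/4 each (f_e = 4), marginal contributions
    0.5 for A then 0.5 for B (f_a = 2).
    """
    recs = [
        AnimalRecord(id="F1", sex="male", birth_year=1988),
        AnimalRecord(id="F2", sex="female", birth_year=1988),
        AnimalRecord(id="F3", sex="male", birth_year=1989),
        AnimalRecord(id="F4", sex="female", birth_year=1989),
        AnimalRecord(id="A", sire="F1", dam="F2", sex="male", birth_year=1990),
        AnimalRecord(id="B", sire="F3", dam="F4", sex="female", birth_year=1991),
    ]
    for i, name in enumerate(["C", "D", "E", "G"]):
        recs.append(
            AnimalRecord(id=name, sire="A", dam="B", birth_year=1995 + i)
        )
    return Pedigree(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
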