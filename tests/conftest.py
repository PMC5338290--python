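import pytest

from phytophagnet.model import (
    CompoundCatalog,
    PlantHerbivoreNetwork,
    TaxonomyMap,
    TaxonomyRecord,
)
from phytophagnet.synthetic import GeneratorConfig, generate_all


@pytest.fixture
def toy_net():
    """Two insect families feeding assortatively on two plant families."""
    edges = [
        ("Aaa a", "Pa x"), ("Aaa a", "Pa y"),
        ("Aaa b", "Pa x"), ("Aaa b", "Pb z"),
        ("Bbb c", "Pb z"), ("Bbb c", "Pb w"),
    ]
    return PlantHerbivoreNetwork(edges)


@pytest.fixture
def toy_taxonomies():
    itax = TaxonomyMap(side="insect")
    itax.add("Aaa a", TaxonomyRecord(family="FamA", subfamily="SubA1"))
    itax.add("Aaa b", TaxonomyRecord(family="FamA", subfamily="SubA2"))
    itax.add("Bbb c", TaxonomyRecord(family="FamB"))
    ptax = TaxonomyMap(side="plant")
    ptax.add("Pa x", TaxonomyRecord(family="PFamA"))
    ptax.add("Pa y", TaxonomyRecord(family="PFamA"))
    ptax.add("Pb z", TaxonomyRecord(family="PFamB"))
    ptax.add("Pb w", TaxonomyRecord(family="PFamB"))
    return itax, ptax


@pytest.fixture
def fig_toy():
    """Four plants / five butterflies toy used for the compound partition.

    C1 occurs in every plant; C2 only in P3 and P4, the exclusive hosts of
    butterflies B4 and B5.
    """
    net = PlantHerbivoreNetwork([
        ("But one", "Plant P1"), ("But one", "Plant P2"),
        ("But two", "Plant P1"), ("But three", "Plant P2"),
        ("But four", "Plant P3"), ("But four", "Plant P4"),
        ("But five", "Plant P3"), ("But five", "Plant P4"),
    ])
    cat = CompoundCatalog({
        "Plant P1": {"C1", "C3"},
        "Plant P2": {"C1"},
        "Plant P3": {"C1", "C2"},
        "Plant P4": {"C1", "C2", "C4"},
    })
    return net, cat


def small_generator_config(seed=0, **overrides):
    """Reduced synthetic configuration used for null-model-heavy tests."""
    kwargs = dict(
        n_plant_families=3,
        plants_per_family=10,
        n_insect_families=3,
        subfamilies_per_family=2,
        species_per_subfamily=3,
        hosts_per_species=4,
        n_core_compounds_per_plant_family=3,
        n_background_compounds=10,
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture
def small_bundle():
    return generate_all(small_generator_config(seed=11))
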