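"""Synthetic plant-herbivore networks with planted chemical structure.

The generator emulates the structure the analysis pipeline is built to
detect: a taxonomically balanced bipartite network in which each insect
family (clade) prefers one plant family with strength ``lambda_family``
and is attracted to plants carrying its planted clade-specific compound
with strength ``beta_compound``.  Preferences act as exponential tilts on
per-plant log-weights, giving a single smooth family of models from
uniform random feeding (lambda = beta = 0) to deterministic feeding.

Plant chemistry is layered: an optional globally common compound (present
in every plant, uninformative for selection), family-core compounds shared
by all plants of one family, clade-specific compounds planted into all
plants of designated families, and background compounds sprinkled
independently with probability ``compound_noise``.

Ground truth (preferred families, planted compounds, per-edge generative
log-weights, config echo) is emitted alongside the data so planted effects
can be recovered and calibration checked.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np

from . import io as pio
from .model import CompoundCatalog, PlantHerbivoreNetwork, TaxonomyMap, TaxonomyRecord

__all__ = [
    "GeneratorConfig",
    "SyntheticGroundTruth",
    "SyntheticBundle",
    "generate_taxonomy",
    "generate_compounds",
    "generate_network",
    "generate_all",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the generating model.

    ``lambda_family = beta_compound = 0`` recovers uniform random feeding.
    Optional per-clade overrides (index-aligned with insect families) allow
    heterogeneous selection strengths across clades.
    """

    n_plant_families: int = 4
    plants_per_family: int = 25
    n_insect_families: int = 5
    subfamilies_per_family: int = 2
    species_per_subfamily: int = 5
    hosts_per_species: int = 5
    lambda_family: float = 2.0
    beta_compound: float = 2.0
    lambda_by_clade: Optional[tuple[float, ...]] = None
    beta_by_clade: Optional[tuple[float, ...]] = None
    n_core_compounds_per_plant_family: int = 5
    n_clade_specific_compounds: int = 1
    n_background_compounds: int = 30
    compound_noise: float = 0.05
    include_common_compound: bool = True
    clade_compound_families: int = 1
    clade_compound_plant_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_plant_families", "plants_per_family", "n_insect_families",
            "subfamilies_per_family", "species_per_subfamily", "hosts_per_species",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("lambda_family", "beta_compound"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "n_core_compounds_per_plant_family", "n_clade_specific_compounds",
            "n_background_compounds",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.compound_noise <= 1.0:
            raise ValueError("compound_noise must be in [0, 1]")
        if not 1 <= self.clade_compound_families <= self.n_plant_families:
            raise ValueError("clade_compound_families must be in [1, n_plant_families]")
        if not 0.0 < self.clade_compound_plant_fraction <= 1.0:
            raise ValueError("clade_compound_plant_fraction must be in (0, 1]")
        if self.hosts_per_species > self.n_plant_families * self.plants_per_family:
            raise ValueError("hosts_per_species exceeds the number of plants")
        for name in ("lambda_by_clade", "beta_by_clade"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, tuple(float(x) for x in v))
                if len(getattr(self, name)) != self.n_insect_families:
                    raise ValueError(f"{name} must have one entry per insect family")

    def clade_lambda(self, clade_index: int) -> float:
        return self.lambda_by_clade[clade_index] if self.lambda_by_clade else self.lambda_family

    def clade_beta(self, clade_index: int) -> float:
        return self.beta_by_clade[clade_index] if self.beta_by_clade else self.beta_compound


@dataclass
class SyntheticGroundTruth:
    """What was planted: preferences, compounds, and edge log-weights."""

    clade_preferred_family: dict[str, str] = field(default_factory=dict)
    clade_compound_families: dict[str, list[str]] = field(default_factory=dict)
    clade_compounds: dict[str, list[str]] = field(default_factory=dict)
    core_compounds: dict[str, list[str]] = field(default_factory=dict)
    common_compounds: list[str] = field(default_factory=list)
    background_compounds: list[str] = field(default_factory=list)
    edge_log_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    config: Optional[GeneratorConfig] = None

    def to_json_dict(self) -> dict:
        return {
            "clade_preferred_family": self.clade_preferred_family,
            "clade_compound_families": self.clade_compound_families,
            "clade_compounds": self.clade_compounds,
            "core_compounds": self.core_compounds,
            "common_compounds": self.common_compounds,
            "background_compounds": self.background_compounds,
            "edge_log_weights": {f"{i}\t{p}": w for (i, p), w in self.edge_log_weights.items()},
            "config": dataclasses.asdict(self.config) if self.config else None,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticGroundTruth":
        cfg = d.get("config")
        return cls(
            clade_preferred_family=dict(d["clade_preferred_family"]),
            clade_compound_families={k: list(v) for k, v in d["clade_compound_families"].items()},
            clade_compounds={k: list(v) for k, v in d["clade_compounds"].items()},
            core_compounds={k: list(v) for k, v in d["core_compounds"].items()},
            common_compounds=list(d["common_compounds"]),
            background_compounds=list(d["background_compounds"]),
            edge_log_weights={
                tuple(k.split("\t")): float(w) for k, w in d["edge_log_weights"].items()
            },
            config=GeneratorConfig(**cfg) if cfg else None,
        )


class SyntheticBundle(NamedTuple):
    network: PlantHerbivoreNetwork
    insect_taxonomy: TaxonomyMap
    plant_taxonomy: TaxonomyMap
    catalog: CompoundCatalog
    truth: SyntheticGroundTruth


# -- deterministic naming ----------------------------------------------------

def plant_family_name(f: int) -> str:
    return f"Plantacea{f:02d}"


def insect_family_name(f: int) -> str:
    return f"Lepifam{f:02d}"


def _plant_species(f: int, s: int) -> str:
    return f"Florigena{f:02d} species{s:02d}"


def _insect_species(f: int, sub: int, s: int) -> str:
    return f"Lepidora{f:02d}x{sub:02d} species{s:02d}"


def generate_taxonomy(config: GeneratorConfig) -> tuple[TaxonomyMap, TaxonomyMap]:
    """Balanced (insect, plant) taxonomies with deterministic names."""
    plant_tax = TaxonomyMap(side="plant")
    for f in range(config.n_plant_families):
        for s in range(config.plants_per_family):
            plant_tax.add(
                _plant_species(f, s),
                TaxonomyRecord(
                    family=plant_family_name(f),
                    genus=f"Florigena{f:02d}",
                    order=f"Plantales{f % 2:02d}",
                ),
            )
    insect_tax = TaxonomyMap(side="insect")
    for f in range(config.n_insect_families):
        for sub in range(config.subfamilies_per_family):
            for s in range(config.species_per_subfamily):
                insect_tax.add(
                    _insect_species(f, sub, s),
                    TaxonomyRecord(
                        family=insect_family_name(f),
                        subfamily=f"{insect_family_name(f)}inae{sub:02d}",
                        genus=f"Lepidora{f:02d}x{sub:02d}",
                        order="Lepidoptera",
                    ),
                )
    return insect_tax, plant_tax


def _clade_designated_families(config: GeneratorConfig, clade_index: int) -> list[str]:
    start = clade_index % config.n_plant_families
    return [
        plant_family_name((start + k) % config.n_plant_families)
        for k in range(config.clade_compound_families)
    ]


def generate_compounds(
    config: GeneratorConfig, plant_tax: TaxonomyMap
) -> tuple[CompoundCatalog, SyntheticGroundTruth]:
    """Layered chemistry: common, family-core, clade-specific, background."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    truth = SyntheticGroundTruth(config=config)
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"C{counter:08d}"

    plants = sorted(plant_tax.records)
    by_family: dict[str, list[str]] = {}
    for p in plants:
        by_family.setdefault(plant_tax.family(p), []).append(p)

    assignments: dict[str, set[str]] = {p: set() for p in plants}
    if config.include_common_compound:
        cid = next_id()
        truth.common_compounds.append(cid)
        for p in plants:
            assignments[p].add(cid)
    for fam in sorted(by_family):
        core = [next_id() for _ in range(config.n_core_compounds_per_plant_family)]
        truth.core_compounds[fam] = core
        for p in by_family[fam]:
            assignments[p].update(core)
    for f in range(config.n_insect_families):
        clade = insect_family_name(f)
        designated = _clade_designated_families(config, f)
        truth.clade_preferred_family[clade] = designated[0]
        truth.clade_compound_families[clade] = designated
        planted = [next_id() for _ in range(config.n_clade_specific_compounds)]
        truth.clade_compounds[clade] = planted
        candidates = [p for fam in designated for p in by_family[fam]]
        if config.clade_compound_plant_fraction >= 1.0:
            carriers = candidates
        else:
            # partial within-family chemical sharing; every planted compound
            # must still appear in at least one plant
            keep = rng.random(len(candidates)) < config.clade_compound_plant_fraction
            carriers = [p for p, k in zip(candidates, keep) if k]
            if not carriers and planted:
                carriers = [candidates[int(rng.integers(len(candidates)))]]
        for p in carriers:
            assignments[p].update(planted)
    background = [next_id() for _ in range(config.n_background_compounds)]
    truth.background_compounds = background
    if background and config.compound_noise > 0:
        hit = rng.random((len(plants), len(background))) < config.compound_noise
        for pi, p in enumerate(plants):
            assignments[p].update(c for bi, c in enumerate(background) if hit[pi, bi])

    cat = CompoundCatalog({p: s for p, s in assignments.items() if s})
    return cat, truth


def generate_network(
    config: GeneratorConfig,
    insect_tax: TaxonomyMap,
    plant_tax: TaxonomyMap,
    catalog: CompoundCatalog,
    truth: SyntheticGroundTruth,
) -> tuple[PlantHerbivoreNetwork, SyntheticGroundTruth]:
    """Draw each insect's hosts without replacement from tilted weights.

    log-weight(plant) = lambda_c * 1[plant in clade's preferred family]
                      + beta_c * 1[plant carries a clade-planted compound].
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    plants = sorted(plant_tax.records)
    plant_fams = np.array([plant_tax.family(p) for p in plants])
    clade_index = {insect_family_name(f): f for f in range(config.n_insect_families)}

    edges = []
    for insect in sorted(insect_tax.records):
        clade = insect_tax.family(insect)
        ci = clade_index[clade]
        preferred = truth.clade_preferred_family[clade]
        planted = set(truth.clade_compounds.get(clade, ()))
        in_pref = (plant_fams == preferred).astype(float)
        has_comp = np.array(
            [1.0 if planted and (planted & catalog.compounds_of(p)) else 0.0 for p in plants]
        )
        logw = config.clade_lambda(ci) * in_pref + config.clade_beta(ci) * has_comp
        w = np.exp(logw - logw.max())
        hosts = rng.choice(len(plants), size=config.hosts_per_species, replace=False, p=w / w.sum())
        for h in hosts:
            edges.append((insect, plants[h]))
            truth.edge_log_weights[(insect, plants[h])] = float(logw[h])

    net = PlantHerbivoreNetwork(edges, insects=insect_tax.records, plants=plants)
    return net, truth


def generate_all(config: GeneratorConfig) -> SyntheticBundle:
    """Taxonomy, chemistry, and network in one deterministic call."""
    insect_tax, plant_tax = generate_taxonomy(config)
    catalog, truth = generate_compounds(config, plant_tax)
    net, truth = generate_network(config, insect_tax, plant_tax, catalog, truth)
    return SyntheticBundle(net, insect_tax, plant_tax, catalog, truth)


def write_fixture(directory, bundle: SyntheticBundle) -> dict[str, Path]:
    """Persist all artifacts as TSV + JSON; re-reading round-trips exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": pio.write_interaction_table(bundle.network, directory / "interactions.tsv"),
        "insect_taxonomy": pio.write_taxonomy_table(
            bundle.insect_taxonomy, directory / "insect_taxonomy.tsv"
        ),
        "plant_taxonomy": pio.write_taxonomy_table(
            bundle.plant_taxonomy, directory / "plant_taxonomy.tsv"
        ),
        "compounds": pio.write_compound_table(bundle.catalog, directory / "compounds.tsv"),
        "truth": directory / "truth.json",
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(bundle.truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_fixture(directory) -> SyntheticBundle:
    directory = Path(directory)
    net = pio.read_interaction_table(directory / "interactions.tsv")
    insect_tax = pio.read_taxonomy_table(directory / "insect_taxonomy.tsv", side="insect")
    plant_tax = pio.read_taxonomy_table(directory / "plant_taxonomy.tsv", side="plant")
    cat = pio.read_compound_table(directory / "compounds.tsv")
    with open(directory / "truth.json", "r", encoding="utf-8") as fh:
        truth = SyntheticGroundTruth.from_json_dict(json.load(fh))
    # the interaction TSV does not carry isolated nodes; restore node sets
    net = PlantHerbivoreNetwork(
        net.edges, insects=insect_tax.records, plants=plant_tax.records
    )
    return SyntheticBundle(net, insect_tax, plant_tax, cat, truth)
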