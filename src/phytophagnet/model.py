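"""Core domain types for chemically annotated plant-herbivore networks.

The central object is an unweighted bipartite network linking herbivorous
insect species to the plant species they feed on.  Species are identified by
canonical binomial strings; taxonomic context (genus, subfamily, family,
order) lives in a :class:`TaxonomyMap` per side, and plant chemistry in a
:class:`CompoundCatalog` mapping each plant species to its set of compound
identifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "SpeciesId",
    "PhytophagnetError",
    "TableFormatError",
    "TaxonomyConsistencyError",
    "EmptyNetworkError",
    "normalize_species_name",
    "TaxonomyRecord",
    "TaxonomyMap",
    "PlantHerbivoreNetwork",
    "CompoundCatalog",
    "restrict_to_compound_annotated",
]

#: Canonical binomial species name (genus + epithet, single internal spaces).
SpeciesId = str

_WS = re.compile(r"\s+")

TAXON_LEVELS = ("species", "genus", "subfamily", "family", "order")


class PhytophagnetError(Exception):
    """Base class for package errors."""


class TableFormatError(PhytophagnetError, ValueError):
    """A delimited input table violates the expected layout."""


class TaxonomyConsistencyError(PhytophagnetError, ValueError):
    """A species is assigned to conflicting taxonomic records."""


class EmptyNetworkError(PhytophagnetError, ValueError):
    """An operation requires a non-empty network."""


def normalize_species_name(name: str) -> SpeciesId:
    """Collapse internal whitespace and strip; reject empty names.

    Matching elsewhere in the package is exact after this normalization —
    no fuzzy or synonym matching is attempted.
    """
    if name is None:
        raise ValueError("species name is None")
    norm = _WS.sub(" ", str(name)).strip()
    if not norm:
        raise ValueError("empty species name")
    return norm


@dataclass(frozen=True)
class TaxonomyRecord:
    """Taxonomic placement of one species; only ``family`` is mandatory."""

    family: str
    genus: Optional[str] = None
    subfamily: Optional[str] = None
    order: Optional[str] = None


@dataclass
class TaxonomyMap:
    """Species -> taxonomy lookup for one side (``insect`` or ``plant``)."""

    side: str
    records: dict[SpeciesId, TaxonomyRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in ("insect", "plant"):
            raise ValueError(f"side must be 'insect' or 'plant', got {self.side!r}")

    def __contains__(self, species: SpeciesId) -> bool:
        return species in self.records

    def __len__(self) -> int:
        return len(self.records)

    def add(self, species: SpeciesId, record: TaxonomyRecord) -> None:
        species = normalize_species_name(species)
        existing = self.records.get(species)
        if existing is not None and existing != record:
            raise TaxonomyConsistencyError(
                f"conflicting taxonomy for {species!r}: {existing} vs {record}"
            )
        self.records[species] = record

    def family(self, species: SpeciesId) -> Optional[str]:
        rec = self.records.get(species)
        return rec.family if rec is not None else None

    def level(self, species: SpeciesId, level: str) -> Optional[str]:
        """Taxon name of ``species`` at ``level``; None when unresolvable."""
        if level not in TAXON_LEVELS:
            raise ValueError(f"unknown taxonomic level {level!r}; expected one of {TAXON_LEVELS}")
        if level == "species":
            return species
        rec = self.records.get(species)
        if rec is None:
            return None
        return getattr(rec, level)

    def members(self, taxon: str, level: str, species_pool: Iterable[SpeciesId]) -> set[SpeciesId]:
        """Species from ``species_pool`` that belong to ``taxon`` at ``level``."""
        return {s for s in species_pool if self.level(s, level) == taxon}


class PlantHerbivoreNetwork:
    """Unweighted bipartite network of insect-plant feeding relationships.

    Node sets are retained even when a species has no edges (isolated nodes
    can matter for reporting); edges are unique (insect, plant) pairs.
    """

    def __init__(
        self,
        edges: Iterable[tuple[SpeciesId, SpeciesId]],
        insects: Optional[Iterable[SpeciesId]] = None,
        plants: Optional[Iterable[SpeciesId]] = None,
        _normalized: bool = False,
    ) -> None:
        if _normalized:
            # internal fast path: names already canonical (null-model replicates)
            self.edges = frozenset(edges)
            self.insects = frozenset(insects) if insects is not None else frozenset(
                i for i, _ in self.edges
            )
            self.plants = frozenset(plants) if plants is not None else frozenset(
                p for _, p in self.edges
            )
        else:
            self.edges = frozenset(
                (normalize_species_name(i), normalize_species_name(p)) for i, p in edges
            )
            edge_insects = {i for i, _ in self.edges}
            edge_plants = {p for _, p in self.edges}
            self.insects = frozenset(
                normalize_species_name(s) for s in insects
            ) if insects is not None else frozenset(edge_insects)
            self.plants = frozenset(
                normalize_species_name(s) for s in plants
            ) if plants is not None else frozenset(edge_plants)
            if not edge_insects <= self.insects:
                raise ValueError(
                    f"edges reference unlisted insects: {sorted(edge_insects - self.insects)[:5]}"
                )
            if not edge_plants <= self.plants:
                raise ValueError(
                    f"edges reference unlisted plants: {sorted(edge_plants - self.plants)[:5]}"
                )
        hosts: dict[SpeciesId, set[SpeciesId]] = {}
        herbs: dict[SpeciesId, set[SpeciesId]] = {}
        for i, p in self.edges:
            hosts.setdefault(i, set()).add(p)
            herbs.setdefault(p, set()).add(i)
        self._hosts = {k: frozenset(v) for k, v in hosts.items()}
        self._herbivores = {k: frozenset(v) for k, v in herbs.items()}

    # -- queries ---------------------------------------------------------

    def hosts_of(self, insect: SpeciesId) -> frozenset[SpeciesId]:
        """Host plants of an insect species (empty set if isolated)."""
        return self._hosts.get(insect, frozenset())

    def herbivores_of(self, plant: SpeciesId) -> frozenset[SpeciesId]:
        """Insect species feeding on a plant (empty set if isolated)."""
        return self._herbivores.get(plant, frozenset())

    def insect_degree(self, insect: SpeciesId) -> int:
        return len(self._hosts.get(insect, ()))

    def plant_degree(self, plant: SpeciesId) -> int:
        return len(self._herbivores.get(plant, ()))

    def degree_sequences(self) -> tuple[dict[SpeciesId, int], dict[SpeciesId, int]]:
        """(insect degrees, plant degrees) including isolated nodes at 0."""
        ins = {s: self.insect_degree(s) for s in self.insects}
        pla = {s: self.plant_degree(s) for s in self.plants}
        return ins, pla

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def drop_isolated(self) -> "PlantHerbivoreNetwork":
        return PlantHerbivoreNetwork(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlantHerbivoreNetwork):
            return NotImplemented
        return (
            self.edges == other.edges
            and self.insects == other.insects
            and self.plants == other.plants
        )

    def __repr__(self) -> str:
        return (
            f"PlantHerbivoreNetwork(insects={len(self.insects)}, "
            f"plants={len(self.plants)}, edges={len(self.edges)})"
        )


class CompoundCatalog:
    """Plant species -> set of compound identifiers (opaque strings)."""

    def __init__(self, records: Optional[Mapping[SpeciesId, Iterable[str]]] = None) -> None:
        self._records: dict[SpeciesId, frozenset[str]] = {}
        if records:
            for plant, compounds in records.items():
                self.add(plant, compounds)

    def add(self, plant: SpeciesId, compounds: Iterable[str]) -> None:
        plant = normalize_species_name(plant)
        new = frozenset(str(c) for c in compounds)
        if any(not c or c != c.strip() for c in new):
            raise ValueError(f"blank or padded compound ID for plant {plant!r}")
        self._records[plant] = self._records.get(plant, frozenset()) | new

    def compounds_of(self, plant: SpeciesId) -> frozenset[str]:
        """Compound set of ``plant``; empty when the plant is unknown."""
        return self._records.get(plant, frozenset())

    def n_compounds(self, plant: SpeciesId) -> int:
        return len(self.compounds_of(plant))

    def shared(self, a: SpeciesId, b: SpeciesId) -> int:
        """|C_a ∩ C_b| — the pairwise kernel of N_s and χ."""
        return len(self.compounds_of(a) & self.compounds_of(b))

    @property
    def plants(self) -> frozenset[SpeciesId]:
        return frozenset(self._records)

    def all_compounds(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self._records.values():
            out |= s
        return frozenset(out)

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundCatalog):
            return NotImplemented
        return self._records == other._records

    def items(self):
        return self._records.items()


def restrict_to_compound_annotated(
    net: PlantHerbivoreNetwork, cat: CompoundCatalog
) -> PlantHerbivoreNetwork:
    """Keep only edges whose plant carries at least one known compound.

    This is the extraction step that defines the chemically annotated
    ("real-world") network: species left without edges are dropped.  The
    operation is idempotent and can only shrink node degrees.
    """
    kept = [(i, p) for i, p in net.edges if len(cat.compounds_of(p)) > 0]
    return PlantHerbivoreNetwork(kept)
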