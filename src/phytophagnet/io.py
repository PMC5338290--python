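"""Delimited-text readers and writers for networks, taxonomy and compounds.

Tables are TSV or CSV with a mandatory header row; the delimiter is
auto-detected between tab and comma unless given explicitly.  Column
contracts:

* interaction table: ``insect``, ``plant``
* taxonomy table: ``species``, ``family`` (+ optional ``genus``,
  ``subfamily``, ``order``; blank = absent)
* compound table: ``plant``, ``compound``
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from .model import (
    CompoundCatalog,
    EmptyNetworkError,
    PlantHerbivoreNetwork,
    TableFormatError,
    TaxonomyConsistencyError,
    TaxonomyMap,
    TaxonomyRecord,
    normalize_species_name,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_interaction_table",
    "read_taxonomy_table",
    "read_compound_table",
    "export_network",
    "write_interaction_table",
    "write_taxonomy_table",
    "write_compound_table",
]


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise TableFormatError(f"{path}: cannot detect delimiter (no tab or comma in header)")


def _read_table(path, sep: Optional[str], required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyNetworkError(f"{path}: file is empty")
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def read_interaction_table(path, sep: Optional[str] = None) -> PlantHerbivoreNetwork:
    """Read one-row-per-relationship interactions into a bipartite network.

    Duplicate rows collapse to a single unweighted edge.
    """
    df = _read_table(path, sep, ("insect", "plant"))
    if df.empty:
        raise EmptyNetworkError(f"{path}: no interaction rows")
    edges = {
        (normalize_species_name(i), normalize_species_name(p))
        for i, p in zip(df["insect"], df["plant"])
    }
    net = PlantHerbivoreNetwork(edges)
    log.info(
        "read %s: %d rows -> %d unique edges, %d insects, %d plants",
        path, len(df), net.n_edges, len(net.insects), len(net.plants),
    )
    return net


def read_taxonomy_table(path, side: str, sep: Optional[str] = None) -> TaxonomyMap:
    """Read a species taxonomy table; conflicting duplicate rows are rejected."""
    df = _read_table(path, sep, ("species", "family"))
    tax = TaxonomyMap(side=side)
    for _, row in df.iterrows():
        family = str(row["family"]).strip()
        if not family:
            raise TableFormatError(f"{path}: species {row['species']!r} has no family")
        rec = TaxonomyRecord(
            family=family,
            genus=str(row["genus"]).strip() or None if "genus" in df.columns else None,
            subfamily=str(row["subfamily"]).strip() or None if "subfamily" in df.columns else None,
            order=str(row["order"]).strip() or None if "order" in df.columns else None,
        )
        try:
            tax.add(row["species"], rec)
        except TaxonomyConsistencyError:
            raise TaxonomyConsistencyError(
                f"{path}: species {normalize_species_name(row['species'])!r} "
                f"assigned conflicting taxonomy"
            ) from None
    log.info("read %s: %d %s species", path, len(tax), side)
    return tax


def read_compound_table(path, sep: Optional[str] = None) -> CompoundCatalog:
    """Read (plant, compound) rows into a per-plant compound catalog."""
    df = _read_table(path, sep, ("plant", "compound"))
    cat = CompoundCatalog()
    for plant, compound in zip(df["plant"], df["compound"]):
        compound = str(compound).strip()
        if not compound:
            raise TableFormatError(f"{path}: empty compound ID for plant {plant!r}")
        cat.add(plant, [compound])
    log.info("read %s: %d annotated plants, %d compounds", path, len(cat), len(cat.all_compounds()))
    return cat


def write_interaction_table(net: PlantHerbivoreNetwork, path, sep: str = "\t") -> Path:
    path = Path(path)
    df = pd.DataFrame(sorted(net.edges), columns=["insect", "plant"])
    df.to_csv(path, sep=sep, index=False)
    return path


def write_taxonomy_table(tax: TaxonomyMap, path, sep: str = "\t") -> Path:
    path = Path(path)
    rows = [
        {
            "species": s,
            "genus": rec.genus or "",
            "subfamily": rec.subfamily or "",
            "family": rec.family,
            "order": rec.order or "",
        }
        for s, rec in sorted(tax.records.items())
    ]
    pd.DataFrame(rows, columns=["species", "genus", "subfamily", "family", "order"]).to_csv(
        path, sep=sep, index=False
    )
    return path


def write_compound_table(cat: CompoundCatalog, path, sep: str = "\t") -> Path:
    path = Path(path)
    rows = [
        {"plant": plant, "compound": c}
        for plant, compounds in sorted(cat.items())
        for c in sorted(compounds)
    ]
    pd.DataFrame(rows, columns=["plant", "compound"]).to_csv(path, sep=sep, index=False)
    return path


def export_network(
    net: PlantHerbivoreNetwork,
    path,
    fmt: str = "edgelist",
    insect_tax: Optional[TaxonomyMap] = None,
    plant_tax: Optional[TaxonomyMap] = None,
) -> Path:
    """Export as a two-column edge list or GraphML with taxonomy attributes.

    Re-reading an exported edge list with :func:`read_interaction_table`
    reproduces the edge set exactly.
    """
    path = Path(path)
    if fmt == "edgelist":
        return write_interaction_table(net, path)
    if fmt == "graphml":
        g = nx.Graph()
        for s in sorted(net.insects):
            attrs = {"side": "insect"}
            if insect_tax is not None and s in insect_tax:
                rec = insect_tax.records[s]
                attrs["family"] = rec.family
                if rec.subfamily:
                    attrs["subfamily"] = rec.subfamily
            g.add_node(s, **attrs)
        for s in sorted(net.plants):
            attrs = {"side": "plant"}
            if plant_tax is not None and s in plant_tax:
                attrs["family"] = plant_tax.records[s].family
            g.add_node(s, **attrs)
        g.add_edges_from(sorted(net.edges))
        nx.write_graphml(g, path)
        return path
    raise ValueError(f"unknown export format {fmt!r}; expected 'edgelist' or 'graphml'")
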