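"""Chemistry-aware statistics for the feed-on-compound hypothesis.

Three families of measures:

* the food-pairing statistic N_s(k) — the mean number of compounds shared
  over all unordered pairs of a butterfly's host plants — and its Z-test
  against the degree-preserving null;
* the per-plant compound-contribution coefficient χ_i — observed minus
  expected average compound overlap between plant i and the other hosts of
  its herbivores, positive when plant i contributes to compound-driven
  host selection;
* the enrichment screen for "common specific" compounds — per compound, a
  2x2 Fisher's exact test (clade vs non-clade x compound present vs
  absent) with Cramér's V as effect size.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CompoundCatalog, PlantHerbivoreNetwork, SpeciesId, TaxonomyMap
from .null_models import NullModelConfig, ZScoreResult, null_distribution, zscore

log = logging.getLogger(__name__)

__all__ = [
    "FoodPairingResult",
    "ChiResult",
    "EnrichmentRow",
    "InsufficientHostsError",
    "shared_compound_count",
    "food_pairing_ns",
    "food_pairing_table",
    "mean_food_pairing",
    "feed_on_compound_test",
    "compound_contribution_chi",
    "chi_degree_profile",
    "fisher_cramers_v",
    "enrichment",
    "common_vs_common_specific",
]


class InsufficientHostsError(ValueError):
    """A butterfly has fewer than two compound-annotated hosts: N_s undefined."""


@dataclass(frozen=True)
class FoodPairingResult:
    butterfly: SpeciesId
    n_hosts: int
    n_s: float


@dataclass(frozen=True)
class ChiResult:
    """Compound contribution of one plant species."""

    plant: SpeciesId
    chi: float
    f_i: int          # herbivore count (plant degree)
    t1: float         # observed mean overlap via the plant's herbivores
    t2: float         # expected mean overlap under no host selectivity
    s_i: float        # mean host count over the plant's herbivores (reported only)
    n_compounds: int


@dataclass(frozen=True)
class EnrichmentRow:
    compound: str
    clade: str
    level: str
    a: int            # clade observations with the compound
    b: int            # clade observations without it
    c: int            # non-clade observations with it
    d: int            # non-clade observations without it
    p: float
    cramers_v: float
    direction: str    # "enriched" | "depleted"
    passes: bool


def shared_compound_count(a: SpeciesId, b: SpeciesId, cat: CompoundCatalog) -> int:
    """|C_a ∩ C_b|: number of compounds common to plants a and b."""
    return cat.shared(a, b)


# ---------------------------------------------------------------------------
# food pairing
# ---------------------------------------------------------------------------

def _eligible_hosts(net: PlantHerbivoreNetwork, cat: CompoundCatalog, butterfly: SpeciesId):
    return sorted(p for p in net.hosts_of(butterfly) if cat.n_compounds(p) > 0)


def food_pairing_ns(
    net: PlantHerbivoreNetwork, cat: CompoundCatalog, butterfly: SpeciesId
) -> FoodPairingResult:
    """N_s(k): mean compound overlap over unordered pairs of k's hosts.

    Only hosts with at least one compound count; fewer than two such hosts
    raises :class:`InsufficientHostsError` (batch callers exclude, not fail).
    """
    hosts = _eligible_hosts(net, cat, butterfly)
    n = len(hosts)
    if n < 2:
        raise InsufficientHostsError(
            f"{butterfly!r} has {n} compound-annotated host(s); N_s needs >= 2"
        )
    total = sum(cat.shared(a, b) for a, b in itertools.combinations(hosts, 2))
    return FoodPairingResult(butterfly, n, 2.0 * total / (n * (n - 1)))


def food_pairing_table(
    net: PlantHerbivoreNetwork, cat: CompoundCatalog
) -> tuple[pd.DataFrame, int]:
    """Per-butterfly N_s table plus the count of excluded species."""
    rows, excluded = [], 0
    for b in sorted(net.insects):
        try:
            r = food_pairing_ns(net, cat, b)
        except InsufficientHostsError:
            excluded += 1
            continue
        rows.append({"butterfly": r.butterfly, "n_hosts": r.n_hosts, "n_s": r.n_s})
    return pd.DataFrame(rows, columns=["butterfly", "n_hosts", "n_s"]), excluded


def mean_food_pairing(net: PlantHerbivoreNetwork, cat: CompoundCatalog) -> float:
    """⟨N_s⟩ over species with >= 2 compound-annotated hosts."""
    total = n = 0
    for b in sorted(net.insects):
        try:
            total += food_pairing_ns(net, cat, b).n_s
        except InsufficientHostsError:
            continue
        n += 1
    if n == 0:
        raise ValueError("no butterfly with >= 2 compound-annotated hosts")
    return total / n


def _clade_mean_ns(
    net: PlantHerbivoreNetwork, cat: CompoundCatalog, members: set[SpeciesId]
) -> float:
    vals = []
    for b in sorted(members):
        try:
            vals.append(food_pairing_ns(net, cat, b).n_s)
        except InsufficientHostsError:
            continue
    return float(np.mean(vals)) if vals else math.nan


def feed_on_compound_test(
    net: PlantHerbivoreNetwork,
    cat: CompoundCatalog,
    config: NullModelConfig,
    insect_tax: Optional[TaxonomyMap] = None,
    levels: Sequence[str] = ("family", "subfamily"),
) -> tuple[ZScoreResult, dict[tuple[str, str], ZScoreResult]]:
    """Test the feed-on-compound hypothesis against the null model.

    Positive global z: hosts share more compounds than degree-matched
    chance.  Per-clade Z uses the clade members' mean N_s; all statistics
    share one replicate stream.
    """
    cats: list[tuple[str, str, set[SpeciesId]]] = []
    if insect_tax is not None:
        for level in levels:
            taxa = sorted({t for s in net.insects if (t := insect_tax.level(s, level)) is not None})
            for t in taxa:
                cats.append((level, t, insect_tax.members(t, level, net.insects)))

    def stat(rep: PlantHerbivoreNetwork) -> np.ndarray:
        out = [mean_food_pairing(rep, cat)]
        out.extend(_clade_mean_ns(rep, cat, members) for _, _, members in cats)
        return np.asarray(out)

    observed = stat(net)
    nulls = null_distribution(net, stat, config).reshape(config.replicates, -1)
    global_result = zscore(observed[0], nulls[:, 0])
    per_clade = {}
    for k, (level, taxon, _) in enumerate(cats):
        col = nulls[:, k + 1]
        if np.isnan(observed[k + 1]) or np.isnan(col).any():
            per_clade[(level, taxon)] = ZScoreResult(
                observed[k + 1], math.nan, math.nan, None, config.replicates, True
            )
        else:
            per_clade[(level, taxon)] = zscore(observed[k + 1], col)
    return global_result, per_clade


# ---------------------------------------------------------------------------
# compound contribution χ
# ---------------------------------------------------------------------------

def compound_contribution_chi(
    net: PlantHerbivoreNetwork, cat: CompoundCatalog, plant: SpeciesId
) -> ChiResult:
    """χ_i = T1 − T2 for plant i.

    T1 averages, over i's herbivores k with at least one other host, the
    mean overlap |C_i ∩ C_j| across k's other hosts j; T2 is the same mean
    over every other plant in the network — the no-selectivity expectation.
    Complete-bipartite feeding therefore gives χ = 0 exactly, as does a
    plant with no compounds.
    """
    herbs = net.herbivores_of(plant)
    if not herbs:
        raise ValueError(f"plant {plant!r} has no herbivore; chi undefined")
    plants = sorted(net.plants)
    if len(plants) < 2:
        raise ValueError("chi needs at least 2 plants in the network")

    t1_terms = []
    host_counts = []
    for k in sorted(herbs):
        hosts = net.hosts_of(k)
        host_counts.append(len(hosts))
        others = [j for j in hosts if j != plant]
        if not others:
            continue  # single-host herbivore: no pairing information
        t1_terms.append(sum(cat.shared(plant, j) for j in others) / len(others))
    t1 = float(np.mean(t1_terms)) if t1_terms else 0.0
    t2 = sum(cat.shared(plant, j) for j in plants if j != plant) / (len(plants) - 1)
    return ChiResult(
        plant=plant,
        chi=t1 - t2,
        f_i=len(herbs),
        t1=t1,
        t2=float(t2),
        s_i=float(np.mean(host_counts)),
        n_compounds=cat.n_compounds(plant),
    )


def chi_degree_profile(
    net: PlantHerbivoreNetwork,
    cat: CompoundCatalog,
    plant_tax: Optional[TaxonomyMap] = None,
) -> tuple[pd.DataFrame, float, float]:
    """Per-plant (chi, degree, average neighbour degree) with Spearman r.

    Returns (table, spearman_rho, spearman_p); the correlation of chi vs
    degree is NaN-suppressed when there are fewer than 3 plants or chi has
    zero variance.
    """
    from .family_networks import average_neighbour_degree

    rows = []
    for p in sorted(net.plants):
        if not net.herbivores_of(p):
            continue
        r = compound_contribution_chi(net, cat, p)
        row = {
            "plant": p,
            "chi": r.chi,
            "f_i": r.f_i,
            "degree": r.f_i,
            "n_compounds": r.n_compounds,
        }
        if plant_tax is not None:
            row["avg_neighbour_degree"] = average_neighbour_degree(net, plant_tax, p)
            row["family"] = plant_tax.family(p)
        rows.append(row)
    table = pd.DataFrame(rows)
    rho = pval = math.nan
    if len(table) >= 3 and table["chi"].nunique() > 1 and table["degree"].nunique() > 1:
        rho, pval = stats.spearmanr(table["chi"], table["degree"])
        rho, pval = float(rho), float(pval)
    else:
        log.info("chi-degree Spearman correlation suppressed (n=%d or zero variance)", len(table))
    return table, rho, pval


# ---------------------------------------------------------------------------
# enrichment screen
# ---------------------------------------------------------------------------

def fisher_cramers_v(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact p and Cramér's V for a 2x2 table.

    V = sqrt(chi2/n) with the uncorrected Pearson chi-square; V = 0 when a
    margin is empty (the table carries no association information).
    """
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return float(p), 0.0
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(p), math.sqrt(chi2 / n)


def enrichment(
    net: PlantHerbivoreNetwork,
    cat: CompoundCatalog,
    insect_tax: TaxonomyMap,
    clade: str,
    level: str = "family",
    unit: str = "relationship",
    p_threshold: float = 1e-6,
    v_threshold: float = 0.0,
    bh_correction: bool = False,
) -> list[EnrichmentRow]:
    """Screen compounds for specificity to a clade's host plants.

    Observation unit ``relationship`` counts every plant-herbivore edge
    (rows of the 2x2: clade vs non-clade edges; columns: the edge's plant
    carries the compound or not).  Unit ``plant`` counts each network plant
    once (clade row = plants hosting at least one clade member); edge rows
    are not independent, which is why the plant unit exists as an
    alternative.  Candidates pass at a fixed p threshold (optionally after
    Benjamini-Hochberg adjustment) and a minimum Cramér's V.
    """
    if unit not in ("relationship", "plant"):
        raise ValueError(f"unit must be 'relationship' or 'plant', got {unit!r}")
    members = insect_tax.members(clade, level, net.insects)
    if not members:
        raise LookupError(f"clade {clade!r} ({level}) has no species in the network")
    if unit == "relationship":
        log.info("enrichment unit 'relationship': rows are edges and are not independent")
        obs = [(i in members, p) for i, p in net.edges]
    else:
        obs = [
            (len(net.herbivores_of(p) & members) > 0, p)
            for p in net.plants
            if net.herbivores_of(p)
        ]
    n_clade = sum(1 for inc, _ in obs if inc)
    n_other = len(obs) - n_clade
    if n_clade == 0 or n_other == 0:
        raise ValueError(f"clade {clade!r} covers all or none of the observations")

    compounds = sorted({c for _, p in obs for c in cat.compounds_of(p)})
    rows = []
    for compound in compounds:
        a = sum(1 for inc, p in obs if inc and compound in cat.compounds_of(p))
        c = sum(1 for inc, p in obs if not inc and compound in cat.compounds_of(p))
        b, d = n_clade - a, n_other - c
        p_val, v = fisher_cramers_v(a, b, c, d)
        direction = "enriched" if a * n_other >= c * n_clade else "depleted"
        rows.append(EnrichmentRow(compound, clade, level, a, b, c, d, p_val, v, direction, False))

    if bh_correction and rows:
        from statsmodels.stats.multitest import multipletests
        reject, p_adj, _, _ = multipletests([r.p for r in rows], alpha=p_threshold, method="fdr_bh")
        passes = [bool(rej) and r.cramers_v >= v_threshold for rej, r in zip(reject, rows)]
    else:
        passes = [r.p < p_threshold and r.cramers_v >= v_threshold for r in rows]
    rows = [
        EnrichmentRow(r.compound, r.clade, r.level, r.a, r.b, r.c, r.d, r.p, r.cramers_v,
                      r.direction, ok)
        for r, ok in zip(rows, passes)
    ]
    rows.sort(key=lambda r: (-r.cramers_v, r.p, r.compound))
    return rows


def common_vs_common_specific(
    cat: CompoundCatalog,
    host_set: set[SpeciesId],
    background_set: set[SpeciesId],
) -> dict[str, set[str]]:
    """Partition compounds into common / common-specific / other.

    A compound present in every plant of both sets is *common* (likely a
    general survival metabolite); one present in every host plant and
    absent from every background plant is *common specific* — a candidate
    attractant for the herbivores of the host set and repellent for others.
    """
    if not host_set or not background_set:
        raise ValueError("host_set and background_set must be non-empty")
    if host_set & background_set:
        raise ValueError(f"host and background sets overlap: {sorted(host_set & background_set)}")
    host_sets = [cat.compounds_of(p) for p in host_set]
    back_sets = [cat.compounds_of(p) for p in background_set]
    in_all_hosts = frozenset.intersection(*host_sets)
    in_all_backs = frozenset.intersection(*back_sets)
    in_any_back = frozenset().union(*back_sets)
    universe = frozenset().union(*host_sets, in_any_back)
    common = set(in_all_hosts & in_all_backs)
    common_specific = set(in_all_hosts - in_any_back)
    other = set(universe) - common - common_specific
    return {"common": common, "common_specific": common_specific, "other": other}
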