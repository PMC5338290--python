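"""Taxonomy-aggregated network statistics.

Covers the family-level interaction count matrix W_ij and its null-model
Z-scores (attraction/avoidance patterns between insect and plant families),
the family-based evenness index used to test the feed-on-family hypothesis,
neighbour-degree profiles, and similarity of ecozone family compositions.

The evenness of insect category i (a species, subfamily or family) over
plant families is a Pielou-style normalized Shannon entropy:

    E(i) = − Σ_j (N_ij / S_i) · ln(N_ij / S_i) / ln |m_f|

where S_i is the number of (family-resolvable) host plants of category i,
N_ij the number of those hosts in plant family j, and m_f the set of plant
families appearing in the whole network.  E = 0 when all hosts fall in one
family; E = 1 when they spread exactly uniformly over all |m_f| families.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import PlantHerbivoreNetwork, SpeciesId, TaxonomyMap
from .null_models import NullModelConfig, ZScoreResult, null_distribution, zscore

log = logging.getLogger(__name__)

__all__ = [
    "EvennessResult",
    "interaction_counts",
    "family_zscores",
    "zscore_matrix_to_table",
    "evenness",
    "average_evenness",
    "evenness_test",
    "average_neighbour_degree",
    "ecozone_similarity",
]


@dataclass(frozen=True)
class EvennessResult:
    """Family-based evenness of one insect category."""

    category: str
    level: str
    s_hosts: int               # S_i: family-resolvable host plants
    evenness: float            # E in [0, 1]
    n_families_used: int       # plant families among the hosts
    n_network_families: int    # |m_f| for the whole network


# ---------------------------------------------------------------------------
# interaction counts and Z-scores
# ---------------------------------------------------------------------------

def _resolved_edge_taxa(
    net: PlantHerbivoreNetwork,
    insect_tax: TaxonomyMap,
    plant_tax: TaxonomyMap,
    insect_level: str,
    plant_level: str,
):
    """Map each edge to (insect taxon, plant taxon); unresolvable edges dropped."""
    pairs = []
    dropped = 0
    for i, p in net.edges:
        ti = insect_tax.level(i, insect_level)
        tp = plant_tax.level(p, plant_level)
        if ti is None or tp is None:
            dropped += 1
            continue
        pairs.append((ti, tp))
    if dropped:
        log.info("dropped %d edges unresolvable at (%s, %s)", dropped, insect_level, plant_level)
    return pairs


def interaction_counts(
    net: PlantHerbivoreNetwork,
    insect_tax: TaxonomyMap,
    plant_tax: TaxonomyMap,
    insect_level: str = "family",
    plant_level: str = "family",
) -> pd.DataFrame:
    """W_ij: number of edges between insect taxon i and plant taxon j."""
    pairs = _resolved_edge_taxa(net, insect_tax, plant_tax, insect_level, plant_level)
    counts = Counter(pairs)
    rows = sorted({t for t, _ in pairs}) or []
    cols = sorted({t for _, t in pairs}) or []
    W = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (ti, tp), n in counts.items():
        W.loc[ti, tp] = n
    return W


def family_zscores(
    net: PlantHerbivoreNetwork,
    insect_tax: TaxonomyMap,
    plant_tax: TaxonomyMap,
    config: NullModelConfig,
    insect_level: str = "family",
    plant_level: str = "family",
) -> dict[tuple[str, str], ZScoreResult]:
    """Z-score every W_ij cell against the null model.

    Positive z: the insect taxon feeds on the plant family more than
    degree-matched chance (attraction); negative z: less (avoidance).
    Degenerate cells (constant null) are flagged, not dropped.
    """
    W = interaction_counts(net, insect_tax, plant_tax, insect_level, plant_level)
    rows, cols = list(W.index), list(W.columns)
    if not rows or not cols:
        return {}

    def stat(rep: PlantHerbivoreNetwork) -> np.ndarray:
        w = interaction_counts(rep, insect_tax, plant_tax, insect_level, plant_level)
        return w.reindex(index=rows, columns=cols, fill_value=0).to_numpy(dtype=float).ravel()

    nulls = null_distribution(net, stat, config)
    observed = W.to_numpy(dtype=float).ravel()
    out: dict[tuple[str, str], ZScoreResult] = {}
    for k, (ti, tp) in enumerate(itertools.product(rows, cols)):
        out[(ti, tp)] = zscore(observed[k], nulls[:, k])
    return out


def zscore_matrix_to_table(results: dict[tuple[str, str], ZScoreResult]) -> pd.DataFrame:
    """Long-format table of per-cell Z-scores (degenerate cells print NA)."""
    rows = []
    for (ti, tp), r in sorted(results.items()):
        rows.append({
            "insect_taxon": ti,
            "plant_family": tp,
            "W": r.observed,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "z": r.z_or_nan(),
            "degenerate": r.degenerate,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evenness
# ---------------------------------------------------------------------------

def network_plant_families(net: PlantHerbivoreNetwork, plant_tax: TaxonomyMap) -> set[str]:
    """m_f: plant families appearing in the whole network."""
    return {f for p in net.plants if (f := plant_tax.family(p)) is not None}


def _evenness_from_counts(family_counts: Counter, n_network_families: int) -> float:
    s = sum(family_counts.values())
    if s == 0:
        raise ValueError("no family-resolvable hosts")
    if len(family_counts) <= 1 or n_network_families <= 1:
        return 0.0
    h = -sum((n / s) * math.log(n / s) for n in family_counts.values() if n > 0)
    return h / math.log(n_network_families)


def evenness(
    net: PlantHerbivoreNetwork,
    plant_tax: TaxonomyMap,
    category: str,
    level: str = "species",
    insect_tax: Optional[TaxonomyMap] = None,
    _m_f_size: Optional[int] = None,
) -> EvennessResult:
    """Family-based evenness of one insect category.

    At levels above species the category's hosts are the union of its
    member species' host plants (each distinct plant counted once).
    """
    if level == "species":
        members = {category} if category in net.insects else set()
    else:
        if insect_tax is None:
            raise ValueError(f"insect taxonomy required for level {level!r}")
        members = insect_tax.members(category, level, net.insects)
    hosts: set[SpeciesId] = set()
    for m in members:
        hosts |= net.hosts_of(m)
    fams = Counter(f for p in hosts if (f := plant_tax.family(p)) is not None)
    if not fams:
        raise LookupError(f"category {category!r} ({level}) has no family-resolvable host in the network")
    n_net_fams = _m_f_size if _m_f_size is not None else len(network_plant_families(net, plant_tax))
    return EvennessResult(
        category=category,
        level=level,
        s_hosts=sum(fams.values()),
        evenness=_evenness_from_counts(fams, n_net_fams),
        n_families_used=len(fams),
        n_network_families=n_net_fams,
    )


def average_evenness(net: PlantHerbivoreNetwork, plant_tax: TaxonomyMap) -> float:
    """Unweighted mean of species-level evenness over insect species.

    Species without any family-resolvable host are skipped.
    """
    m_f = len(network_plant_families(net, plant_tax))
    vals = []
    for s in sorted(net.insects):
        fams = Counter(f for p in net.hosts_of(s) if (f := plant_tax.family(p)) is not None)
        if fams:
            vals.append(_evenness_from_counts(fams, m_f))
    if not vals:
        raise ValueError("no insect species with family-resolvable hosts")
    return float(np.mean(vals))


def _category_list(
    net: PlantHerbivoreNetwork, insect_tax: TaxonomyMap, levels: Sequence[str]
) -> list[tuple[str, str]]:
    cats = []
    for level in levels:
        taxa = sorted({t for s in net.insects if (t := insect_tax.level(s, level)) is not None})
        cats.extend((level, t) for t in taxa)
    return cats


def evenness_test(
    net: PlantHerbivoreNetwork,
    plant_tax: TaxonomyMap,
    config: NullModelConfig,
    insect_tax: Optional[TaxonomyMap] = None,
    levels: Sequence[str] = ("family", "subfamily"),
) -> tuple[ZScoreResult, dict[tuple[str, str], ZScoreResult]]:
    """Test the feed-on-family hypothesis against the null model.

    Returns the global Z for the across-species mean evenness ⟨E⟩ plus one
    Z per insect category at each requested level (category evenness of the
    pooled hosts).  Negative z means feeding is more family-selective than
    the degree-preserving null.  All statistics share one replicate stream.
    """
    m_f = len(network_plant_families(net, plant_tax))
    cats = _category_list(net, insect_tax, levels) if insect_tax is not None else []

    def stat(rep: PlantHerbivoreNetwork) -> np.ndarray:
        out = [average_evenness(rep, plant_tax)]
        for level, taxon in cats:
            out.append(
                evenness(rep, plant_tax, taxon, level, insect_tax, _m_f_size=m_f).evenness
            )
        return np.asarray(out)

    observed = stat(net)
    nulls = null_distribution(net, stat, config)
    nulls = nulls.reshape(config.replicates, -1)
    global_result = zscore(observed[0], nulls[:, 0])
    per_cat = {
        cats[k]: zscore(observed[k + 1], nulls[:, k + 1]) for k in range(len(cats))
    }
    return global_result, per_cat


# ---------------------------------------------------------------------------
# neighbour degree and ecozone similarity
# ---------------------------------------------------------------------------

def average_neighbour_degree(
    net: PlantHerbivoreNetwork, plant_tax: TaxonomyMap, plant: SpeciesId
) -> float:
    """Mean number of distinct host-plant families used by a plant's herbivores."""
    herbs = net.herbivores_of(plant)
    if not herbs:
        raise ValueError(f"plant {plant!r} has no herbivore in the network")
    counts = []
    for k in herbs:
        fams = {f for p in net.hosts_of(k) if (f := plant_tax.family(p)) is not None}
        counts.append(len(fams))
    return float(np.mean(counts))


def ecozone_similarity(composition: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between ecozone family compositions.

    ``composition`` has one row per insect family and one column per
    ecozone (non-negative counts).  Each column is first converted to
    relative proportions, so the similarity is scale-invariant.
    """
    comp = composition.astype(float)
    if comp.shape[0] < 2 or comp.shape[1] < 2:
        raise ValueError("need at least 2 families and 2 ecozones")
    if (comp.to_numpy() < 0).any():
        raise ValueError("composition counts must be non-negative")
    totals = comp.sum(axis=0)
    zero = [c for c in comp.columns if totals[c] == 0]
    if zero:
        raise ValueError(f"ecozone column(s) with zero total: {zero}")
    props = comp / totals
    r = np.corrcoef(props.to_numpy().T)
    return pd.DataFrame(r, index=comp.columns, columns=comp.columns)
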