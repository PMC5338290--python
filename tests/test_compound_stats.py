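"""Food pairing, compound contribution, and the enrichment screen."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phytophagnet.compound_stats import (
    InsufficientHostsError,
    chi_degree_profile,
    common_vs_common_specific,
    compound_contribution_chi,
    enrichment,
    feed_on_compound_test,
    fisher_cramers_v,
    food_pairing_ns,
    food_pairing_table,
    shared_compound_count,
)
from phytophagnet.model import CompoundCatalog, PlantHerbivoreNetwork
from phytophagnet.null_models import NullModelConfig
from tests.conftest import small_generator_config


def _star_net(hosts):
    return PlantHerbivoreNetwork([("Bug one", p) for p in hosts])


class TestSharedCompounds:
    def test_single_overlap(self):
        cat = CompoundCatalog({"Plant a": {"c1", "c2"}, "Plant b": {"c2", "c3"}})
        assert shared_compound_count("Plant a", "Plant b", cat) == 1
        assert shared_compound_count("Plant b", "Plant a", cat) == 1

    def test_self_overlap_is_set_size(self):
        cat = CompoundCatalog({"Plant a": {"c1", "c2", "c3"}})
        assert shared_compound_count("Plant a", "Plant a", cat) == 3

    def test_disjoint_and_unknown(self):
        cat = CompoundCatalog({"Plant a": {"c1"}, "Plant b": {"c2"}})
        assert shared_compound_count("Plant a", "Plant b", cat) == 0
        assert shared_compound_count("Plant a", "Plant zzz", cat) == 0


class TestFoodPairing:
    def test_single_pair(self):
        cat = CompoundCatalog({"Plant a": {"x", "y"}, "Plant b": {"y", "z"}})
        r = food_pairing_ns(_star_net(["Plant a", "Plant b"]), cat, "Bug one")
        assert r.n_s == 1.0 and r.n_hosts == 2

    def test_three_hosts_enumeration(self):
        cat = CompoundCatalog({
            "Plant a": {"x", "y"}, "Plant b": {"y", "z"}, "Plant c": {"w"},
        })
        r = food_pairing_ns(_star_net(["Plant a", "Plant b", "Plant c"]), cat, "Bug one")
        assert r.n_s == pytest.approx(1 / 3)

    def test_identical_sets_give_set_size(self):
        cat = CompoundCatalog({f"Plant p{k}": {"a", "b", "c"} for k in range(4)})
        r = food_pairing_ns(_star_net([f"Plant p{k}" for k in range(4)]), cat, "Bug one")
        assert r.n_s == 3.0

    def test_too_few_annotated_hosts(self):
        cat = CompoundCatalog({"Plant a": {"x"}})
        with pytest.raises(InsufficientHostsError):
            food_pairing_ns(_star_net(["Plant a", "Plant b"]), cat, "Bug one")

    def test_batch_excludes_not_fails(self):
        cat = CompoundCatalog({"Plant a": {"x"}, "Plant b": {"x"}})
        net = PlantHerbivoreNetwork([
            ("Bug ok", "Plant a"), ("Bug ok", "Plant b"), ("Bug thin", "Plant a"),
        ])
        table, excluded = food_pairing_table(net, cat)
        assert list(table["butterfly"]) == ["Bug ok"] and excluded == 1

    @settings(deadline=None, max_examples=30)
    @given(
        sets=st.lists(
            st.sets(st.integers(min_value=0, max_value=8), min_size=1, max_size=5),
            min_size=2, max_size=5,
        ),
        offset=st.integers(min_value=1, max_value=50),
    )
    def test_invariance_under_relabeling_and_unused_compounds(self, sets, offset):
        """N_s sees only pairwise overlaps, never compound identities."""
        hosts = [f"Plant p{k}" for k in range(len(sets))]
        cat_a = CompoundCatalog({h: {f"c{v}" for v in s} for h, s in zip(hosts, sets)})
        cat_b = CompoundCatalog({h: {f"c{v + offset}" for v in s} for h, s in zip(hosts, sets)})
        cat_b.add("Plant unused", {"c999999"})
        net = _star_net(hosts)
        a = food_pairing_ns(net, cat_a, "Bug one").n_s
        b = food_pairing_ns(net, cat_b, "Bug one").n_s
        assert a == pytest.approx(b)


class TestFeedOnCompoundTest:
    def test_compound_driven_network_positive(self):
        from phytophagnet.model import restrict_to_compound_annotated
        from phytophagnet.synthetic import generate_all

        b = generate_all(small_generator_config(seed=21, lambda_family=0.0, beta_compound=4.0))
        net = restrict_to_compound_annotated(b.network, b.catalog)
        g, per_clade = feed_on_compound_test(
            net, b.catalog, NullModelConfig(replicates=200, seed=4), b.insect_taxonomy
        )
        assert g.z > 3
        assert per_clade

    def test_same_seed_identical(self, small_bundle):
        b = small_bundle
        cfg = NullModelConfig(replicates=50, seed=12)
        g1, _ = feed_on_compound_test(b.network, b.catalog, cfg)
        g2, _ = feed_on_compound_test(b.network, b.catalog, cfg)
        assert g1 == g2


class TestChi:
    def test_complete_bipartite_zero(self):
        plants = [f"Plant p{k}" for k in range(4)]
        net = PlantHerbivoreNetwork([(f"Bug b{i}", p) for i in range(3) for p in plants])
        cat = CompoundCatalog({p: {f"c{k}", "shared"} for k, p in enumerate(plants)})
        for p in plants:
            assert compound_contribution_chi(net, cat, p).chi == pytest.approx(0.0, abs=1e-12)

    def test_no_compound_plant_zero(self, small_bundle):
        net = small_bundle.network
        cat = CompoundCatalog({p: set() for p in net.plants})
        plant = sorted(p for p in net.plants if net.herbivores_of(p))[0]
        assert compound_contribution_chi(net, cat, plant).chi == 0.0

    def test_isolated_plant_rejected(self):
        net = PlantHerbivoreNetwork([("Bug b", "Plant a")], plants=["Plant a", "Plant b"])
        with pytest.raises(ValueError):
            compound_contribution_chi(net, CompoundCatalog(), "Plant b")

    def test_planted_compound_plants_have_higher_chi(self):
        from phytophagnet.model import restrict_to_compound_annotated
        from phytophagnet.synthetic import generate_all

        chis_carrier, chis_other = [], []
        for seed in range(5):
            b = generate_all(small_generator_config(
                seed=seed, lambda_family=0.0, beta_compound=4.0,
                clade_compound_plant_fraction=0.6,
            ))
            net = restrict_to_compound_annotated(b.network, b.catalog)
            planted = {c for comps in b.truth.clade_compounds.values() for c in comps}
            for p in net.plants:
                if not net.herbivores_of(p):
                    continue
                chi = compound_contribution_chi(net, b.catalog, p).chi
                (chis_carrier if planted & b.catalog.compounds_of(p) else chis_other).append(chi)
        assert np.mean(chis_carrier) > np.mean(chis_other)

    def test_profile_zero_variance_flagged(self):
        plants = [f"Plant p{k}" for k in range(4)]
        net = PlantHerbivoreNetwork([(f"Bug b{i}", p) for i in range(2) for p in plants])
        cat = CompoundCatalog({p: {"c"} for p in plants})
        table, rho, pval = chi_degree_profile(net, cat)
        assert len(table) == 4 and math.isnan(rho) and math.isnan(pval)

    def test_profile_invariant_under_plant_relabeling(self, small_bundle):
        b = small_bundle
        net = b.network.drop_isolated()
        _, rho1, _ = chi_degree_profile(net, b.catalog)
        renamed = {p: f"Zz plant{k}" for k, p in enumerate(sorted(net.plants))}
        net2 = PlantHerbivoreNetwork([(i, renamed[p]) for i, p in net.edges])
        cat2 = CompoundCatalog(
            {renamed[p]: set(c) for p, c in b.catalog.items() if p in renamed}
        )
        _, rho2, _ = chi_degree_profile(net2, cat2)
        assert rho1 == pytest.approx(rho2)


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {x: stats.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    gate = pmf[a] * (1 + 1e-7)
    return float(sum(p for p in pmf.values() if p <= gate))


class TestFisherCramersV:
    def test_perfect_association(self):
        p, v = fisher_cramers_v(10, 0, 0, 10)
        assert v == pytest.approx(1.0) and p < 1e-4

    def test_exact_independence(self):
        p, v = fisher_cramers_v(6, 3, 4, 2)  # identical row proportions
        assert v == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_enumeration_oracle_example(self):
        p, _ = fisher_cramers_v(6, 1, 2, 8)
        assert p == pytest.approx(_fisher_oracle(6, 1, 2, 8), rel=1e-9)

    def test_row_and_column_swap_invariance(self):
        base = fisher_cramers_v(6, 1, 2, 8)
        assert fisher_cramers_v(2, 8, 6, 1) == pytest.approx(base)   # row swap
        assert fisher_cramers_v(1, 6, 8, 2) == pytest.approx(base)   # column swap

    def test_empty_margin_carries_no_association(self):
        p, v = fisher_cramers_v(0, 0, 3, 5)
        assert v == 0.0 and p == pytest.approx(1.0)


class TestEnrichment:
    def test_planted_compound_is_top_candidate(self):
        from phytophagnet.model import restrict_to_compound_annotated
        from phytophagnet.synthetic import generate_all

        b = generate_all(small_generator_config(seed=33, lambda_family=0.0, beta_compound=4.0))
        net = restrict_to_compound_annotated(b.network, b.catalog)
        clade = sorted(b.truth.clade_compounds)[0]
        rows = enrichment(net, b.catalog, b.insect_taxonomy, clade, p_threshold=1e-3)
        planted = set(b.truth.clade_compounds[clade])
        background = set(b.truth.background_compounds)
        v_planted = min(r.cramers_v for r in rows if r.compound in planted)
        v_background = [r.cramers_v for r in rows if r.compound in background]
        assert all(v_planted > v for v in v_background)

    def test_contingency_margins_sum_to_sample_size(self, small_bundle):
        b = small_bundle
        clade = sorted(b.truth.clade_compounds)[0]
        rows = enrichment(b.network, b.catalog, b.insect_taxonomy, clade)
        n = b.network.n_edges
        assert all(r.a + r.b + r.c + r.d == n for r in rows)

    def test_plant_unit(self, small_bundle):
        b = small_bundle
        clade = sorted(b.truth.clade_compounds)[0]
        rows = enrichment(b.network, b.catalog, b.insect_taxonomy, clade, unit="plant")
        n_plants = sum(1 for p in b.network.plants if b.network.herbivores_of(p))
        assert all(r.a + r.b + r.c + r.d == n_plants for r in rows)

    def test_unknown_clade_rejected(self, small_bundle):
        b = small_bundle
        with pytest.raises(LookupError):
            enrichment(b.network, b.catalog, b.insect_taxonomy, "Nosuchfam")


class TestCommonVsCommonSpecific:
    def test_toy_partition(self, fig_toy):
        _, cat = fig_toy
        parts = common_vs_common_specific(
            cat, {"Plant P3", "Plant P4"}, {"Plant P1", "Plant P2"}
        )
        assert "C1" in parts["common"]
        assert "C2" in parts["common_specific"]

    def test_hosts_share_nothing(self):
        cat = CompoundCatalog({"Plant a": {"x"}, "Plant b": {"y"}, "Plant c": {"z"}})
        parts = common_vs_common_specific(cat, {"Plant a", "Plant b"}, {"Plant c"})
        assert parts["common_specific"] == set() and parts["common"] == set()

    def test_single_host_vs_single_background(self):
        cat = CompoundCatalog({"Plant a": {"x", "y"}, "Plant b": {"y", "z"}})
        parts = common_vs_common_specific(cat, {"Plant a"}, {"Plant b"})
        assert parts["common_specific"] == {"x"} and parts["common"] == {"y"}

    def test_overlapping_sets_rejected(self, fig_toy):
        _, cat = fig_toy
        with pytest.raises(ValueError):
            common_vs_common_specific(cat, {"Plant P1"}, {"Plant P1", "Plant P2"})
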