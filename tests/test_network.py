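"""Edge screening, PFN construction, modules, hubs, enrichment, traits."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from plaqueomics.matrix import IntensityMatrix
from plaqueomics.network import (
    EdgeSet,
    Module,
    build_pfn,
    detect_modules,
    find_hubs,
    module_eigengene,
    module_set_enrichment,
    module_trait_correlation,
    pairwise_pearson,
    reported_modules,
    significant_correlations,
)

from conftest import make_matrix


def euler_planarity_certificate(g: nx.Graph) -> bool:
    """Independent planarity verification: count faces of the embedding
    returned by the planarity checker and check Euler's formula
    V - E + F = 1 + C (F counted once globally, C components)."""
    ok, embedding = nx.check_planarity(g)
    if not ok:
        return False
    seen = set()
    n_faces = 0
    for v in embedding:
        for w in embedding[v]:
            if (v, w) not in seen:
                face = embedding.traverse_face(v, w, mark_half_edges=seen)
                n_faces += 1
    n_faces = max(n_faces, 1)
    c = nx.number_connected_components(g)
    v, e = g.number_of_nodes(), g.number_of_edges()
    return v - e + n_faces == 1 + c


def _edge_df(pairs_rho):
    df = pd.DataFrame(pairs_rho, columns=["protein_a", "protein_b", "rho"])
    df["q_perm"] = 0.0
    return EdgeSet(df, 0.0)


class TestPairwisePearson:
    def test_matches_pairwise_complete_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (12, 30))
        x[rng.random(x.shape) < 0.2] = np.nan
        r, n = pairwise_pearson(x, min_overlap=3)
        for i, j in itertools.combinations(range(12), 2):
            ok = np.isfinite(x[i]) & np.isfinite(x[j])
            if ok.sum() < 3:
                assert np.isnan(r[i, j])
                continue
            ref = sp_stats.pearsonr(x[i, ok], x[j, ok]).statistic
            assert r[i, j] == pytest.approx(ref, abs=1e-12)
            assert n[i, j] == ok.sum()


class TestSignificantCorrelations:
    def test_duplicated_profiles_always_retained(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(20, 1, (30, 40))
        vals[1] = vals[0]  # identical pair
        m = make_matrix(vals)
        es = significant_correlations(m, n_perm=30, seed=0)
        pair = es.edges[(es.edges["protein_a"] == "P000") &
                        (es.edges["protein_b"] == "P001")]
        assert len(pair) == 1
        assert pair["rho"].iloc[0] == pytest.approx(1.0)

    def test_null_matrix_fdr_controlled(self):
        kept_frac = []
        for seed in range(2):
            rng = np.random.default_rng(seed)
            m = make_matrix(rng.normal(20, 1, (100, 40)))
            es = significant_correlations(m, n_perm=40, fdr=0.05, seed=seed)
            kept_frac.append(len(es.edges) / (100 * 99 / 2))
        assert np.mean(kept_frac) <= 0.05 + 0.02


class TestBuildPfn:
    def test_k4_fully_kept(self):
        pairs = [(f"N{a}", f"N{b}", 0.9 - 0.01 * (a + b))
                 for a, b in itertools.combinations(range(4), 2)]
        g = build_pfn(_edge_df(pairs))
        assert g.number_of_edges() == 6

    def test_k5_drops_exactly_one(self):
        pairs = [(f"N{a}", f"N{b}", 0.9 - 0.02 * (2 * a + b))
                 for a, b in itertools.combinations(range(5), 2)]
        g = build_pfn(_edge_df(pairs))
        assert g.number_of_edges() == 9  # 3(5-2)
        (missing,) = [
            (a, b) for a, b in itertools.combinations([f"N{i}" for i in range(5)], 2)
            if not g.has_edge(a, b)
        ]
        # the dropped edge is one whose insertion would break planarity
        g.add_edge(*missing)
        assert not nx.check_planarity(g)[0]

    @pytest.mark.parametrize("seed", range(4))
    def test_random_inputs_planar_with_bound(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        pairs = [(f"N{a:02d}", f"N{b:02d}", float(rng.uniform(-1, 1)))
                 for a, b in itertools.combinations(range(n), 2)
                 if rng.random() < 0.3]
        g = build_pfn(_edge_df(pairs))
        assert g.number_of_edges() <= 3 * (g.number_of_nodes() - 2)
        assert euler_planarity_certificate(g)


class TestDetectModules:
    def test_two_cliques_give_two_modules(self):
        pairs = []
        for off in (0, 12):
            pairs += [(f"N{a + off:02d}", f"N{b + off:02d}", 0.9)
                      for a, b in itertools.combinations(range(12), 2)]
        pairs.append(("N00", "N12", 0.4))
        g = build_pfn(_edge_df(pairs))
        mods = detect_modules(g, n_null=100, seed=0)
        rep = reported_modules(mods)
        assert sorted(m.size for m in rep) == [12, 12]

    def test_small_cluster_never_reported(self):
        pairs = [(f"S{a}", f"S{b}", 0.9) for a, b in itertools.combinations(range(5), 2)]
        mods = detect_modules(build_pfn(_edge_df(pairs)), n_null=50, seed=0)
        assert reported_modules(mods) == []

    def test_deterministic_given_seed(self):
        pairs = []
        for off in (0, 12):
            pairs += [(f"N{a + off:02d}", f"N{b + off:02d}", 0.9)
                      for a, b in itertools.combinations(range(12), 2)]
        pairs.append(("N00", "N12", 0.4))
        g = build_pfn(_edge_df(pairs))
        a = detect_modules(g, n_null=50, seed=3)
        b = detect_modules(g, n_null=50, seed=3)
        assert [(m.module_id, m.members) for m in a] == \
               [(m.module_id, m.members) for m in b]


class TestFindHubs:
    def _star(self):
        g = nx.Graph()
        for i in range(11):
            g.add_edge("CENTER", f"L{i:02d}", rho=0.8, weight=0.8)
        return g

    def test_star_center_unique_hub(self):
        g = self._star()
        mod = Module("M1", None, tuple(sorted(g.nodes)), np.nan, 0)
        find_hubs(g, mod, n_null=1000, seed=0)
        assert mod.hubs == ("CENTER",)

    def test_regular_ring_no_hubs(self):
        g = nx.relabel_nodes(nx.cycle_graph(12), {i: f"R{i:02d}" for i in range(12)})
        nx.set_edge_attributes(g, 0.8, "weight")
        nx.set_edge_attributes(g, 0.8, "rho")
        mod = Module("M1", None, tuple(sorted(g.nodes)), np.nan, 0)
        find_hubs(g, mod, n_null=1000, seed=0)
        assert mod.hubs == ()


class TestModuleEnrichment:
    def test_hand_computed_running_sum(self):
        """10-protein toy ranking; members at positions 0 and 1.

        Weighted running sum rises by w_i / (w_0 + w_1) per hit and falls
        by 1/8 per miss; the maximum is reached after the second hit.
        """
        stats = pd.Series([10.0, 6.0, 5, 4, 3, 2, 1, 1, 1, 1],
                          index=[f"P{i}" for i in range(10)])
        es, p = module_set_enrichment(["P0", "P1"], stats, n_perm=200, seed=0)
        assert es == pytest.approx(1.0)  # both hits before any miss
        members = ["P1", "P3"]  # positions 1 and 3
        es2, _ = module_set_enrichment(members, stats, n_perm=200, seed=0)
        # running sum: miss(-1/8), hit(+6/10), miss(-1/8), hit(+4/10)
        expected = 6 / 10 - 1 / 8 + 4 / 10 - 1 / 8
        assert es2 == pytest.approx(expected, abs=1e-12)

    def test_top_module_minimal_p(self):
        rng = np.random.default_rng(0)
        stats = pd.Series(np.abs(rng.normal(0, 1, 300)),
                          index=[f"P{i:04d}" for i in range(300)])
        top = stats.sort_values(ascending=False).index[:12]
        es, p = module_set_enrichment(top, stats, n_perm=1000, seed=1)
        assert es == pytest.approx(1.0, abs=1e-9)
        assert p <= 2 / 1000

    def test_empty_intersection_rejected(self):
        stats = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValueError):
            module_set_enrichment(["Z"], stats)


class TestEigengeneAndTrait:
    def test_rank_one_module(self):
        rng = np.random.default_rng(2)
        profile = rng.normal(0, 1, 20)
        vals = np.vstack([5.0 * profile + 10 + i for i in range(12)])
        m = make_matrix(vals, ages=(3,))
        eg = module_eigengene(m, list(m.protein_ids))
        prof_z = (profile - profile.mean()) / profile.std(ddof=1)
        assert abs(np.corrcoef(eg, prof_z)[0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert np.corrcoef(eg, prof_z)[0, 1] > 0  # orientation rule
        assert eg.std(ddof=1) == pytest.approx(1.0)

    def test_member_order_invariance(self, qc_cohort):
        _, m, truth = qc_cohort
        members = sorted(p for p, b in truth.block_assignment.items() if b == 0
                         and p in m.values.index)
        a = module_eigengene(m, members)
        b = module_eigengene(m, members[::-1])
        assert np.allclose(a, b, atol=1e-9)

    def test_planted_plaque_module_flagged(self, qc_cohort):
        cfg, m, truth = qc_cohort
        linked = tuple(sorted(p for p, b in truth.block_assignment.items()
                              if b == 0 and p in m.values.index))
        unlinked = tuple(sorted(p for p, b in truth.block_assignment.items()
                                if b == cfg.n_blocks - 1 and p in m.values.index))
        mods = [Module("M1", None, linked, np.nan, 0),
                Module("M2", None, unlinked, np.nan, 0)]
        module_trait_correlation(mods, m)
        assert mods[0].trait_associated and mods[0].trait_r > 0.4
        assert not mods[1].trait_associated

    def test_r_cut_blocks_flagging(self, qc_cohort):
        cfg, m, truth = qc_cohort
        linked = tuple(sorted(p for p, b in truth.block_assignment.items()
                              if b == 0 and p in m.values.index))
        mods = [Module("M1", None, linked, np.nan, 0)]
        module_trait_correlation(mods, m, r_cut=0.999)
        assert mods[0].trait_q < 0.05 and not mods[0].trait_associated
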