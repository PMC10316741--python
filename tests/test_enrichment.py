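import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methtraj.enrichment import (
    PermConfig,
    bidirectional_chaos,
    chromosome_enrichment_perm,
    cross_tissue_compare,
    feature_enrichment,
    geneset_enrichment,
    hypergeom_tail,
    top_k_by_pn,
)
from methtraj.io import GeneSetCollection
from methtraj.simulate import SimConfig, simulate_dataset

from conftest import make_manifest
from oracle_helpers import fisher_upper_tail


class TestHypergeomTail:
    def test_hand_enumerated_six_outcomes(self):
        # N=4, K=2, n=2: of the 6 equally likely draws exactly one hits both
        p_up, p_lo = hypergeom_tail(4, 2, 2, 2)
        assert p_up == pytest.approx(1 / 6)
        assert p_lo == pytest.approx(1.0)

    def test_zero_observed(self):
        p_up, p_lo = hypergeom_tail(100, 10, 5, 0)
        assert p_up == pytest.approx(1.0)
        assert 0 < p_lo < 1

    def test_tail_identity(self):
        N, K, n, k = 60, 17, 22, 7
        p_up, p_lo = hypergeom_tail(N, K, n, k)
        pmf = stats.hypergeom.pmf(k, N, K, n)
        assert p_up + p_lo - pmf == pytest.approx(1.0)

    def test_impossible_count_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 3, 3, 4)


class TestChromosomePermutation:
    def test_degenerate_draw_of_whole_universe(self):
        manifest = make_manifest(
            [f"p{i}" for i in range(40)], chroms=["1"] * 20 + ["2"] * 20
        )
        ids = list(manifest.probe_ids)
        res = chromosome_enrichment_perm(ids, ids, manifest, PermConfig(n_perm=50, seed=0))
        assert (res["p_enrich"] == 1.0).all()
        assert (res["p_deplete"] == 1.0).all()

    def test_matches_hypergeometric_tail(self):
        cfg = SimConfig(seed=0, n_probes=1000)
        _, _, manifest, *_ = simulate_dataset(cfg)
        uni = list(manifest.probe_ids)
        rng = np.random.default_rng(4)
        dmps = list(rng.choice(uni, 50, replace=False))
        res = chromosome_enrichment_perm(dmps, uni, manifest, PermConfig(n_perm=10_000, seed=0))
        chrom = manifest.df["chrom"]
        for _, row in res.iterrows():
            K = int((chrom == row["category"]).sum())
            p_up, p_lo = hypergeom_tail(1000, K, 50, int(row["observed"]))
            for emp, exact in ((row["p_enrich"], p_up), (row["p_deplete"], p_lo)):
                bound = 3 * math.sqrt(exact * (1 - exact) / 10_000) + 2 / 10_000
                assert abs(emp - exact) <= bound

    def test_same_seed_bit_identical_different_seed_close(self):
        cfg = SimConfig(seed=0, n_probes=500)
        _, _, manifest, *_ = simulate_dataset(cfg)
        uni = list(manifest.probe_ids)
        dmps = uni[::10]
        a = chromosome_enrichment_perm(dmps, uni, manifest, PermConfig(n_perm=2000, seed=5))
        b = chromosome_enrichment_perm(dmps, uni, manifest, PermConfig(n_perm=2000, seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = chromosome_enrichment_perm(dmps, uni, manifest, PermConfig(n_perm=2000, seed=6))
        assert np.max(np.abs(a["p_enrich"] - c["p_enrich"])) < 0.05

    def test_pseudocount_keeps_p_positive(self):
        manifest = make_manifest(["a", "b", "c", "d"], chroms=["1", "1", "2", "2"])
        res = chromosome_enrichment_perm(
            ["a", "b"], ["a", "b", "c", "d"], manifest, PermConfig(n_perm=100, seed=0)
        )
        assert (res["p_enrich"] > 0).all()
        assert (res["p_deplete"] > 0).all()

    def test_dmp_outside_universe_rejected(self):
        manifest = make_manifest(["a", "b"])
        with pytest.raises(ValueError):
            chromosome_enrichment_perm(["z"], ["a", "b"], manifest, PermConfig(n_perm=10))


class TestFeatureEnrichment:
    def test_all_island_query_matches_exact_tail(self):
        ids = [f"p{i}" for i in range(200)]
        cgi = ["Island"] * 100 + ["OpenSea"] * 100
        manifest = make_manifest(ids, cgi=cgi)
        dmps = ids[:20]  # all Island
        res = feature_enrichment(dmps, ids, manifest, axis="cgi").set_index("category")
        expected = fisher_upper_tail(200, 100, 20, 20)
        assert res.loc["Island", "p_enrich"] == pytest.approx(expected)
        assert res.loc["Island", "observed"] == 20

    def test_cgi_axis_categories(self):
        ids = [f"p{i}" for i in range(40)]
        cgi = (["Island", "Shore", "Shelf", "OpenSea"] * 10)[:40]
        manifest = make_manifest(ids, cgi=cgi)
        res = feature_enrichment(ids[:10], ids, manifest, axis="cgi")
        assert sorted(res["category"]) == ["Island", "OpenSea", "Shelf", "Shore"]

    def test_balanced_query_shows_no_signal(self):
        ids = [f"p{i}" for i in range(200)]
        cgi = (["Island", "OpenSea"] * 100)[:200]
        manifest = make_manifest(ids, cgi=cgi)
        dmps = ids[:100]  # alternating, same 50/50 split as universe
        res = feature_enrichment(dmps, ids, manifest, axis="cgi")
        assert (res["adj_p"] > 0.05).all()
        np.testing.assert_allclose(res["odds_ratio"], 1.0, atol=0.05)

    def test_probe_counts_once_per_distinct_feature(self):
        ids = ["a", "b"]
        manifest = make_manifest(
            ids,
            genes=[("G1", "G2"), ("G3",)],
            features=[("Body", "Body"), ("TSS200",)],
        )
        res = feature_enrichment(["a"], ids, manifest, axis="feature").set_index("category")
        assert res.loc["Body", "observed"] == 1


class TestTopK:
    def test_rank_by_p_then_effect_magnitude(self):
        dmps = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c", "d", "e"],
                "contrast": "P/N",
                "delta_beta": [0.2, 0.11, 0.3, 0.2, -0.4],
                "stat": 0.0,
                "p": [0.1, 0.01, 0.02, 0.5, 0.01],
                "adj_p": 0.0,
                "call": "hyper",
            }
        )
        calls = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c", "d", "e"],
                "type": pd.array([1, 1, 1, 1, 1], dtype="Int64"),
                "group": "sHyperMethyl",
                "delta_cp": 0.2,
            }
        )
        top = top_k_by_pn(dmps, calls, type_filter=1, k=3)
        # ties at p=0.01 broken by |delta| descending: e (0.4) before b (0.11)
        assert top == ["e", "b", "c"]

    def test_k_larger_than_pool_warns_and_returns_all(self):
        dmps = pd.DataFrame(
            {
                "probe_id": ["a"],
                "contrast": "P/N",
                "delta_beta": [0.2],
                "stat": 0.0,
                "p": [0.1],
                "adj_p": 0.0,
                "call": "hyper",
            }
        )
        calls = pd.DataFrame(
            {
                "probe_id": ["a"],
                "type": pd.array([2], dtype="Int64"),
                "group": "sHyperMethyl",
                "delta_cp": 0.0,
            }
        )
        with pytest.warns(UserWarning):
            assert top_k_by_pn(dmps, calls, (1, 2), k=10) == ["a"]


class TestGenesetEnrichment:
    def test_exact_tail_on_constructed_overlap(self):
        universe = [f"G{i}" for i in range(100)]
        sets = GeneSetCollection({"s": frozenset(universe[:10])})
        query = universe[5:25]  # overlap 5
        res = geneset_enrichment(query, universe, sets)
        assert res["observed"].iloc[0] == 5
        assert res["p_enrich"].iloc[0] == pytest.approx(fisher_upper_tail(100, 10, 20, 5))

    def test_agrees_with_scipy_fisher_oracle(self):
        universe = [f"G{i}" for i in range(60)]
        rng = np.random.default_rng(3)
        sets = {
            f"s{j}": frozenset(rng.choice(universe, 15, replace=False)) for j in range(8)
        }
        query = list(rng.choice(universe, 25, replace=False))
        res = geneset_enrichment(query, universe, GeneSetCollection(sets), min_size=1)
        for _, row in res.iterrows():
            k = int(row["observed"])
            K = len(sets[row["category"]])
            table = [[k, 25 - k], [K - k, 60 - K - (25 - k)]]
            _, p = stats.fisher_exact(table, alternative="greater")
            assert row["p_enrich"] == pytest.approx(p)

    def test_no_overlap_is_uninteresting(self):
        universe = [f"G{i}" for i in range(100)]
        sets = GeneSetCollection({"s": frozenset(universe[:10])})
        res = geneset_enrichment(universe[50:60], universe, sets)
        assert res["p_enrich"].iloc[0] > 0.5

    def test_query_equal_to_set_is_extreme(self):
        universe = [f"G{i}" for i in range(100)]
        sets = GeneSetCollection(
            {"hit": frozenset(universe[:10]), "other": frozenset(universe[40:50])}
        )
        res = geneset_enrichment(universe[:10], universe, sets).set_index("category")
        assert res.loc["hit", "p_enrich"] < res.loc["other", "p_enrich"]
        assert res.loc["hit", "observed"] == 10

    def test_size_filter_and_stray_query_warning(self):
        universe = [f"G{i}" for i in range(50)]
        sets = GeneSetCollection(
            {"tiny": frozenset(universe[:2]), "ok": frozenset(universe[:12])}
        )
        with pytest.warns(UserWarning):
            res = geneset_enrichment(universe[:5] + ["MISSING"], universe, sets)
        assert res["category"].tolist() == ["ok"]


class TestChaosAndCrossTissue:
    def _enr(self, cats, adj_ps):
        return pd.DataFrame(
            {
                "category": cats,
                "observed": 1,
                "expected": 1.0,
                "p_enrich": adj_ps,
                "p_deplete": 1.0,
                "adj_p": adj_ps,
                "odds_ratio": 1.0,
            }
        )

    def test_chaos_needs_both_directions(self):
        hyper = self._enr(["a", "b"], [0.01, 0.5])
        hypo = self._enr(["a", "b"], [0.03, 0.01])
        assert bidirectional_chaos(hyper, hypo) == {"a"}

    def test_chaos_end_to_end_with_planted_sets(self):
        cfg = SimConfig(
            seed=13,
            n_probes=3000,
            planted={1: 150, 2: 150, 5: 150, 6: 150},
            planted_sets={"both_ways": (10, 10), "hyper_only": (20, 0)},
            gene_set_size=20,
            n_gene_sets=5,
        )
        bm, sheet, manifest, genesets, _, truth = simulate_dataset(cfg)
        universe = sorted(manifest.genes_for(manifest.probe_ids))
        hyper_genes = sorted(set(truth.loc[truth["type"].isin([1, 2]), "gene"]) - {""})
        hypo_genes = sorted(set(truth.loc[truth["type"].isin([5, 6]), "gene"]) - {""})
        enr_hyper = geneset_enrichment(hyper_genes, universe, genesets)
        enr_hypo = geneset_enrichment(hypo_genes, universe, genesets)
        flagged = bidirectional_chaos(enr_hyper, enr_hypo)
        assert "both_ways" in flagged
        assert "hyper_only" not in flagged

    def test_cross_tissue_classes(self):
        tables = {
            ("liver", "hyper"): self._enr(["rap1", "axon", "solo"], [0.01, 0.01, 0.01]),
            ("liver", "hypo"): self._enr(["rap1"], [0.01]),
            ("prostate", "hyper"): self._enr(["wnt"], [0.01]),
            ("prostate", "hypo"): self._enr(["axon"], [0.01]),
        }
        out = cross_tissue_compare(tables).set_index(["pathway", "tissue", "direction"])
        assert out.loc[("rap1", "liver", "hyper"), "class"] == "bidirectional-within-tissue"
        assert out.loc[("axon", "liver", "hyper"), "class"] == "different-direction-shared"
        assert out.loc[("solo", "liver", "hyper"), "class"] == "unique"
        assert out.loc[("wnt", "prostate", "hyper"), "class"] == "unique"

    def test_cross_tissue_same_direction_shared(self):
        tables = {
            ("liver", "hyper"): self._enr(["focal"], [0.01]),
            ("prostate", "hyper"): self._enr(["focal"], [0.01]),
        }
        out = cross_tissue_compare(tables)
        assert set(out["class"]) == {"same-direction-shared"}
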