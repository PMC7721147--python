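"""Hypergeometric ORA, catalog handling, and cell-type trajectory embedding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from natalaxis import syndata
from natalaxis.enrichment import (
    GeneSetCatalog,
    build_celltype_trajectory_matrix,
    embed_celltypes,
    enrichment_ratio,
    hypergeom_ora,
    hypergeom_upper_tail,
    run_class_enrichment,
)
from oracles import hypergeom_upper_tail_exact


class TestHypergeomTail:
    def test_worked_example_matches_exact_fraction(self):
        # M=20, K=5, N=4, x=3: [C(5,3)C(15,1) + C(5,4)C(15,0)] / C(20,4)
        assert hypergeom_upper_tail(3, 20, 5, 4) == pytest.approx(155 / 4845,
                                                                  rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        assert hypergeom_upper_tail(0, 30, 10, 5) == 1.0

    @settings(max_examples=300, deadline=None)
    @given(st.integers(0, 100_000))
    def test_matches_exact_enumeration_for_small_backgrounds(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(1, 26))
        K = int(rng.integers(0, M + 1))
        N = int(rng.integers(1, M + 1))
        x = int(rng.integers(0, min(K, N) + 1))
        assert hypergeom_upper_tail(x, M, K, N) == pytest.approx(
            hypergeom_upper_tail_exact(x, M, K, N), abs=1e-12)

    def test_agrees_with_scipy_survival_function(self):
        from scipy.stats import hypergeom as h
        for (x, M, K, N) in [(3, 200, 40, 25), (10, 5000, 300, 100),
                             (1, 50, 2, 3)]:
            assert hypergeom_upper_tail(x, M, K, N) == pytest.approx(
                float(h.sf(x - 1, M, K, N)), rel=1e-9)

    def test_p_non_increasing_in_x(self):
        ps = [hypergeom_upper_tail(x, 40, 12, 10) for x in range(0, 11)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestOra:
    def test_ratio_arithmetic(self):
        assert enrichment_ratio(2, 4, 5, 20) == pytest.approx(2.0)
        assert enrichment_ratio(1, 4, 5, 20) == pytest.approx(1.0)
        assert enrichment_ratio(0, 4, 5, 20) == 0.0

    def test_saturated_set_is_uninformative(self):
        bg = [f"g{i}" for i in range(30)]
        res = hypergeom_ora(bg[:10], bg, bg)
        assert res.x == res.N and res.p == 1.0
        assert res.enrichment_ratio == pytest.approx(1.0)

    def test_duplicates_and_order_do_not_matter(self):
        bg = [f"g{i}" for i in range(40)]
        s = bg[:8]
        q = bg[4:14]
        r1 = hypergeom_ora(q, s, bg)
        r2 = hypergeom_ora(q[::-1] + q[:3], s * 2, bg[::-1])
        assert (r1.x, r1.N, r1.K, r1.M, r1.p) == (r2.x, r2.N, r2.K, r2.M, r2.p)

    def test_query_outside_background_dropped(self):
        bg = [f"g{i}" for i in range(20)]
        res = hypergeom_ora(bg[:5] + ["not_there"], bg[:10], bg)
        assert res.N == 5

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_ora(["a"], ["a"], [])


class TestCatalog:
    def test_unique_variant_sets_are_pairwise_disjoint(self, universe_truth):
        cat, _ = syndata.generate_geneset_catalog(
            universe_truth, markers_per_class=20, overlap_rate=0.3, seed=2)
        uniq = cat.unique_variant
        names = list(uniq)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not (set(uniq[a]) & set(uniq[b]))

    def test_gmt_roundtrip(self, universe_truth, tmp_path):
        cat, _ = syndata.generate_geneset_catalog(
            universe_truth, markers_per_class=10, seed=3)
        path = tmp_path / "cat.gmt"
        cat.to_gmt(path)
        back = GeneSetCatalog.from_gmt(path)
        assert back.sets == cat.sets

    def test_universe_membership_enforced(self):
        with pytest.raises(ValueError):
            GeneSetCatalog(sets={"a": ["g1", "g99"]}, universe=["g1", "g2"])

    def test_timing_sets_pool_by_metadata(self, universe_truth):
        cat, _ = syndata.generate_geneset_catalog(
            universe_truth, markers_per_class=10, seed=4)
        timing = cat.timing_sets()
        precursors = {"OPC", "intermediate_progenitor", "radial_glia"}
        expected = set().union(*(cat.sets[c] for c in precursors))
        assert set(timing["precursor"]) == expected


class TestClassEnrichment:
    def test_planted_class_ranks_first(self, universe_truth):
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            cat, truth = syndata.generate_geneset_catalog(
                universe_truth, markers_per_class=20,
                enrichment_plan={"microglia": 0.6}, seed=5000 + rep)
            table = run_class_enrichment(truth.planted_genes, cat,
                                         background="all",
                                         include_timing=False)
            classes = table[~table.set_name.str.contains(":")]
            best = classes.sort_values("p").iloc[0]
            if best.set_name == "microglia" and best.enrichment_ratio > 2:
                hits += 1
        assert hits / n_rep >= 0.9

    def test_uniform_query_false_positive_rate_near_alpha(self, universe_truth):
        rng = np.random.default_rng(0)
        cat, truth = syndata.generate_geneset_catalog(
            universe_truth, markers_per_class=20, seed=6)
        universe = truth.gene_universe
        n_tests = rejections = 0
        for rep in range(300):
            query = list(rng.choice(universe, size=40, replace=False))
            table = run_class_enrichment(query, cat, background="all",
                                         include_timing=False)
            n_tests += len(table)
            rejections += int((table["p"] < 0.05).sum())
        rate = rejections / n_tests
        # binomial 99% interval around 0.05
        se = np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(rate - 0.05) < 2.58 * se + 0.01

    def test_marker_background_never_larger_than_universe(self, universe_truth):
        cat, truth = syndata.generate_geneset_catalog(
            universe_truth, markers_per_class=20, seed=7)
        t_all = run_class_enrichment(truth.planted_genes[:20], cat,
                                     background="all", include_timing=False)
        t_mark = run_class_enrichment(truth.planted_genes[:20], cat,
                                      background="fetal_markers",
                                      include_timing=False)
        assert (t_mark["M"] <= t_all["M"]).all()


def _grid_frame(trajs: dict[str, dict[str, np.ndarray]], ages) -> pd.DataFrame:
    rows = []
    for gene, per_region in trajs.items():
        for region, y in per_region.items():
            for a, v in zip(ages, y):
                rows.append({"gene": gene, "region": region, "age": a,
                             "predicted_log2": v})
    return pd.DataFrame(rows)


class TestCelltypeEmbedding:
    def test_rows_built_from_unit_norm_region_blocks(self):
        ages = np.linspace(84, 259, 10)
        trajs = {"g1": {"V1": np.linspace(1, 5, 10), "M1": np.ones(10)}}
        cat = GeneSetCatalog(sets={"c1": ["g1"]})
        mat = build_celltype_trajectory_matrix(_grid_frame(trajs, ages), cat,
                                               regions=["M1", "V1"])
        row = mat.loc["c1"].to_numpy()
        assert np.linalg.norm(row[:10]) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(row[10:]) == pytest.approx(1.0, abs=1e-10)

    def test_identical_marker_trajectories_give_identical_rows(self):
        ages = np.linspace(84, 259, 8)
        shape = np.sin(np.linspace(0, 3, 8)) + 2
        trajs = {"g1": {"V1": shape, "M1": shape * 2},
                 "g2": {"V1": shape, "M1": shape * 2}}
        cat = GeneSetCatalog(sets={"c1": ["g1"], "c2": ["g2"]})
        mat = build_celltype_trajectory_matrix(_grid_frame(trajs, ages), cat)
        assert np.allclose(mat.loc["c1"], mat.loc["c2"])

    def test_archetype_classes_separate_in_embedding(self):
        """Three trajectory archetypes assigned to three class groups stay
        closer within class than between classes after UMAP."""
        rng = np.random.default_rng(1)
        ages = np.linspace(84, 259, 20)
        t = (ages - ages.mean()) / (np.ptp(ages) / 2)
        archetypes = [2 + 2 * t, 3 - 2 * t, 2 + 2 * t ** 2]
        trajs, sets = {}, {}
        labels = {}
        for a_i, arch in enumerate(archetypes):
            for j in range(4):
                g = f"g{a_i}_{j}"
                trajs[g] = {"V1": arch + rng.normal(0, 0.05, 20),
                            "M1": arch + rng.normal(0, 0.05, 20)}
                cls = f"type{a_i}_{j}"
                sets[cls] = [g]
                labels[cls] = a_i
        cat = GeneSetCatalog(sets=sets)
        mat = build_celltype_trajectory_matrix(_grid_frame(trajs, ages), cat)
        for seed in range(3):
            emb = embed_celltypes(mat, seed=seed, n_neighbors=4)
            coords = emb.to_numpy()
            lab = np.array([labels[c] for c in emb.index])
            within, between = [], []
            for i in range(len(lab)):
                for j in range(i + 1, len(lab)):
                    d = np.linalg.norm(coords[i] - coords[j])
                    (within if lab[i] == lab[j] else between).append(d)
            assert np.mean(within) < np.mean(between)

    def test_embedding_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(8, 12)))
        e1 = embed_celltypes(mat, seed=5)
        e2 = embed_celltypes(mat, seed=5)
        assert np.allclose(e1.to_numpy(), e2.to_numpy())
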