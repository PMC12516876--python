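import numpy as np
import pandas as pd
import pytest

from spikemap import (
    CountMatrix,
    IntegrationParams,
    NeighborMap,
    contribution_matrix,
    cosine_knn,
    impute_expression,
    merge_stage_results,
    project_cluster_labels,
)
from spikemap.integrate import ImputedMatrix

from conftest import brute_force_cosine_knn


def _cpm_like(values, cells=None, genes=None):
    values = np.asarray(values, dtype=float)
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return CountMatrix(values, cells, genes, layer="cpm")


class TestCosineKnn:
    def test_identical_vector_ranks_first_with_similarity_one(self):
        ref = _cpm_like([[1, 2, 3], [3, 1, 0], [0, 0, 1]], cells=["r0", "r1", "r2"])
        q = _cpm_like([[1, 2, 3]], cells=["q"])
        params = IntegrationParams(k=2, shared_genes=["g0", "g1", "g2"])
        nm = cosine_knn(q, ref, params)
        (rid, s), *_ = nm.neighbors["q"]
        assert rid == "r0" and s == pytest.approx(1.0)

    def test_orthogonal_vectors_similarity_zero(self):
        ref = _cpm_like([[0, 1]], cells=["r"])
        q = _cpm_like([[1, 0]], cells=["q"])
        nm = cosine_knn(q, ref, IntegrationParams(k=1, shared_genes=["g0", "g1"]))
        assert nm.neighbors["q"][0][1] == pytest.approx(0.0)

    def test_hand_cosine_ordering(self):
        # q=(1,1) vs refs (1,0): s=1/sqrt(2), (1,1): s=1 -> order [(1,1),(1,0)]
        ref = _cpm_like([[1, 0], [1, 1]], cells=["ra", "rb"])
        q = _cpm_like([[1, 1]], cells=["q"])
        nm = cosine_knn(q, ref, IntegrationParams(k=2, shared_genes=["g0", "g1"]))
        ids = [rid for rid, _ in nm.neighbors["q"]]
        sims = [s for _, s in nm.neighbors["q"]]
        assert ids == ["rb", "ra"]
        assert sims[0] == pytest.approx(1.0)
        assert sims[1] == pytest.approx(1 / np.sqrt(2))

    def test_tie_broken_by_reference_id(self):
        # two identical reference rows: lexicographically smaller id first
        ref = _cpm_like([[2, 2], [1, 1]], cells=["rz", "ra"])
        q = _cpm_like([[3, 3]], cells=["q"])
        nm = cosine_knn(q, ref, IntegrationParams(k=2, shared_genes=["g0", "g1"]))
        assert [rid for rid, _ in nm.neighbors["q"]] == ["ra", "rz"]

    def test_all_zero_query_excluded_with_report(self):
        ref = _cpm_like([[1, 1]], cells=["r"])
        q = _cpm_like([[0, 0], [1, 2]], cells=["qz", "qok"])
        nm = cosine_knn(q, ref, IntegrationParams(k=1, shared_genes=["g0", "g1"]))
        assert nm.excluded_queries == ["qz"]
        assert "qz" not in nm.neighbors and "qok" in nm.neighbors

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        q = _cpm_like(rng.lognormal(size=(40, 15)),
                      cells=[f"q{i:03d}" for i in range(40)])
        ref = _cpm_like(rng.lognormal(size=(120, 15)),
                        cells=[f"r{i:03d}" for i in range(120)])
        params = IntegrationParams(k=5, shared_genes=[f"g{j}" for j in range(15)])
        nm = cosine_knn(q, ref, params)
        oracle = brute_force_cosine_knn(q.to_frame(), ref.to_frame(), k=5)
        for qid, pairs in nm.neighbors.items():
            assert [rid for rid, _ in pairs] == [rid for rid, _ in oracle[qid]]
            for (_, s1), (_, s2) in zip(pairs, oracle[qid]):
                assert s1 == pytest.approx(s2, abs=1e-12)


class TestImputation:
    def test_equal_similarity_gives_arithmetic_mean(self):
        ref = _cpm_like([[2.0], [4.0]], cells=["r1", "r2"])
        nm = NeighborMap({"q": [("r1", 0.5), ("r2", 0.5)]})
        out = impute_expression(nm, ref)
        assert out.values.loc["q", "g0"] == pytest.approx(3.0)

    def test_weighted_average_hand_value(self):
        # neighbors {0, 4} with weights {3, 1} -> (3*0 + 1*4)/4 = 1
        ref = _cpm_like([[0.0], [4.0]], cells=["r1", "r2"])
        nm = NeighborMap({"q": [("r1", 3.0), ("r2", 1.0)]})
        out = impute_expression(nm, ref)
        assert out.values.loc["q", "g0"] == pytest.approx(1.0)

    def test_single_neighbor_copies_row(self):
        ref = _cpm_like([[1.0, 7.0, 0.2]], cells=["r"])
        nm = NeighborMap({"q": [("r", 0.9)]})
        out = impute_expression(nm, ref)
        np.testing.assert_allclose(out.values.loc["q"].to_numpy(), ref.values[0])

    def test_convexity_bound(self):
        rng = np.random.default_rng(1)
        ref = _cpm_like(rng.lognormal(size=(30, 8)),
                        cells=[f"r{i}" for i in range(30)])
        nm_dict = {}
        for qi in range(10):
            rows = rng.choice(30, size=5, replace=False)
            sims = sorted(rng.random(5), reverse=True)
            nm_dict[f"q{qi}"] = [(f"r{r}", s) for r, s in zip(rows, sims)]
        out = impute_expression(NeighborMap(nm_dict), ref)
        for qid, pairs in nm_dict.items():
            sub = ref.to_frame().loc[[rid for rid, _ in pairs]]
            assert np.all(out.values.loc[qid] >= sub.min(axis=0) - 1e-12)
            assert np.all(out.values.loc[qid] <= sub.max(axis=0) + 1e-12)

    def test_zero_weight_sum_reported_missing(self):
        ref = _cpm_like([[5.0]], cells=["r"])
        nm = NeighborMap({"q": [("r", 0.0)]})
        out = impute_expression(nm, ref)
        assert out.missing_cells == ["q"]
        assert np.isnan(out.values.loc["q", "g0"])

    def test_self_consistency_k1(self):
        # a query identical to a reference cell recovers that cell's full
        # profile exactly at k = 1
        rng = np.random.default_rng(2)
        full = rng.lognormal(size=(20, 30))
        ref = _cpm_like(full, cells=[f"r{i:02d}" for i in range(20)])
        panel = [f"g{j}" for j in range(10)]
        q = CountMatrix(full[3:4, :10], ["q"], panel, layer="cpm")
        params = IntegrationParams(k=1, shared_genes=panel)
        nm = cosine_knn(q, ref, params)
        out = impute_expression(nm, ref)
        np.testing.assert_allclose(out.values.loc["q"].to_numpy(), full[3],
                                   rtol=1e-12)


class TestProjection:
    def _nm(self, labels_sims):
        pairs = [(f"r{i}", s) for i, (_, s) in enumerate(labels_sims)]
        clusters = pd.Series({f"r{i}": lab for i, (lab, _) in
                              enumerate(labels_sims)})
        pairs.sort(key=lambda t: -t[1])
        return NeighborMap({"q": pairs}), clusters

    def test_majority_label_wins(self):
        nm, clusters = self._nm([("c8", 0.9), ("c8", 0.8), ("c3", 0.7),
                                 ("c14", 0.6), ("c16", 0.5)])
        pt = project_cluster_labels(nm, clusters, IntegrationParams(
            shared_genes=["g"]))
        assert pt.table.loc["q", "label"] == "c8"
        assert pt.table.loc["q", "votes"] == 2

    def test_all_unique_labels_give_no_projection(self):
        nm, clusters = self._nm([("c1", 0.9), ("c2", 0.8), ("c3", 0.7),
                                 ("c4", 0.6), ("c5", 0.5)])
        pt = project_cluster_labels(nm, clusters, IntegrationParams(
            shared_genes=["g"]))
        assert pt.table.loc["q", "label"] is None

    def test_frequency_tie_broken_by_summed_similarity(self):
        # c8: 0.8+0.6=1.4, c3: 0.7+0.4=1.1 -> c8
        nm, clusters = self._nm([("c8", 0.8), ("c3", 0.7), ("c8", 0.6),
                                 ("c3", 0.4), ("c16", 0.5)])
        pt = project_cluster_labels(nm, clusters, IntegrationParams(
            shared_genes=["g"]))
        assert pt.table.loc["q", "label"] == "c8"
        assert pt.table.loc["q", "summed_similarity"] == pytest.approx(1.4)

    def test_exact_tie_gives_no_projection(self):
        nm, clusters = self._nm([("a", 0.7), ("b", 0.7), ("a", 0.5), ("b", 0.5)])
        pt = project_cluster_labels(nm, clusters, IntegrationParams(
            shared_genes=["g"]))
        assert pt.table.loc["q", "label"] is None

    def test_similarity_floor_excludes_neighbors(self):
        # the two c9 votes sit at or below 0.3 and are discarded; remaining
        # labels are unique -> no projection
        nm, clusters = self._nm([("c9", 0.3), ("c9", 0.2), ("c1", 0.9),
                                 ("c2", 0.8), ("c3", 0.7)])
        pt = project_cluster_labels(nm, clusters, IntegrationParams(
            shared_genes=["g"], min_similarity=0.3))
        assert pt.table.loc["q", "label"] is None

    def test_no_qualifying_neighbors_gives_no_projection(self):
        nm, clusters = self._nm([("c1", 0.1), ("c1", 0.05)])
        pt = project_cluster_labels(nm, clusters, IntegrationParams(
            shared_genes=["g"], min_similarity=0.3))
        assert pt.table.loc["q", "label"] is None


class TestContributionMatrix:
    def _pt(self, mapping):
        rows = [(cid, lab, 2, 1.0) for cid, lab in mapping.items()]
        table = pd.DataFrame(rows, columns=["cell_id", "label", "votes",
                                            "summed_similarity"])
        return pd.DataFrame(table).set_index("cell_id")

    def test_fraction_matches_hand_ratio(self):
        from spikemap.integrate import ProjectionTable
        mapping = {f"cell{i}": "cA" for i in range(114)}
        pt = ProjectionTable(self._pt(mapping))
        sc_clusters = pd.Series({f"cell{i}": "sc0" for i in range(114)})
        cm = contribution_matrix(pt, sc_clusters, {"cA": 2151})
        assert cm.counts.loc["cA", "sc0"] == 114
        assert cm.fractions.loc["cA", "sc0"] == pytest.approx(114 / 2151)

    def test_unprojected_cells_excluded_and_empty_rows_zero(self):
        from spikemap.integrate import ProjectionTable
        table = self._pt({"x": "cA"})
        table.loc["y"] = [None, 0, 0.0]
        pt = ProjectionTable(table)
        sc_clusters = pd.Series({"x": "sc0", "y": "sc1"})
        cm = contribution_matrix(pt, sc_clusters, {"cA": 10, "cB": 5})
        assert cm.counts.loc["cA", "sc0"] == 1
        assert (cm.counts.loc["cB"] == 0).all()

    def test_counts_reconstructable_from_fractions(self):
        from spikemap.integrate import ProjectionTable
        mapping = {"a": "cA", "b": "cA", "c": "cB"}
        pt = ProjectionTable(self._pt(mapping))
        sc_clusters = pd.Series({"a": "sc0", "b": "sc1", "c": "sc0"})
        cm = contribution_matrix(pt, sc_clusters, {"cA": 4, "cB": 8})
        recon = cm.fractions.mul(cm.smfish_sizes, axis=0)
        np.testing.assert_allclose(recon.to_numpy(), cm.counts.to_numpy())

    def test_missing_size_rejected(self):
        from spikemap.integrate import ProjectionTable
        pt = ProjectionTable(self._pt({"a": "cX"}))
        with pytest.raises(KeyError, match="size table"):
            contribution_matrix(pt, pd.Series({"a": "sc0"}), {"cA": 3})


class TestMergeStages:
    def _imp(self, cells, genes, fill=1.0):
        vals = np.full((len(cells), len(genes)), fill)
        return ImputedMatrix(pd.DataFrame(vals, index=cells, columns=genes))

    def test_gene_union_inclusion_exclusion(self):
        a = self._imp(["x1"], ["a", "b", "c"])
        b = self._imp(["y1"], ["b", "c", "d"])
        merged = merge_stage_results(a, b)
        assert len(merged.gene_ids) == 3 + 3 - 2
        assert set(merged.gene_ids) == {"a", "b", "c", "d"}

    def test_identical_gene_sets(self):
        a = self._imp(["x1"], ["a", "b"])
        b = self._imp(["y1"], ["a", "b"])
        merged = merge_stage_results(a, b)
        assert merged.gene_ids == ["a", "b"]

    def test_stage_exclusive_gene_is_missing_not_zero(self):
        a = self._imp(["x1"], ["a", "b"], fill=2.0)
        b = self._imp(["y1"], ["b", "d"], fill=3.0)
        merged = merge_stage_results(a, b)
        assert np.isnan(merged.values.loc["y1", "a"])
        assert np.isnan(merged.values.loc["x1", "d"])
        assert merged.values.loc["x1", "a"] == 2.0

    def test_overlapping_cells_rejected(self):
        a = self._imp(["same"], ["a"])
        b = self._imp(["same"], ["a"])
        with pytest.raises(ValueError, match="overlap"):
            merge_stage_results(a, b)
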