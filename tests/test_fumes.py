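"""Communication scoring: preprocessing, z-scores, permutation p, differentials."""

import numpy as np
import pandas as pd
import pytest

from scfumes.fumes import (CommunicationScorer, celltype_mean_expression,
                           celltype_zscore, communication_scores,
                           differential_pairs, fdr_adjust, intersect_with_mr,
                           preprocess_counts)
from conftest import make_adata


def pairs_table(sensors, A=0.5):
    A = [A] * len(sensors) if np.isscalar(A) else A
    return pd.DataFrame({"metabolite_id": [s.replace("g", "m") for s in sensors],
                         "sensor_id": sensors, "A": A})


class TestPreprocess:
    def test_normalization_and_log1p(self):
        adata = make_adata([[1, 1, 2], [2, 2, 4]], ["a", "b"])
        out = preprocess_counts(adata, min_genes=1, min_cells=1)
        np.testing.assert_allclose(out.X[0], np.log1p([2500, 2500, 5000]))
        np.testing.assert_allclose(out.X[1], np.log1p([2500, 2500, 5000]))

    def test_min_genes_boundary(self):
        # 250-gene panel: one cell expresses 199 genes, one expresses 200
        X = np.zeros((2, 250))
        X[0, :199] = 1
        X[1, :200] = 1
        adata = make_adata(X, ["a", "b"])
        out = preprocess_counts(adata, min_cells=0)
        assert list(out.obs_names) == ["c2"]

    def test_min_cells_boundary(self):
        # gene1 in 9 cells, gene2 in 10 cells
        X = np.zeros((12, 2))
        X[:9, 0] = 1
        X[:10, 1] = 1
        adata = make_adata(X, ["a"] * 12)
        out = preprocess_counts(adata, min_genes=1)
        assert list(out.var_names) == ["g2"]

    def test_empty_after_filtering_is_an_error(self):
        adata = make_adata(np.ones((3, 4)), ["a"] * 3)
        with pytest.raises(ValueError, match="min_genes=200"):
            preprocess_counts(adata)


class TestCellTypeProfile:
    def test_mean_and_proportion(self):
        adata = make_adata([[1.0, 9], [3.0, 9], [5.0, 9], [7.0, 9]],
                           ["k", "k", "l", "l"])
        prof = celltype_mean_expression(adata, pairs_table(["g1", "g2"]),
                                        low_expr_quantile=0.0)
        row = prof[(prof.gene == "g1") & (prof.cell_type == "k")].iloc[0]
        assert row["mu"] == 2.0 and row["prop"] == 1.0 and row["n_cells"] == 2

    def test_low_expression_quantile_boundary(self):
        # stratum means 0.1, 0.2, 0.3, 0.4 -> 25th percentile 0.175
        X = np.array([[0.1, 0.2, 0.3, 0.4]] * 2 + [[5.0, 5, 5, 5]] * 2)
        adata = make_adata(X, ["k", "k", "l", "l"])
        prof = celltype_mean_expression(adata,
                                        pairs_table(["g1", "g2", "g3", "g4"]),
                                        low_expr_quantile=0.25)
        prof = prof[prof.cell_type == "k"].set_index("gene")
        assert bool(prof.loc["g1", "low_expr"]) is True     # 0.1 < 0.175
        assert bool(prof.loc["g2", "low_expr"]) is False    # 0.2 >= 0.175

    def test_all_zero_gene_flagged(self):
        adata = make_adata([[0.0, 1], [0.0, 2], [1.0, 3], [2.0, 4]],
                           ["k", "k", "l", "l"])
        prof = celltype_mean_expression(adata, pairs_table(["g1", "g2"]))
        row = prof[(prof.gene == "g1") & (prof.cell_type == "k")].iloc[0]
        assert row["mu"] == 0 and row["prop"] == 0 and bool(row["low_expr"])


class TestZScore:
    def profile(self, mus, gene="g"):
        return pd.DataFrame({"gene": gene, "cell_type": [f"k{i}" for i in
                                                         range(len(mus))],
                             "group": "G", "mu": mus, "prop": 1.0,
                             "n_cells": 10, "low_expr": False})

    def test_hand_computed_examples(self):
        z = celltype_zscore(self.profile([1.0, 2.0, 3.0]))["Z"]
        np.testing.assert_allclose(z, [-1, 0, 1])
        z2 = celltype_zscore(self.profile([0.0, 4.0]))["Z"]
        np.testing.assert_allclose(z2, [-0.7071, 0.7071], atol=1e-4)

    def test_constant_gene_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = celltype_zscore(self.profile([2.0, 2.0, 2.0]))
        assert len(out) == 0

    def test_single_cell_type_rejected(self):
        with pytest.raises(ValueError, match=">= 2 cell types"):
            celltype_zscore(self.profile([1.0]))

    def test_rows_standardized_by_construction(self):
        rng = np.random.default_rng(5)
        out = []
        for gene in "abcde":
            out.append(celltype_zscore(
                self.profile(rng.uniform(0, 5, 6), gene=gene)))
        for _, sub in pd.concat(out).groupby("gene"):
            assert sub["Z"].mean() == pytest.approx(0, abs=1e-10)
            assert sub["Z"].std(ddof=1) == pytest.approx(1, abs=1e-10)


class TestScores:
    def test_score_is_z_times_a(self):
        z = pd.DataFrame({"gene": ["s1", "s1", "s2"], "cell_type": list("kkl"),
                          "group": "G", "Z": [2.0, 0.0, -1.2], "prop": 1.0,
                          "low_expr": False})
        z["cell_type"] = ["k", "l", "k"]
        acts = pd.DataFrame({"metabolite_id": ["m1", "m2"],
                             "sensor_id": ["s1", "s2"], "A": [0.5, 0.556]})
        out = communication_scores(z, acts)
        got = out.set_index(["metabolite_id", "cell_type"])["score"]
        assert got[("m1", "k")] == pytest.approx(1.0)
        assert got[("m1", "l")] == pytest.approx(0.0)
        assert got[("m2", "k")] == pytest.approx(-0.667, abs=5e-4)

    def test_low_expr_entries_excluded(self):
        z = pd.DataFrame({"gene": ["s1", "s1"], "cell_type": ["k", "l"],
                          "group": "G", "Z": [1.0, -1.0], "prop": 1.0,
                          "low_expr": [False, True]})
        acts = pd.DataFrame({"metabolite_id": ["m1"], "sensor_id": ["s1"],
                             "A": [1.0]})
        out = communication_scores(z, acts)
        assert out["cell_type"].tolist() == ["k"]


class TestFdrAdjust:
    def test_textbook_bh(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_vectors(self):
        assert fdr_adjust([0.2]).tolist() == [0.2]
        assert fdr_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_nan_propagates_without_affecting_ranking(self):
        q = fdr_adjust([0.01, np.nan, 0.02, 0.03, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(np.delete(q, 1), [0.04, 0.04, 0.04, 0.04])


class TestDifferentialPairs:
    def results(self, group, scores, qs):
        n = len(scores)
        return pd.DataFrame({"metabolite_id": [f"m{i}" for i in range(n)],
                             "sensor_id": [f"s{i}" for i in range(n)],
                             "cell_type": "k", "group": group,
                             "score": scores, "q": qs})

    def test_threshold_semantics(self):
        a = self.results("AD", [0.9, 0.3, 1.51, 1.50], [0.01, 0.01, 0.049, 0.049])
        b = self.results("CT", [0.1, 0.1, 1.0, 1.0], [0.6, 0.01, 0.6, 0.6])
        out = differential_pairs(a, b)
        assert out.set_index("metabolite_id")["differential"].tolist() == [
            True,    # diff 0.8 > 0.5, q 0.01
            False,   # diff 0.2
            True,    # diff 0.51 just over, q 0.049 just under
            False,   # diff exactly 0.5 is not > 0.5
        ]
        assert out["specific_group"].tolist() == ["AD", "", "AD", ""]

    def test_fdr_boundary(self):
        a = self.results("AD", [1.0], [0.05])   # q exactly at cutoff: not sig
        b = self.results("CT", [0.0], [0.5])
        assert not differential_pairs(a, b)["differential"].iloc[0]

    def test_identical_groups_yield_nothing(self):
        a = self.results("AD", [1.0, -0.5], [0.01, 0.01])
        b = a.assign(group="CT")
        assert differential_pairs(a, b)["differential"].sum() == 0

    def test_highly_selective_annotation(self):
        a = self.results("AD", [12.0], [0.001])
        b = self.results("CT", [0.5], [0.9])
        out = differential_pairs(a, b)
        assert bool(out["highly_selective"].iloc[0])


class TestMrIntersection:
    def mr(self, fdr, betas):
        cols = {f"beta_{m}": [b] for m, b in
                zip(["ivw", "maxlik", "presso", "wm"], betas)}
        return pd.DataFrame({"metabolite_id": ["m1"], **cols, "fdr": [fdr]})

    def scored(self):
        return pd.DataFrame({"metabolite_id": ["m1"], "sensor_id": ["s1"],
                             "cell_type": ["k"], "score": [1.0]})

    def test_consistent_positive_kept_as_risk(self):
        out = intersect_with_mr(self.scored(), self.mr(0.03, [0.8, 0.7, 0.9, 0.75]))
        assert len(out) == 1 and out["mr_direction"].iloc[0] == "risk"

    def test_inconsistent_direction_dropped(self):
        out = intersect_with_mr(self.scored(), self.mr(0.03, [0.8, -0.2, 0.9, 0.7]))
        assert len(out) == 0

    def test_fdr_over_threshold_dropped(self):
        out = intersect_with_mr(self.scored(), self.mr(0.08, [0.8, 0.7, 0.9, 0.75]))
        assert len(out) == 0

    def test_consistent_negative_is_protective(self):
        out = intersect_with_mr(self.scored(), self.mr(0.01, [-0.8, -0.7, -0.9, -0.75]))
        assert out["mr_direction"].iloc[0] == "protective"


class TestScorerEndToEnd:
    def small_adata(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 20, size=(24, 6)).astype(float)
        cts = (["k1"] * 4 + ["k2"] * 4 + ["k3"] * 4) * 2
        grp = ["A"] * 12 + ["B"] * 12
        return make_adata(X, cts, groups=grp)

    def test_determinism_under_fixed_seed(self):
        adata = self.small_adata()
        pairs = pairs_table([f"g{i}" for i in range(1, 7)])
        kw = dict(n_permutations=200, random_state=11, preprocess=False)
        r1 = CommunicationScorer(**kw).fit(adata, pairs).results_
        r2 = CommunicationScorer(**kw).fit(adata, pairs).results_
        pd.testing.assert_frame_equal(r1, r2)

    def test_invariant_to_pair_row_order_and_cell_relabeling(self):
        adata = self.small_adata()
        pairs = pairs_table([f"g{i}" for i in range(1, 7)])
        kw = dict(n_permutations=100, random_state=3, preprocess=False)
        r1 = CommunicationScorer(**kw).fit(adata, pairs).results_
        shuffled = pairs.sample(frac=1.0, random_state=9)
        r2 = CommunicationScorer(**kw).fit(adata, shuffled).results_
        renamed = adata.copy()
        renamed.obs_names = [f"zz{i}" for i in range(adata.n_obs)]
        r3 = CommunicationScorer(**kw).fit(renamed, pairs).results_
        for other in (r2, r3):
            pd.testing.assert_frame_equal(
                r1.sort_values(["group", "metabolite_id", "cell_type"])
                  .reset_index(drop=True),
                other.sort_values(["group", "metabolite_id", "cell_type"])
                     .reset_index(drop=True))

    def test_identical_cells_drop_all_genes(self):
        X = np.tile(np.array([3.0, 1.0, 2.0, 5.0]), (8, 1))
        adata = make_adata(X, ["k", "k", "l", "l"] * 2)
        est = CommunicationScorer(n_permutations=100, random_state=0,
                                  preprocess=False)
        est.fit(adata, pairs_table(["g1", "g2", "g3", "g4"]))
        assert len(est.results_) == 0  # constant mu across cell types: sd 0

    def test_single_cell_type_rejected(self):
        adata = make_adata(np.ones((4, 3)), ["k"] * 4)
        with pytest.raises(ValueError, match=">= 2 cell types"):
            CommunicationScorer(preprocess=False).fit(
                adata, pairs_table(["g1"]))

    def test_missing_sensor_counted_in_coverage(self):
        adata = self.small_adata()
        pairs = pd.concat([pairs_table(["g1", "g2"]),
                           pairs_table(["absent_gene"])])
        est = CommunicationScorer(n_permutations=100, random_state=0,
                                  preprocess=False).fit(adata, pairs)
        assert est.coverage_["n_sensors_missing"] == 1
        assert est.coverage_["n_pairs_scored"] == 2
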