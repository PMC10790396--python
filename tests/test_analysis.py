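"""Downstream statistics: depletion/dilution metrics, t-tests, BH, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import kipquant as kq


def matrix_from(data, scale="linear", **kw):
    return kq.ProteinQuantMatrix(pd.DataFrame(data, **kw), scale)


class TestDepletionMetrics:
    def test_identification_fraction(self):
        df = pd.DataFrame(
            {"round0": [1.0, 1, 1, 1, 1], "round1": [1.0, 1, 1, 1, np.nan]},
            index=list("ABCDE"),
        )
        m = kq.depletion_metrics(kq.ProteinQuantMatrix(df, "linear"))
        assert m.identification_fraction == [1.0, 0.8]

    def test_abundance_fraction(self):
        df = pd.DataFrame({"round0": [600.0, 400.0], "round1": [180.0, 100.0]},
                          index=["A", "B"])
        m = kq.depletion_metrics(kq.ProteinQuantMatrix(df, "linear"))
        assert m.abundance_fraction[1] == pytest.approx(0.28)

    def test_geometric_model_noiseless(self):
        spec = kq.DepletionSpec(n_kinases=100, binding_fraction=0.7,
                                detection_floor=0.0, noise_cv=0.0, seed=0)
        mat, _ = kq.gen_depletion_series(spec)
        m = kq.depletion_metrics(mat)
        assert m.abundance_fraction[1] == pytest.approx(0.30, abs=1e-9)

    def test_empty_round_zero_rejected(self):
        df = pd.DataFrame({"round0": [np.nan], "round1": [1.0]}, index=["A"])
        with pytest.raises(ValueError):
            kq.depletion_metrics(kq.ProteinQuantMatrix(df, "linear"))


class TestDilutionLinearity:
    def test_perfect_proportionality(self):
        totals = pd.Series({12.5: 25.0, 25.0: 50.0, 50.0: 100.0, 100.0: 200.0})
        slope, r2, _ = kq.dilution_linearity(totals)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_saturating_gene_flagged(self):
        m, truth = kq.gen_dilution_series(
            [12.5, 25.0, 50.0, 100.0, 200.0], n_genes=5,
            saturating_genes={"CDK4": 25.0}, seed=0,
        )
        totals = m.data.sum(axis=0)
        totals.index = [float(c) for c in totals.index]
        _, _, flags = kq.dilution_linearity(totals, per_gene=m)
        assert flags["CDK4"]
        assert not flags.drop("CDK4").any()

    def test_constant_totals_poor_fit(self):
        totals = pd.Series({12.5: 100.0, 50.0: 100.0, 200.0: 100.0})
        _, r2, _ = kq.dilution_linearity(totals)
        assert r2 < 0.5

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            kq.dilution_linearity(pd.Series({50.0: 1.0, 100.0: 2.0}))


class TestPrepareSamples:
    def test_replicates_averaged_on_log_scale(self):
        df = pd.DataFrame({"s1_r1": [4.0], "s1_r2": [6.0]}, index=["G1"])
        m = kq.ProteinQuantMatrix(df, "log2")
        out = kq.prepare_samples(m, {"s1_r1": "s1", "s1_r2": "s1"}, min_samples=0)
        assert out.data.loc["G1", "s1"] == 5.0

    def test_sparse_gene_dropped(self):
        n = 16
        cols = {f"s{i}_r1": [1.0, 1.0 if i < 9 else np.nan] for i in range(n)}
        m = kq.ProteinQuantMatrix(pd.DataFrame(cols, index=["dense", "sparse"]), "log2")
        rmap = {f"s{i}_r1": f"s{i}" for i in range(n)}
        out = kq.prepare_samples(m, rmap, min_samples=10)
        assert "dense" in out.genes and "sparse" not in out.genes

    def test_min_samples_zero_keeps_all(self):
        df = pd.DataFrame({"s1_r1": [np.nan]}, index=["G1"])
        m = kq.ProteinQuantMatrix(df, "log2")
        out = kq.prepare_samples(m, {"s1_r1": "s1"}, min_samples=0)
        assert out.genes == ["G1"]

    def test_uncovered_column_rejected(self):
        df = pd.DataFrame({"s1_r1": [1.0], "s1_r2": [1.0]}, index=["G1"])
        m = kq.ProteinQuantMatrix(df, "log2")
        with pytest.raises(ValueError, match="s1_r2"):
            kq.prepare_samples(m, {"s1_r1": "s1"}, min_samples=0)


def brute_force_bh(pvals):
    """Independent step-up oracle: sort, p*(m/i), cumulative min from the largest."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestDifferentialExpression:
    def _matrix(self, a_vals, b_vals, gene="G1"):
        cols = {f"a{i}": [v] for i, v in enumerate(a_vals)}
        cols.update({f"b{i}": [v] for i, v in enumerate(b_vals)})
        groups = {f"a{i}": "basal" for i in range(len(a_vals))}
        groups.update({f"b{i}": "luminal" for i in range(len(b_vals))})
        return kq.ProteinQuantMatrix(pd.DataFrame(cols, index=[gene]), "log2"), groups

    def test_student_closed_form(self):
        m, groups = self._matrix([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        out = kq.differential_expression(m, groups, test="student")
        assert out.loc["G1", "t"] == pytest.approx(-3.674, abs=1e-3)
        assert out.loc["G1", "p_value"] == pytest.approx(0.0213, abs=2e-4)
        assert out.loc["G1", "direction"] == "up_luminal"

    def test_identical_groups_guarded(self):
        m, groups = self._matrix([2.0, 2.0], [2.0, 2.0])
        out = kq.differential_expression(m, groups)
        assert out.loc["G1", "p_value"] == 1.0
        assert out.loc["G1", "fold_change"] == 1.0
        assert out.loc["G1", "direction"] == "undefined"

    def test_bh_adjustment_of_even_spacing(self):
        cols = {f"a{i}": np.random.default_rng(i).normal(size=4) for i in range(3)}
        # direct check of the BH helper on the printed example
        adj = kq.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_sparse_gene_untested_not_error(self):
        df = pd.DataFrame(
            {"a0": [1.0, 1.0], "a1": [2.0, np.nan], "b0": [4.0, 2.0], "b1": [5.0, 2.5]},
            index=["ok", "sparse"],
        )
        m = kq.ProteinQuantMatrix(df, "log2")
        groups = {"a0": "basal", "a1": "basal", "b0": "luminal", "b1": "luminal"}
        out = kq.differential_expression(m, groups)
        assert out.loc["sparse", "direction"] == "untested"
        assert np.isnan(out.loc["sparse", "p_value"])
        assert np.isfinite(out.loc["ok", "p_value"])

    def test_direction_matches_sign_of_difference(self, pdx_cohort):
        matrix, rmap, _ = pdx_cohort
        prep = kq.prepare_samples(kq.log_transform(matrix), rmap, min_samples=10)
        groups = {s: ("basal" if s.startswith("B") else "luminal") for s in prep.samples}
        out = kq.differential_expression(prep, groups)
        tested = out[out.direction.isin(["up_basal", "up_luminal"])]
        diff = tested["mean_basal"] - tested["mean_luminal"]
        assert ((diff > 0) == (tested.direction == "up_basal")).all()
        # adjusted p never below raw p
        assert (tested.p_adjusted >= tested.p_value - 1e-15).all()

    def test_welch_differs_under_unequal_variance(self):
        m, groups = self._matrix([1.0, 1.1, 0.9, 1.05], [3.0, 7.0, 1.0, 5.0])
        s = kq.differential_expression(m, groups, test="student").loc["G1", "p_value"]
        w = kq.differential_expression(m, groups, test="welch").loc["G1", "p_value"]
        assert s != w

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=40))
    def test_bh_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(
            kq.benjamini_hochberg(pvals), brute_force_bh(pvals), rtol=1e-12
        )


class TestClusterSamples:
    def test_planted_subtypes_recovered(self, pdx_cohort):
        matrix, rmap, _ = pdx_cohort
        prep = kq.prepare_samples(kq.log_transform(matrix), rmap, min_samples=10)
        true = [0 if s.startswith("B") else 1 for s in prep.samples]
        for method in ("hierarchical", "kmeans"):
            labels, _ = kq.cluster_samples(prep, method=method, k=2, seed=0)
            assert adjusted_rand_score(true, labels.values) == 1.0

    def test_k_equals_n_singletons(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.normal(size=(10, 4)), scale="log2",
                        index=[f"G{i}" for i in range(10)], columns=list("abcd"))
        labels, _ = kq.cluster_samples(m, method="hierarchical", k=4)
        assert labels.nunique() == 4

    def test_kmeans_deterministic_with_seed(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.normal(size=(20, 6)), scale="log2",
                        index=[f"G{i}" for i in range(20)], columns=list("abcdef"))
        l1, _ = kq.cluster_samples(m, method="kmeans", k=3, seed=7)
        l2, _ = kq.cluster_samples(m, method="kmeans", k=3, seed=7)
        pd.testing.assert_series_equal(l1, l2)

    def test_k_above_n_rejected(self):
        m = matrix_from([[1.0, 2.0]], scale="log2", index=["G1"], columns=["a", "b"])
        with pytest.raises(ValueError):
            kq.cluster_samples(m, k=3)


class TestCrossDatasetCorrelation:
    def test_affine_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(2)
        a = matrix_from(rng.normal(size=(10, 6)), scale="log2",
                        index=[f"G{i}" for i in range(10)], columns=list("abcdef"))
        b = kq.ProteinQuantMatrix(2 * a.data + 1, "log2")
        r, median = kq.cross_dataset_correlation(a, b)
        np.testing.assert_allclose(r, 1.0)
        assert median == pytest.approx(1.0)

    def test_independent_noise_near_zero_median(self):
        rng = np.random.default_rng(3)
        idx = [f"G{i}" for i in range(100)]
        cols = [f"s{i}" for i in range(16)]
        a = matrix_from(rng.normal(size=(100, 16)), scale="log2", index=idx, columns=cols)
        b = matrix_from(rng.normal(size=(100, 16)), scale="log2", index=idx, columns=cols)
        _, median = kq.cross_dataset_correlation(a, b)
        assert abs(median) < 0.15

    def test_sparse_gene_excluded(self):
        df_a = pd.DataFrame({"s1": [1.0, 1.0], "s2": [2.0, np.nan], "s3": [3.0, np.nan]},
                            index=["dense", "sparse"])
        df_b = pd.DataFrame({"s1": [2.0, 1.0], "s2": [4.0, 2.0], "s3": [6.0, 3.0]},
                            index=["dense", "sparse"])
        r, _ = kq.cross_dataset_correlation(
            kq.ProteinQuantMatrix(df_a, "log2"), kq.ProteinQuantMatrix(df_b, "log2")
        )
        assert "sparse" not in r.index

    def test_disjoint_genes_rejected(self):
        a = matrix_from([[1.0, 2.0, 1.5]], scale="log2", index=["G1"], columns=list("abc"))
        b = matrix_from([[1.0, 2.0, 1.5]], scale="log2", index=["G2"], columns=list("abc"))
        with pytest.raises(ValueError):
            kq.cross_dataset_correlation(a, b)


class TestTransforms:
    def test_phospho_sites_averaged(self):
        sites = pd.DataFrame({"s1": [1.0, 3.0, 5.0]}, index=["p1", "p2", "p3"])
        out = kq.phospho_rollup(sites, {"p1": "G1", "p2": "G1", "p3": "G2"})
        assert out.loc["G1", "s1"] == 2.0
        assert out.loc["G2", "s1"] == 5.0

    def test_single_site_passthrough_and_missing(self):
        sites = pd.DataFrame({"s1": [1.0, np.nan], "s2": [2.0, np.nan]}, index=["p1", "p2"])
        out = kq.phospho_rollup(sites, {"p1": "G1", "p2": "G2"})
        assert out.loc["G1", "s1"] == 1.0
        assert np.isnan(out.loc["G2", "s1"])

    def test_rna_median_ratio(self):
        tpm = pd.DataFrame({"s1": [10.0], "s2": [20.0], "s3": [40.0]}, index=["G1"])
        out = kq.rna_transform(tpm)
        np.testing.assert_allclose(out.loc["G1"], [-1.0, 0.0, 1.0])

    def test_constant_gene_all_zeros_and_row_medians_zero(self):
        rng = np.random.default_rng(4)
        tpm = pd.DataFrame(rng.lognormal(2, 1, size=(20, 5)),
                           index=[f"G{i}" for i in range(20)],
                           columns=[f"s{j}" for j in range(5)])
        tpm.iloc[0] = 7.0
        out = kq.rna_transform(tpm)
        np.testing.assert_allclose(out.iloc[0], 0.0)
        np.testing.assert_allclose(out.median(axis=1), 0.0, atol=1e-12)
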