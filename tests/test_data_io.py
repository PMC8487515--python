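import numpy as np
import pytest

from lacfnforest.data_io import (
    ExpressionMatrix,
    Orientation,
    PreprocessConfig,
    ZeroVariancePolicy,
    filter_samples_by_missingness,
    impute_knn,
    preprocess,
    read_expression_matrix,
    read_labels,
    write_expression_matrix,
    zscore_normalize,
)
from lacfnforest.synthetic_data import SyntheticSpec, generate_classification_data


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadExpressionMatrix:
    def test_na_cell_is_masked(self, tmp_path):
        p = _write(tmp_path, "m.tsv",
                   "id\tg1\tg2\ns1\t1.0\t2.0\ns2\tNA\t4.0\ns3\t5.0\t6.0\n")
        m = read_expression_matrix(p)
        assert m.missing_mask.sum() == 1
        assert m.missing_mask[1, 0]
        assert m.sample_ids == ["s1", "s2", "s3"]
        assert m.values[0, 1] == 2.0

    def test_transposed_read_matches_untransposed(self, tmp_path):
        p1 = _write(tmp_path, "rows.csv", "id,g1,g2\ns1,1,2\ns2,3,4\n")
        p2 = _write(tmp_path, "cols.csv", "id,s1,s2\ng1,1,3\ng2,2,4\n")
        a = read_expression_matrix(p1, Orientation.SAMPLES_IN_ROWS)
        b = read_expression_matrix(p2, Orientation.GENES_IN_ROWS)
        assert a.sample_ids == b.sample_ids and a.gene_ids == b.gene_ids
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize(
        "text,match",
        [
            ("", "empty"),
            ("id,g1,g1\ns1,1,2\n", "duplicate"),
            ("id,g1\ns1,frog\n", "non-numeric"),
        ],
    )
    def test_malformed_inputs_raise(self, tmp_path, text, match):
        p = _write(tmp_path, "bad.csv", text)
        with pytest.raises(ValueError, match=match):
            read_expression_matrix(p)

    def test_roundtrip_identity(self, tmp_path):
        spec = SyntheticSpec(n_samples=8, n_genes=12, n_classes=2,
                             n_informative=3, missing_rate=0.1, seed=0)
        m, _, _ = generate_classification_data(spec)
        p = tmp_path / "round.csv"
        write_expression_matrix(m, p)
        m2 = read_expression_matrix(p)
        assert m2.sample_ids == m.sample_ids and m2.gene_ids == m.gene_ids
        np.testing.assert_array_equal(m2.missing_mask, m.missing_mask)
        obs = ~m.missing_mask
        np.testing.assert_allclose(m2.values[obs], m.values[obs], rtol=1e-12)


class TestFilterSamples:
    def _matrix(self, mask_rows):
        n, d = len(mask_rows), 20
        vals = np.ones((n, d))
        mask = np.zeros((n, d), dtype=bool)
        for i, frac in enumerate(mask_rows):
            k = int(round(frac * d))
            mask[i, :k] = True
            vals[i, :k] = np.nan
        return ExpressionMatrix([f"s{i}" for i in range(n)],
                                [f"g{j}" for j in range(d)], vals, mask)

    def test_over_threshold_removed_at_threshold_kept(self):
        m = self._matrix([0.25, 0.20, 0.0])
        out = filter_samples_by_missingness(m, PreprocessConfig())
        assert out.sample_ids == ["s1", "s2"]  # strictly more than 20% dropped

    def test_no_missing_is_identity(self):
        m = self._matrix([0.0, 0.0])
        out = filter_samples_by_missingness(m)
        np.testing.assert_array_equal(out.values, m.values)
        assert out.sample_ids == m.sample_ids

    def test_all_filtered_raises(self):
        m = self._matrix([0.5, 0.6])
        with pytest.raises(ValueError, match="unusable"):
            filter_samples_by_missingness(m)


class TestImputeKNN:
    def test_hand_computed_neighbour_mean(self):
        # s1 misses gene g2; s2 and s3 are its 2 nearest, with g2 = 4 and 6
        vals = np.array([[1.0, np.nan, 1.0],
                         [1.1, 4.0, 1.1],
                         [0.9, 6.0, 0.9]])
        mask = np.isnan(vals)
        m = ExpressionMatrix(["s1", "s2", "s3"], ["g1", "g2", "g3"], vals, mask)
        out = impute_knn(m, PreprocessConfig(knn_k=2))
        assert out.values[0, 1] == pytest.approx(5.0)
        assert not out.missing_mask.any()

    def test_observed_cells_unchanged(self, rng):
        spec = SyntheticSpec(n_samples=15, n_genes=10, n_classes=2,
                             n_informative=2, missing_rate=0.1, seed=4)
        m, _, _ = generate_classification_data(spec)
        out = impute_knn(m, PreprocessConfig(knn_k=3))
        obs = ~m.missing_mask
        np.testing.assert_array_equal(out.values[obs], m.values[obs])

    def test_no_missing_is_identity(self):
        vals = np.arange(6.0).reshape(2, 3)
        m = ExpressionMatrix(["a", "b"], ["g1", "g2", "g3"], vals,
                             np.zeros((2, 3), bool))
        assert impute_knn(m) is m

    def test_k_clamped_to_available_donors(self):
        vals = np.array([[1.0, np.nan], [1.0, 3.0], [1.0, 5.0]])
        m = ExpressionMatrix(["a", "b", "c"], ["g1", "g2"], vals,
                             np.isnan(vals))
        out = impute_knn(m, PreprocessConfig(knn_k=50))
        assert out.values[0, 1] == pytest.approx(4.0)

    def test_gene_missing_everywhere_raises(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        m = ExpressionMatrix(["a", "b"], ["g1", "g2"], vals, np.isnan(vals))
        with pytest.raises(ValueError, match="g2"):
            impute_knn(m)

    def test_matches_reference_imputer_on_simple_case(self):
        # cross-check against sklearn's KNNImputer where the two rules agree:
        # uniform weights, all donors observed for the target gene
        from sklearn.impute import KNNImputer

        rng = np.random.default_rng(0)
        vals = rng.normal(size=(12, 6))
        vals[3, 2] = np.nan
        m = ExpressionMatrix([f"s{i}" for i in range(12)],
                             [f"g{j}" for j in range(6)], vals, np.isnan(vals))
        ours = impute_knn(m, PreprocessConfig(knn_k=4))
        ref = KNNImputer(n_neighbors=4, weights="uniform").fit_transform(vals)
        assert ours.values[3, 2] == pytest.approx(ref[3, 2])


class TestZscoreNormalize:
    def test_hand_computed_column(self):
        vals = np.array([[2.0], [4.0], [6.0]])
        m = ExpressionMatrix(["a", "b", "c"], ["g"], vals,
                             np.zeros((3, 1), bool))
        out = zscore_normalize(m)
        np.testing.assert_allclose(
            out.values[:, 0], [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_constant_gene_set_zero(self):
        vals = np.column_stack([np.full(4, 7.0), np.arange(4.0)])
        m = ExpressionMatrix(list("abcd"), ["g1", "g2"], vals,
                             np.zeros((4, 2), bool))
        out = zscore_normalize(m)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)
        assert out.gene_ids == ["g1", "g2"]

    def test_constant_gene_dropped_under_drop_policy(self):
        vals = np.column_stack([np.full(4, 7.0), np.arange(4.0)])
        m = ExpressionMatrix(list("abcd"), ["g1", "g2"], vals,
                             np.zeros((4, 2), bool))
        out = zscore_normalize(
            m, PreprocessConfig(zero_variance_policy=ZeroVariancePolicy.DROP_GENE)
        )
        assert out.gene_ids == ["g2"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(30, 5))
        m = ExpressionMatrix([f"s{i}" for i in range(30)],
                             [f"g{j}" for j in range(5)], vals,
                             np.zeros((30, 5), bool))
        once = zscore_normalize(m)
        twice = zscore_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_missing_values_raise(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        m = ExpressionMatrix(["a", "b"], ["g1", "g2"], vals, np.isnan(vals))
        with pytest.raises(ValueError, match="imputed"):
            zscore_normalize(m)


def test_full_pipeline_centres_and_scales_every_gene():
    spec = SyntheticSpec(n_samples=40, n_genes=25, n_classes=3,
                         n_informative=5, missing_rate=0.05, seed=9)
    m, _, _ = generate_classification_data(spec)
    out = preprocess(m)
    assert not out.missing_mask.any()
    np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
    sd = out.values.std(axis=0)
    np.testing.assert_allclose(sd[sd > 0], 1.0, atol=1e-9)


def test_label_reading_and_alignment(tmp_path):
    p = tmp_path / "labels.csv"
    p.write_text("sample_id,label\ns2,B\ns1,A\n")
    lv = read_labels(p)
    assert lv.class_names == ["A", "B"]
    m = ExpressionMatrix(["s1", "s2"], ["g"], np.zeros((2, 1)),
                         np.zeros((2, 1), bool))
    aligned = lv.aligned_to(m)
    assert aligned.labels == ["A", "B"]
    np.testing.assert_array_equal(aligned.as_indices(), [0, 1])
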