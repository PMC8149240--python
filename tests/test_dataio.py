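import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swarmstack import dataio
from swarmstack.dataio import (SplitSpec, auto_multiplier, impute_mean,
                               load_csv, minmax_normalize, round_half_up,
                               smote, stratified_split, train_size)

from conftest import make_dataset


class TestLoadCsv:
    def test_clean_csv_has_no_missing_cells(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,b,label\n1,2,x\n3,4,y\n5,6,x\n")
        ds = load_csv(p, "label")
        assert not ds.missing_mask.any()
        assert ds.X.shape == (3, 2)

    def test_missing_token_sets_mask(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,b,label\n5.1,?,1\n2.0,3.0,0\n1.0,1.0,1\n")
        ds = load_csv(p, "label", missing_tokens={"?"})
        assert ds.missing_mask[0, 1]
        assert ds.missing_mask.sum() == 1

    def test_minority_class_is_positive(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,label\n1,sick\n2,well\n3,well\n4,well\n")
        ds = load_csv(p, "label")
        assert ds.y.sum() == 1
        assert ds.class_names[1] == "sick"

    def test_three_label_values_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,label\n1,x\n2,y\n3,z\n")
        with pytest.raises(ValueError, match="2 label"):
            load_csv(p, "label")

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,label\nfoo,x\n2,y\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_csv(p, "label")


class TestImputeMean:
    def test_no_missing_is_identity(self):
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0]], [0, 1])
        out = impute_mean(ds)
        np.testing.assert_array_equal(out.X, ds.X)

    def test_missing_cell_gets_observed_mean(self):
        ds = make_dataset([[1.0], [99.0], [3.0]], [0, 1, 0])
        ds.missing_mask[1, 0] = True
        out = impute_mean(ds)
        assert out.X[1, 0] == 2.0
        assert not out.missing_mask.any()

    def test_two_missing_cells_share_the_imputed_value(self):
        ds = make_dataset([[1.0], [0.0], [0.0], [5.0]], [0, 1, 0, 1])
        ds.missing_mask[1, 0] = ds.missing_mask[2, 0] = True
        out = impute_mean(ds)
        assert out.X[1, 0] == out.X[2, 0] == 3.0

    def test_fully_missing_feature_is_an_error(self):
        ds = make_dataset([[1.0], [2.0]], [0, 1])
        ds.missing_mask[:, 0] = True
        with pytest.raises(ValueError, match="no observed"):
            impute_mean(ds)


@pytest.mark.parametrize(
    "n_maj,n_min,expected",
    [(150, 120, 1), (123, 32, 4), (210, 100, 2), (357, 212, 2),
     (102, 63, 2), (416, 167, 2), (164, 139, 1)],
)
def test_auto_multiplier_from_class_ratio(n_maj, n_min, expected):
    assert auto_multiplier(n_maj, n_min) == expected


class TestSmote:
    def test_multiplier_one_is_identity(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=(20, 3)), [0] * 12 + [1] * 8)
        out = smote(ds, multiplier=1)
        np.testing.assert_array_equal(out.X, ds.X)

    def test_row_count_closed_form(self):
        # hepatitis-shaped: 123 majority / 32 minority, multiplier 4 -> 251
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.normal(size=(155, 4)), [0] * 123 + [1] * 32)
        out = smote(ds, k_neighbors=5, multiplier=4, seed=0)
        assert out.n_instances == 123 + 4 * 32 == 251
        assert out.class_counts() == (123, 128)

    def test_synthetic_points_lie_on_segment(self):
        # two minority points, k=1: every synthetic point is a convex combo
        X = np.array([[0.0, 0.0], [1.0, 2.0], [5.0, 5.0], [6.0, 5.0],
                      [5.0, 6.0], [6.0, 6.0], [5.5, 5.5], [5.0, 5.5]])
        y = [1, 1, 0, 0, 0, 0, 0, 0]
        ds = make_dataset(X, y)
        out = smote(ds, k_neighbors=1, multiplier=2, seed=3)
        synth = out.X[8:]
        p, q = X[0], X[1]
        for s in synth:
            t = (s - p) / (q - p)
            assert np.allclose(t, t[0]) and 0.0 <= t[0] <= 1.0

    def test_minority_smaller_than_k_plus_one_rejected(self):
        ds = make_dataset(np.arange(12.0).reshape(6, 2), [0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="minority"):
            smote(ds, k_neighbors=5, multiplier=2)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.normal(size=(40, 3)), [0] * 28 + [1] * 12)
        a = smote(ds, multiplier=2, seed=9)
        b = smote(ds, multiplier=2, seed=9)
        np.testing.assert_array_equal(a.X, b.X)


class TestMinMax:
    def test_hand_example(self):
        ds = make_dataset([[2.0], [4.0], [6.0]], [0, 1, 0])
        out, params = minmax_normalize(ds)
        np.testing.assert_allclose(out.X.ravel(), [0.0, 0.5, 1.0])
        assert params.min_a[0] == 2.0 and params.max_a[0] == 6.0

    def test_constant_feature_maps_to_zero(self):
        ds = make_dataset([[7.0], [7.0], [7.0]], [0, 1, 0])
        out, _ = minmax_normalize(ds)
        assert (out.X == 0.0).all()

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=2,
                    max_size=30))
    def test_idempotent_on_unit_interval(self, vals):
        ds = make_dataset(np.array(vals)[:, None], [0] + [1] * (len(vals) - 1))
        once, _ = minmax_normalize(ds)
        twice, _ = minmax_normalize(once)
        np.testing.assert_allclose(twice.X, once.X, atol=1e-12)
        assert once.X.min() >= 0.0 and once.X.max() <= 1.0

    def test_params_roundtrip_via_dict(self):
        ds = make_dataset([[2.0, 1.0], [4.0, 3.0]], [0, 1])
        _, params = minmax_normalize(ds)
        restored = dataio.NormalizationParams.from_dict(params.to_dict())
        np.testing.assert_array_equal(restored.min_a, params.min_a)


class TestSplit:
    @pytest.mark.parametrize(
        "n,frac,expected_train",
        [(780, 0.6, 468), (270, 0.6, 162), (228, 0.6, 137), (251, 0.6, 151),
         (410, 0.6, 246), (303, 0.6, 182), (750, 0.6, 450),
         (312, 0.8, 250), (108, 0.8, 86), (91, 0.8, 73), (100, 0.8, 80),
         (164, 0.8, 131), (121, 0.8, 97), (300, 0.8, 240)],
    )
    def test_half_up_sizes(self, n, frac, expected_train):
        assert train_size(n, frac) == expected_train

    def test_partition_and_stratification(self):
        rng = np.random.default_rng(4)
        y = (rng.uniform(size=251) < 0.3).astype(int)
        ds = make_dataset(rng.normal(size=(251, 2)), y)
        tr, te = stratified_split(ds, SplitSpec(0.6, True, 0))
        assert tr.n_instances == 151 and te.n_instances == 100
        # partition: multiset of rows conserved
        allX = np.vstack([tr.X, te.X])
        assert sorted(map(tuple, allX)) == sorted(map(tuple, ds.X))
        for c in (0, 1):
            ideal = 0.6 * (y == c).sum()
            got = (tr.y == c).sum()
            assert abs(got - ideal) <= 1

    def test_fraction_one_keeps_everything_in_train(self):
        ds = make_dataset(np.arange(8.0).reshape(4, 2), [0, 1, 0, 1])
        tr, te = stratified_split(ds, SplitSpec(1.0, True, 0))
        assert tr.n_instances == 4 and te.n_instances == 0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.normal(size=(50, 3)), [0] * 30 + [1] * 20)
        a = stratified_split(ds, SplitSpec(0.6, True, 42))
        b = stratified_split(ds, SplitSpec(0.6, True, 42))
        np.testing.assert_array_equal(a[0].X, b[0].X)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=0.0)


def test_round_half_up_on_halves():
    assert round_half_up(249.5) == 250
    assert round_half_up(2.5) == 3
    assert round_half_up(2.49) == 2
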