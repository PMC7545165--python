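"""Distinctiveness, restrictedness, classification, thresholds, local checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from skbio import DistanceMatrix

import ecorare as ec
from ecorare.rarity import OccurrenceMatrix

from conftest import random_mixed_table


def _dm(mat, ids=None):
    mat = np.asarray(mat, dtype=float)
    return DistanceMatrix(mat, ids=ids or [f"s{i}" for i in range(mat.shape[0])])


def _occ(mat, cells=None, species=None):
    mat = np.asarray(mat)
    df = pd.DataFrame(
        mat,
        index=cells or [f"c{i}" for i in range(mat.shape[0])],
        columns=species or [f"s{i}" for i in range(mat.shape[1])],
    )
    return OccurrenceMatrix(df)


class TestDistinctiveness:
    def test_identical_pool_is_zero(self):
        d = ec.functional_distinctiveness(_dm(np.zeros((6, 6))))
        assert (d == 0).all()

    def test_maximally_different_focal_is_one(self):
        m = np.zeros((4, 4))
        m[0, 1:] = m[1:, 0] = 1.0
        assert ec.functional_distinctiveness(_dm(m))["s0"] == 1.0

    def test_three_species_mean(self):
        m = np.array([[0, 0.2, 0.4], [0.2, 0, 0.0], [0.4, 0.0, 0]])
        assert ec.functional_distinctiveness(_dm(m))["s0"] == pytest.approx(0.3)

    @pytest.mark.parametrize("n", [3, 10, 20])
    def test_matches_double_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        got = ec.functional_distinctiveness(_dm(m))
        for i in range(n):
            expected = sum(m[i, j] for j in range(n) if j != i) / (n - 1)
            assert got.iloc[i] == pytest.approx(expected)

    def test_duplicate_never_increases_distinctiveness(self):
        rng = np.random.default_rng(9)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        base = ec.functional_distinctiveness(_dm(m))["s0"]
        # append an exact duplicate of s0 (distance 0 to it)
        m2 = np.zeros((7, 7))
        m2[:6, :6] = m
        m2[6, :6] = m[0]
        m2[:6, 6] = m[0]
        dup = ec.functional_distinctiveness(_dm(m2))["s0"]
        assert dup <= base

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            ec.functional_distinctiveness(_dm(np.zeros((1, 1))))


class TestRestrictedness:
    def test_ubiquitous_species_is_zero(self):
        r = ec.geographical_restrictedness(_occ(np.ones((100, 1), dtype=int)))
        assert r.iloc[0] == 0.0

    def test_single_cell_of_hundred(self):
        m = np.zeros((100, 2), dtype=int)
        m[0, 0] = 1
        m[:, 1] = 1
        r = ec.geographical_restrictedness(_occ(m))
        assert r["s0"] == pytest.approx(0.99)

    def test_quarter_occupancy(self):
        m = np.zeros((100, 2), dtype=int)
        m[:25, 0] = 1
        m[:, 1] = 1
        assert ec.geographical_restrictedness(_occ(m))["s0"] == pytest.approx(0.75)

    def test_zero_occupancy_rejected(self):
        m = np.zeros((4, 2), dtype=int)
        m[:, 1] = 1
        with pytest.raises(ValueError, match="zero occupancy"):
            ec.geographical_restrictedness(_occ(m))

    def test_strictly_decreasing_in_occupancy(self):
        m = np.zeros((10, 3), dtype=int)
        m[:2, 0] = 1
        m[:5, 1] = 1
        m[:9, 2] = 1
        r = ec.geographical_restrictedness(_occ(m))
        assert r["s0"] > r["s1"] > r["s2"]


class TestClassify:
    def test_extremes_are_rare_and_common(self):
        rng = np.random.default_rng(0)
        n = 50
        D = pd.Series(rng.permutation(n).astype(float), index=[f"s{i}" for i in range(n)])
        R = pd.Series(rng.permutation(n).astype(float), index=D.index)
        top = D.idxmax()
        R[top] = n + 1.0
        bottom = D.idxmin()
        R[bottom] = -1.0
        prof = ec.classify(D, R)
        assert prof.loc[top, "rarity_class"] == "rare"
        assert prof.loc[bottom, "rarity_class"] == "common"

    def test_classes_partition_the_pool(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(200)]
        prof = ec.classify(
            pd.Series(rng.random(200), index=idx), pd.Series(rng.random(200), index=idx)
        )
        counts = prof["rarity_class"].value_counts()
        assert counts.sum() == 200
        assert not prof["rarity_class"].isna().any()

    def test_species_exactly_at_quantile_is_not_rare(self):
        # with values 0..4 the 75% quantile is exactly 3 (linear interpolation)
        idx = [f"s{i}" for i in range(5)]
        v = pd.Series([0.0, 1.0, 2.0, 3.0, 4.0], index=idx)
        prof = ec.classify(v, v)
        assert prof.loc["s3", "rarity_class"] != "rare"
        assert prof.loc["s4", "rarity_class"] == "rare"

    @given(st.integers(0, 10_000))
    def test_rare_at_most_quarter_of_distinct_pool(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        idx = [f"s{i}" for i in range(n)]
        D = pd.Series(rng.permutation(n).astype(float), index=idx)
        R = pd.Series(rng.permutation(n).astype(float), index=idx)
        prof = ec.classify(D, R)
        assert (prof["rarity_class"] == "rare").sum() <= int(np.ceil(n / 4))

    def test_mismatched_species_rejected(self):
        D = pd.Series([1.0, 2.0], index=["a", "b"])
        R = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(ValueError):
            ec.classify(D, R)


@pytest.fixture(scope="module")
def pool():
    rng = np.random.default_rng(7)
    idx = [f"s{i}" for i in range(120)]
    return (
        pd.Series(rng.random(120), index=idx),
        pd.Series(rng.random(120), index=idx),
    )


class TestThresholdSensitivity:
    def test_rare_sets_are_nested(self, pool):
        D, R = pool
        sens = ec.threshold_sensitivity(D, R)
        r70 = sens.rare_set((0.30, 0.70))
        r75 = sens.rare_set((0.25, 0.75))
        r80 = sens.rare_set((0.20, 0.80))
        assert r80 <= r75 <= r70

    def test_identical_thresholds_correlate_perfectly(self, small_pool):
        traits, occ = small_pool
        D = ec.functional_distinctiveness(ec.gower_distance(traits))
        R = ec.geographical_restrictedness(occ)
        sens = ec.threshold_sensitivity(D, R, thresholds=[(0.25, 0.75)], occ=occ)
        assert sens.rare_richness_corr.iloc[0] == pytest.approx(1.0)

    def test_alternative_thresholds_positively_correlated(self, small_pool):
        traits, occ = small_pool
        D = ec.functional_distinctiveness(ec.gower_distance(traits))
        R = ec.geographical_restrictedness(occ)
        sens = ec.threshold_sensitivity(D, R, occ=occ)
        assert (sens.rare_richness_corr > 0).all()


class TestLocalDistinctiveness:
    def test_full_pool_cell_recovers_global_values(self):
        rng = np.random.default_rng(3)
        n = 8
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = _dm(m)
        occ_mat = np.ones((1, n), dtype=int)
        res = ec.local_distinctiveness(_occ(occ_mat), dm)
        np.testing.assert_allclose(
            res.local.iloc[0].to_numpy(), ec.functional_distinctiveness(dm).to_numpy()
        )

    def test_two_species_cell_equals_pairwise_distance(self):
        m = np.array([[0, 0.6, 0.1], [0.6, 0, 0.2], [0.1, 0.2, 0]])
        occ_mat = np.array([[1, 1, 0], [1, 1, 1]])
        res = ec.local_distinctiveness(_occ(occ_mat), _dm(m))
        assert res.local.iloc[0]["s0"] == pytest.approx(0.6)
        assert res.local.iloc[0]["s1"] == pytest.approx(0.6)

    def test_singleton_cells_skipped_with_warning(self):
        m = np.array([[0, 0.5], [0.5, 0]])
        occ_mat = np.array([[1, 0], [1, 1]])
        with pytest.warns(UserWarning, match="skipped"):
            res = ec.local_distinctiveness(_occ(occ_mat), _dm(m))
        assert res.n_skipped_cells == 1
        assert np.isnan(res.local.iloc[0]["s0"])

    def test_reproducible_on_synthetic_pool(self, small_pool):
        traits, occ = small_pool
        dm = ec.gower_distance(traits)
        r1 = ec.local_distinctiveness(occ, dm).pearson_r
        r2 = ec.local_distinctiveness(occ, dm).pearson_r
        assert -1.0 <= r1 <= 1.0 and r1 == r2
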