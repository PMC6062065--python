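import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from ggiforest.features import (
    FEATURE_NAMES,
    N_FEATURES,
    WELCH_SENTINEL,
    GenePair,
    PairFeatureVector,
    compute_features,
    feature_matrix,
    mutual_information,
    pcc,
    undersample,
    welch_t,
    write_feature_table,
)

from conftest import random_pair


class TestWelch:
    def test_identical_samples(self):
        assert welch_t([1, 2, 3], [1, 2, 3]) == 0.0

    def test_zero_variance_sentinel(self):
        assert welch_t([0, 0, 0, 0], [1, 1, 1, 1]) == -WELCH_SENTINEL
        assert welch_t([1, 1], [0, 0]) == WELCH_SENTINEL

    def test_zero_variance_equal_means(self):
        assert welch_t([2, 2], [2, 2]) == 0.0

    def test_against_scipy(self):
        x, y = [1, 2, 3, 4, 5], [2, 4, 6]
        expected = st.ttest_ind(x, y, equal_var=False).statistic
        assert welch_t(x, y) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_against_scipy_random(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(2, 40))
        y = rng.normal(1.0, 2.0, size=rng.integers(2, 40))
        expected = st.ttest_ind(x, y, equal_var=False).statistic
        assert welch_t(x, y) == pytest.approx(expected, abs=1e-10)

    def test_antisymmetry(self):
        x, y = [1.0, 2, 3, 7], [0.5, 2, 9]
        assert welch_t(x, y) == pytest.approx(-welch_t(y, x))

    def test_too_short(self):
        with pytest.raises(ValueError):
            welch_t([1], [1, 2])


class TestPcc:
    def test_perfect_linear(self):
        assert pcc([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_antilinear(self):
        assert pcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_zero_variance_contract(self):
        assert pcc([1, 2, 3], [5, 5, 5]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pcc([1, 2], [1, 2, 3])

    def test_bounds_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = pcc(rng.normal(size=10), rng.normal(size=10))
            assert -1 <= v <= 1


class TestMutualInformation:
    def test_self_mi_equals_entropy(self):
        # equal counts in each of 2 bins -> H = 1 bit
        x = [0.0, 0.0, 1.0, 1.0]
        assert mutual_information(x, x, bins=2) == pytest.approx(1.0)

    def test_constant_list_zero(self):
        assert mutual_information([3, 3, 3, 3], [1, 2, 3, 4], bins=5) == 0.0

    def test_histogram2d_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(size=200)
        y = rng.uniform(size=200)
        bins = 10
        joint, _, _ = np.histogram2d(
            x, y, bins=[np.linspace(x.min(), x.max(), bins + 1),
                        np.linspace(y.min(), y.max(), bins + 1)])
        joint /= joint.sum()
        px, py = joint.sum(axis=1), joint.sum(axis=0)
        expected = sum(
            joint[i, j] * np.log2(joint[i, j] / (px[i] * py[j]))
            for i in range(bins) for j in range(bins) if joint[i, j] > 0)
        assert mutual_information(x, y, bins=bins) == pytest.approx(
            expected, abs=1e-12)

    def test_non_negative(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(2, 60))
            assert mutual_information(rng.normal(size=n),
                                      rng.normal(size=n), bins=7) >= 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2], [1, 2, 3], bins=2)


class TestUndersample:
    def test_order_preserving_subset(self):
        longer = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = undersample(longer, 3, rng_seed=7)
        assert len(out) == 3
        idx = [longer.index(v) for v in out]
        assert idx == sorted(idx)
        assert set(out) <= set(longer)

    def test_noop_when_equal_length(self):
        np.testing.assert_array_equal(
            undersample([1.0, 2.0, 3.0], 3, rng_seed=0), [1, 2, 3])

    def test_deterministic(self):
        longer = np.arange(50, dtype=float)
        a = undersample(longer, 20, rng_seed=123)
        b = undersample(longer, 20, rng_seed=123)
        np.testing.assert_array_equal(a, b)

    def test_target_too_large(self):
        with pytest.raises(ValueError):
            undersample([1.0, 2.0], 3, rng_seed=0)


class TestGenePair:
    def test_canonicalisation(self):
        p = GenePair.make("GB", "GA", [1, 2], [3, 4], [5, 6], [7, 8])
        assert (p.gene_a, p.gene_b) == ("GA", "GB")
        np.testing.assert_array_equal(p.e_a_l0, [5, 6])
        assert p.pair_id == "GA|GB"

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            GenePair.make("G1", "G1", [1, 2], [3, 4], [1, 2], [3, 4])

    def test_class_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            GenePair("GA", "GB", [1, 2], [3, 4], [5, 6, 7], [7, 8])


class TestComputeFeatures:
    def test_length_and_finiteness(self):
        rng = np.random.default_rng(0)
        vec = compute_features(random_pair(rng))
        assert len(vec.values) == N_FEATURES == 22
        assert np.all(np.isfinite(vec.values))

    def test_identical_lists(self):
        rng = np.random.default_rng(1)
        a0, a1 = rng.normal(size=10), rng.normal(size=12)
        pair = GenePair("GA", "GB", a0, a1, a0.copy(), rng.normal(size=12))
        vec = compute_features(pair)
        assert vec["PCC_A_L0_B_L0"] == pytest.approx(1.0)
        assert vec["WT_A_L0_B_L0"] == pytest.approx(0.0, abs=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        p = random_pair(rng)
        swapped = GenePair(p.gene_b, p.gene_a, p.e_b_l0, p.e_b_l1,
                           p.e_a_l0, p.e_a_l1)
        v1 = compute_features(p, rng_seed=9)
        v2 = compute_features(swapped, rng_seed=9)
        swap_map = {
            "Mean_A_L0": "Mean_B_L0", "Mean_A_L1": "Mean_B_L1",
            "Mean_B_L0": "Mean_A_L0", "Mean_B_L1": "Mean_A_L1",
            "SD_A_L0": "SD_B_L0", "SD_A_L1": "SD_B_L1",
            "SD_B_L0": "SD_A_L0", "SD_B_L1": "SD_A_L1",
            "dMm_A_L0": "dMm_B_L0", "dMm_A_L1": "dMm_B_L1",
            "dMm_B_L0": "dMm_A_L0", "dMm_B_L1": "dMm_A_L1",
            "WT_A_L0_A_L1": "WT_B_L0_B_L1", "WT_B_L0_B_L1": "WT_A_L0_A_L1",
            "MI_A_L0_A_L1": "MI_B_L0_B_L1", "MI_B_L0_B_L1": "MI_A_L0_A_L1",
        }
        for name in FEATURE_NAMES:
            if name in ("WT_A_L0_B_L0", "WT_A_L1_B_L1"):
                assert v2[name] == pytest.approx(-v1[name])
            elif name.startswith(("PCC", "MI_A_L0_B_L0", "MI_A_L1_B_L1")):
                assert v2[name] == pytest.approx(v1[name])
            else:
                assert v2[name] == pytest.approx(v1[swap_map[name]])

    @settings(deadline=None, max_examples=20)
    @given(st_h.floats(-50, 50, allow_nan=False), st_h.integers(0, 2**31))
    def test_shift_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        p = random_pair(rng)
        shifted = GenePair(p.gene_a, p.gene_b, p.e_a_l0 + c, p.e_a_l1 + c,
                           p.e_b_l0 + c, p.e_b_l1 + c)
        v1 = compute_features(p, rng_seed=1)
        v2 = compute_features(shifted, rng_seed=1)
        for name in FEATURE_NAMES:
            if name.startswith("Mean"):
                assert v2[name] == pytest.approx(v1[name] + c, abs=1e-8)
            else:
                assert v2[name] == pytest.approx(v1[name], abs=1e-8)

    def test_too_short_lists(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_features(GenePair("GA", "GB", [1.0], [1, 2], [1.0], [3, 4]))


class TestFeatureVector:
    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="22"):
            PairFeatureVector((1.0,) * 21)

    def test_nan_rejected(self):
        vals = [0.0] * 22
        vals[3] = float("nan")
        with pytest.raises(ValueError, match="non-finite"):
            PairFeatureVector(tuple(vals))


class TestFeatureMatrix:
    def _pairs(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return [GenePair.make(f"G{2*i}", f"G{2*i+1}",
                              rng.normal(size=8), rng.normal(size=9),
                              rng.normal(size=8), rng.normal(size=9))
                for i in range(n)]

    def test_shape(self):
        X, ids = feature_matrix(self._pairs(10))
        assert X.shape == (10, 22)
        assert len(ids) == 10

    def test_permutation_invariance(self):
        pairs = self._pairs(6)
        X1, ids1 = feature_matrix(pairs, rng_seed=5)
        X2, ids2 = feature_matrix(pairs[::-1], rng_seed=5)
        lookup = dict(zip(ids2, X2))
        for pid, row in zip(ids1, X1):
            np.testing.assert_array_equal(row, lookup[pid])

    def test_deterministic(self):
        pairs = self._pairs(5)
        X1, _ = feature_matrix(pairs, rng_seed=3)
        X2, _ = feature_matrix(pairs, rng_seed=3)
        np.testing.assert_array_equal(X1, X2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            feature_matrix([])

    def test_write_table(self, tmp_path):
        import pandas as pd

        pairs = self._pairs(4)
        X, _ = feature_matrix(pairs)
        out = tmp_path / "features.tsv"
        write_feature_table(out, X, pairs, labels=[1, 0, 1, 0])
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == (["pair_id", "gene_a", "gene_b"]
                                    + list(FEATURE_NAMES) + ["label"])
        np.testing.assert_allclose(df[list(FEATURE_NAMES)].to_numpy(), X,
                                   rtol=1e-10)
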