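import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ccc_oracle
from octradiomics.stability import (
    ccc,
    ccc_per_feature,
    consistent_core,
    cross_bw_reproducibility,
    repeatability_screen,
    spearman_dedup,
)


class TestCcc:
    def test_perfect_agreement(self):
        assert ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_constant_offset_worked_value(self):
        # population variance 2/3, mean shift 1 -> 2*(2/3) / (2/3+2/3+1) = 4/7
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_inverse_concordance(self):
        assert ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_both_constant_is_undefined(self):
        assert np.isnan(ccc([5, 5, 5], [5, 5, 5]))

    def test_length_mismatch_and_short_input_error(self):
        with pytest.raises(ValueError):
            ccc([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            ccc([1, 2], [1, 2])

    def test_matches_moment_oracle_on_1000_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(3, 30))
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), n)
            y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), n)
            assert ccc(x, y) == pytest.approx(ccc_oracle(x, y), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.floats(-1e3, 1e3, allow_nan=False),
                st.floats(-1e3, 1e3, allow_nan=False),
            ),
            min_size=3,
            max_size=25,
        )
    )
    def test_symmetry_identity_and_attenuation(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        cxy = ccc(x, y)
        if np.isnan(cxy):
            return
        assert cxy == pytest.approx(ccc(y, x), abs=1e-12)
        if x.std() > 0:
            assert ccc(x, x) == pytest.approx(1.0)
        if x.std() > 0 and y.std() > 0:
            rho = np.corrcoef(x, y)[0, 1]
            assert abs(cxy) <= abs(rho) + 1e-9


def _tables(columns_test, columns_retest, index=None):
    idx = index or [f"L{i}" for i in range(len(next(iter(columns_test.values()))))]
    return (
        pd.DataFrame(columns_test, index=idx),
        pd.DataFrame(columns_retest, index=idx),
    )


class TestRepeatabilityScreen:
    def test_identical_tables_repeat_every_varying_feature(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {"a": rng.normal(size=10), "b": rng.normal(size=10), "const": 1.0},
            index=[f"L{i}" for i in range(10)],
        )
        rep, cccs = repeatability_screen(t, t.copy())
        assert rep == {"a", "b"}  # constant feature is non-evaluable
        assert np.isnan(cccs["const"])

    def test_pure_noise_pseudofeature_is_excluded(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=40)
        test, retest = _tables(
            {"real": base, "noise": rng.normal(size=40)},
            {"real": base + rng.normal(0, 0.01, 40), "noise": rng.normal(size=40)},
        )
        rep, cccs = repeatability_screen(test, retest)
        assert "real" in rep
        assert "noise" not in rep
        assert abs(cccs["noise"]) < 0.5

    def test_threshold_is_inclusive_at_the_boundary(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = x + rng.normal(0, 0.4, size=20)
        test, retest = _tables({"f": x}, {"f": y})
        value = ccc(x, y)
        rep, _ = repeatability_screen(test, retest, threshold=value)
        assert "f" in rep  # CCC == threshold counts as repeatable

    def test_raising_threshold_never_enlarges_the_set(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        test, retest = _tables(
            {f"f{i}": x + rng.normal(0, s, 30) for i, s in enumerate((0.01, 0.2, 1.0))},
            {f"f{i}": x + rng.normal(0, s, 30) for i, s in enumerate((0.01, 0.2, 1.0))},
        )
        sets = [
            repeatability_screen(test, retest, threshold=t)[0]
            for t in (0.5, 0.7, 0.9, 0.99)
        ]
        for lo, hi in zip(sets, sets[1:]):
            assert hi <= lo

    def test_too_few_pairs_error(self):
        test, retest = _tables({"f": [1.0, 2.0]}, {"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            repeatability_screen(test, retest)


class TestSpearmanDedup:
    def test_exact_multiple_keeps_single_survivor(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=20)
        values = pd.DataFrame({"f": f, "g": 2 * f})
        cccs = pd.Series({"f": 0.95, "g": 0.92})
        kept = spearman_dedup({"f", "g"}, values, cccs)
        assert kept == {"f"}  # higher-CCC member survives

    def test_uncorrelated_set_unchanged(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame({c: rng.normal(size=50) for c in "abc"})
        cccs = pd.Series({c: 0.95 for c in "abc"})
        assert spearman_dedup(set("abc"), values, cccs) == set("abc")

    def test_three_mutually_correlated_keep_highest_ccc(self):
        rng = np.random.default_rng(6)
        f = rng.normal(size=30)
        values = pd.DataFrame({"a": f, "b": f + 1, "c": 3 * f})
        cccs = pd.Series({"a": 0.95, "b": 0.92, "c": 0.99})
        assert spearman_dedup({"a", "b", "c"}, values, cccs) == {"c"}

    def test_empty_set_passthrough(self):
        assert spearman_dedup(set(), pd.DataFrame(), pd.Series(dtype=float)) == set()


class TestConsistentCore:
    def test_identical_sets_intersect_to_themselves(self):
        sets = {bw: {"x", "y"} for bw in (5, 10, 15)}
        core, only = consistent_core(sets)
        assert core == {"x", "y"}
        assert all(not s for s in only.values())

    def test_feature_missing_at_one_bw_is_dropped(self):
        sets = {5: {"x", "y"}, 10: {"x"}, 15: {"x", "y"}}
        core, _ = consistent_core(sets)
        assert core == {"x"}

    def test_bw_unique_features_are_reported(self):
        sets = {5: {"x", "special5"}, 10: {"x"}}
        _, only = consistent_core(sets)
        assert only[5] == {"special5"}


class TestCrossBwReproducibility:
    def test_diagonal_counts_all_finite_features_and_matrix_is_symmetric(self):
        rng = np.random.default_rng(7)
        idx = [f"s{i}" for i in range(12)]
        base = rng.normal(size=12)
        tables = {
            bw: pd.DataFrame(
                {"stable": base, "scaledep": base * bw, "const": 1.0}, index=idx
            )
            for bw in (5, 10)
        }
        counts = cross_bw_reproducibility(tables)
        assert counts.loc[5, 5] == 2  # the constant feature is non-evaluable
        np.testing.assert_array_equal(counts.to_numpy(), counts.to_numpy().T)

    def test_bw_invariant_feature_always_reproducible(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(10)]
        shape_like = rng.normal(size=10)
        tables = {
            bw: pd.DataFrame(
                {"shape": shape_like, "texture": rng.normal(size=10)}, index=idx
            )
            for bw in (5, 50)
        }
        counts = cross_bw_reproducibility(tables)
        assert counts.loc[5, 50] >= 1  # shape counts; independent texture does not
        assert counts.loc[5, 50] < 2
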