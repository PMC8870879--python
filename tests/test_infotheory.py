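"""Entropy, mutual information, SU, total correlation and MSU."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cuffbp import infotheory as it

settings.register_profile("ci", deadline=None, max_examples=60, derandomize=True)
settings.load_profile("ci")

labels = st.lists(st.integers(0, 3), min_size=4, max_size=60)


class TestDiscretize:
    def test_equal_frequency_balanced_bins(self):
        d = it.discretize(np.arange(1, 101), n_bins=4)
        _, counts = np.unique(d.labels, return_counts=True)
        assert list(counts) == [25, 25, 25, 25]

    def test_stored_edges_reproduce_labels(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        d = it.discretize(x, n_bins=6)
        assert np.array_equal(d.apply(x).labels, d.labels)

    def test_uniform_bins_binomial_range(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 10000)
        d = it.discretize(x, n_bins=10)
        _, counts = np.unique(d.labels, return_counts=True)
        sigma = np.sqrt(10000 * 0.1 * 0.9)
        assert np.all(np.abs(counts - 1000) <= 3 * sigma + 1)

    def test_constant_input_flagged(self):
        d = it.discretize(np.ones(20), n_bins=4)
        assert d.constant and d.n_bins == 1


class TestEntropy:
    @pytest.mark.parametrize("x, expected", [
        ([0, 1] * 50, 1.0),
        ([0] * 30, 0.0),
        ([0] * 25 + [1] * 75, 0.8112781244591328),  # -(1/4)log2(1/4)-(3/4)log2(3/4)
    ])
    def test_plugin_entropy(self, x, expected):
        assert it.entropy(np.array(x)) == pytest.approx(expected, abs=1e-12)

    def test_conditional_entropy_brute_force(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 400)
        y = rng.integers(0, 3, 400)
        # oracle: sum_j p(y_j) H(X | y=y_j) from the joint table directly
        expected = 0.0
        for yj in np.unique(y):
            sel = x[y == yj]
            p_y = sel.size / x.size
            _, c = np.unique(sel, return_counts=True)
            p = c / c.sum()
            expected += p_y * float(-(p * np.log2(p)).sum())
        assert it.conditional_entropy(x, y) == pytest.approx(expected, abs=1e-12)

    def test_conditional_entropy_of_self_is_zero(self):
        x = np.array([0, 1, 2, 0, 1, 2, 1])
        assert it.conditional_entropy(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_conditioning_on_constant_gives_marginal(self):
        x = np.array([0, 1, 0, 1, 2, 2])
        y = np.zeros(6, dtype=int)
        assert it.conditional_entropy(x, y) == pytest.approx(it.entropy(x), abs=1e-12)


class TestMutualInformation:
    def test_identical_binary_one_bit(self):
        x = np.array([0, 1] * 500)
        assert it.mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_independent_coins_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 10000)
        y = rng.integers(0, 2, 10000)
        assert it.mutual_information(x, y) < 0.01

    @given(labels, labels)
    def test_symmetry(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        assert it.mutual_information(x, y) == pytest.approx(
            it.mutual_information(y, x), abs=1e-12)


class TestSymmetricUncertainty:
    def test_full_dependence_is_one(self):
        x = np.array([0, 1, 2] * 20)
        assert it.symmetric_uncertainty(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_dependence_seen_by_su_not_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, 2000)
        y = x ** 2
        assert abs(it.pearson(x, y)) < 0.1
        su = it.symmetric_uncertainty(it.discretize(x), it.discretize(y))
        assert su > 0.5

    def test_both_constant_undefined(self):
        c = np.zeros(10, dtype=int)
        assert np.isnan(it.symmetric_uncertainty(c, c))

    @given(labels, labels)
    def test_unit_interval_and_joint_entropy_bound(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        su = it.symmetric_uncertainty(x, y)
        if not np.isnan(su):
            assert 0.0 <= su <= 1.0
        assert it.joint_entropy(x, y) <= it.entropy(x) + it.entropy(y) + 1e-12


class TestMultivariate:
    def test_single_variable_joint_entropy(self):
        x = np.array([0, 1, 1, 2, 0])
        assert it.joint_entropy_multi([x]) == pytest.approx(it.entropy(x), abs=1e-12)

    def test_three_independent_coins_about_three_bits(self):
        rng = np.random.default_rng(5)
        cols = [rng.integers(0, 2, 20000) for _ in range(3)]
        assert it.joint_entropy_multi(cols) == pytest.approx(3.0, abs=0.01)

    def test_identical_columns_collapse(self):
        x = np.array([0, 1, 2, 1] * 10)
        assert it.joint_entropy_multi([x, x, x]) == pytest.approx(it.entropy(x),
                                                                 abs=1e-12)

    def test_total_correlation_of_pair_equals_mi(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 4, 300)
        y = (x + rng.integers(0, 2, 300)) % 4
        assert it.total_correlation([x, y]) == pytest.approx(
            it.mutual_information(x, y), abs=1e-12)

    def test_xor_total_correlation_one_bit(self):
        # exact population: all 8 equally likely (x1, x2) pairs, x3 = xor
        x1 = np.array([0, 0, 1, 1] * 2)
        x2 = np.array([0, 1, 0, 1] * 2)
        x3 = x1 ^ x2
        assert it.total_correlation([x1, x2, x3]) == pytest.approx(1.0, abs=1e-12)

    def test_independent_population_tc_zero(self):
        x1 = np.repeat([0, 1], 4)
        x2 = np.tile(np.repeat([0, 1], 2), 2)
        x3 = np.tile([0, 1], 4)
        assert it.total_correlation([x1, x2, x3]) == pytest.approx(0.0, abs=1e-12)

    def test_msu_bounds_for_identical_and_independent(self):
        x = np.array([0, 1] * 8)
        assert it.msu([x, x, x]) == pytest.approx(1.0, abs=1e-12)
        x1 = np.repeat([0, 1], 4)
        x2 = np.tile(np.repeat([0, 1], 2), 2)
        x3 = np.tile([0, 1], 4)
        assert it.msu([x1, x2, x3]) == pytest.approx(0.0, abs=1e-12)

    def test_capacity_guard(self):
        rng = np.random.default_rng(7)
        cols = [rng.integers(0, 100, 50) for _ in range(5)]
        with pytest.raises(it.CapacityError):
            it.joint_entropy_multi(cols)

    @given(st.lists(st.integers(0, 2), min_size=6, max_size=40),
           st.lists(st.integers(0, 2), min_size=6, max_size=40),
           st.lists(st.integers(0, 2), min_size=6, max_size=40))
    def test_entropy_ratio_inequality_chain(self, a, b, c):
        n = min(len(a), len(b), len(c))
        cols = [np.array(v[:n]) for v in (a, b, c)]
        marg = sum(it.entropy(v) for v in cols)
        if marg == 0:
            return
        ratio = it.joint_entropy_multi(cols) / marg
        assert 1.0 / 3 - 1e-9 <= ratio <= 1.0 + 1e-9

    @given(labels, labels, st.permutations(list(range(4))))
    def test_relabeling_invariance(self, xs, ys, perm):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        x2 = np.array([perm[v] for v in x])
        assert it.mutual_information(x, y) == pytest.approx(
            it.mutual_information(x2, y), abs=1e-12)
        assert it.entropy(x) == pytest.approx(it.entropy(x2), abs=1e-12)


class TestPearson:
    def test_exact_linear(self):
        x = np.array([1.0, 2, 3, 4])
        assert it.pearson(x, 2 * x) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_quadratic_zero(self):
        x = np.array([-1.0, 0.0, 1.0])
        assert it.pearson(x, x ** 2) == pytest.approx(0.0, abs=1e-12)

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5000)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=5000)
        assert it.pearson(x, y) == pytest.approx(0.8, abs=0.02)

    def test_constant_flagged(self):
        assert np.isnan(it.pearson(np.ones(5), np.arange(5.0)))
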