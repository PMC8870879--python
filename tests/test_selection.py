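"""FC-MSU filter, ReliefF weighting, rank fusion and the Pearson baseline."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from cuffbp import selection as sel
from cuffbp import synth
from cuffbp.regression import ElasticNetRegressor


@pytest.fixture(scope="module")
def table_and_roles():
    tab = synth.generate_feature_table(n_rows=2000, seed=1)
    return tab.features, tab.targets["y"].to_numpy(), tab.metadata["roles"]


class TestRelevanceStep:
    def test_target_copy_ranks_first_with_unit_su(self, table_and_roles):
        X, y, _ = table_and_roles
        X = X.copy()
        X["oracle"] = y
        ranking, s1 = sel.fc_step1_relevance(X, y)
        assert ranking[0][0] == "oracle"
        assert ranking[0][1] == pytest.approx(1.0, abs=1e-9)
        assert "oracle" in s1

    def test_zero_threshold_keeps_everything(self, table_and_roles):
        X, y, _ = table_and_roles
        cfg = sel.SelectionConfig(relevance_threshold=0.0)
        _, s1 = sel.fc_step1_relevance(X, y, cfg)
        assert set(s1) == set(X.columns)

    def test_relevant_in_noise_out(self):
        good = 0
        for seed in range(10):
            tab = synth.generate_feature_table(n_rows=2000, seed=seed)
            roles = tab.metadata["roles"]
            _, s1 = sel.fc_step1_relevance(tab.features, tab.targets["y"])
            relevant = {c for c, r in roles.items() if r.startswith("relevant")}
            noise = {c for c, r in roles.items() if r == "noise"}
            good += relevant <= set(s1) and not (noise & set(s1))
        assert good >= 9


class TestRedundancyStep:
    def test_exact_duplicate_eliminated(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1, 1, 1000)
        y = x + 0.2 * rng.normal(size=1000)
        X = pd.DataFrame({"f1": x, "f2": x.copy(), "other": rng.uniform(-1, 1, 1000)})
        res = sel.select_features(X, y)
        assert ("f1" in res.s_prime) != ("f2" in res.s_prime)
        # equal SU -> tie broken by column order
        assert "f1" in res.s_prime

    def test_huge_p_keeps_s1(self, table_and_roles):
        X, y, _ = table_and_roles
        cfg = sel.SelectionConfig(p_start=50.0, p_floor=50.0, msu_stop=1e-9)
        ranking, s1 = sel.fc_step1_relevance(X, y, cfg)
        s_prime, log, _, _ = sel.fc_step2_redundancy(s1, X, y, cfg,
                                                     dict(ranking))
        assert set(s_prime) == set(s1) and not log

    def test_removal_log_reconstructs_s_prime(self, table_and_roles):
        X, y, _ = table_and_roles
        res = sel.select_features(X, y)
        removed = {entry["removed"] for entry in res.removal_log}
        assert set(res.s1) - removed == set(res.s_prime)
        for entry in res.removal_log:
            assert entry["by"] in res.s1
            assert entry["su_pair"] >= entry["p"] * entry["su_target"] - 1e-12

    def test_s_prime_subset_chain(self, table_and_roles):
        X, y, _ = table_and_roles
        res = sel.select_features(X, y)
        assert set(res.s_prime) <= set(res.s1) <= set(X.columns)

    def test_column_permutation_invariance(self, table_and_roles):
        X, y, _ = table_and_roles
        res_a = sel.select_features(X, y)
        rng = np.random.default_rng(3)
        perm = list(rng.permutation(list(X.columns)))
        res_b = sel.select_features(X[perm], y)
        assert set(res_a.s_prime) == set(res_b.s_prime)


class TestReliefF:
    @pytest.mark.parametrize("v1, v2, lo, hi, expected", [
        (2.0, 5.0, 0.0, 10.0, 0.3),
        (0.0, 10.0, 0.0, 10.0, 1.0),
        (4.0, 4.0, 0.0, 10.0, 0.0),
    ])
    def test_numeric_diff(self, v1, v2, lo, hi, expected):
        assert sel.relieff_diff(v1, v2, lo, hi) == pytest.approx(expected)

    def test_nominal_diff(self):
        assert sel.relieff_diff("a", "a", 0, 0, kind="nominal") == 0.0
        assert sel.relieff_diff("a", "b", 0, 0, kind="nominal") == 1.0

    def test_zero_range_flagged_as_zero(self):
        assert sel.relieff_diff(1.0, 1.0, 5.0, 5.0) == 0.0

    def test_interacting_pair_beats_noise(self):
        good = 0
        for seed in range(10):
            tab = synth.generate_feature_table(
                n_rows=2000, n_relevant_linear=0, n_relevant_nonlinear=0,
                n_redundant=0, n_noise=10, n_interacting=2, noise_sd=0.1,
                seed=seed)
            w = dict(sel.relieff_weights(tab.features, tab.targets["y"]))
            noise_max = max(v for k, v in w.items() if k.startswith("noise"))
            good += w["int_a"] > noise_max and w["int_b"] > noise_max
        assert good >= 9

    def test_pure_noise_weights_small(self):
        tab = synth.generate_feature_table(
            n_rows=2000, n_relevant_linear=1, n_relevant_nonlinear=0,
            n_redundant=0, n_noise=10, seed=4)
        cfg = sel.SelectionConfig(prerank_fraction=1.0)
        w = dict(sel.relieff_weights(tab.features, tab.targets["y"], cfg))
        assert all(abs(w[k]) < 0.05 for k in w if k.startswith("noise"))

    def test_class_indicator_dominates(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 5, 600).astype(float)
        X = pd.DataFrame({
            "indicator": y + 0.001 * rng.normal(size=600),
            "junk1": rng.normal(size=600),
            "junk2": rng.normal(size=600),
        })
        w = sel.relieff_weights(X, y, sel.SelectionConfig(prerank_fraction=1.0))
        assert w[0][0] == "indicator"


class TestFusionAndBaseline:
    def test_identical_orders_preserved(self):
        order = ["a", "b", "c"]
        assert sel.fuse_rankings(order, order, 3) == order

    def test_mean_rank_arithmetic(self):
        fused = sel.fuse_rankings(["a", "b", "c"], ["c", "a", "b"], 3,
                                  universe=["a", "b", "c"])
        # mean ranks: a=1.5, b=2.5, c=2.0
        assert fused == ["a", "c", "b"]

    def test_absent_feature_gets_worst_rank(self):
        fused = sel.fuse_rankings(["a", "b"], ["a"], 3, universe=["a", "b", "c"])
        assert fused == ["a", "b", "c"]

    def test_planted_features_fill_topk(self):
        good = 0
        for seed in range(10):
            tab = synth.generate_feature_table(n_rows=2000, seed=seed)
            roles = tab.metadata["roles"]
            planted = {c for c, r in roles.items() if r.startswith("relevant")}
            cfg = sel.SelectionConfig(top_k=len(planted))
            res = sel.select_features(tab.features, tab.targets["y"], cfg)
            good += planted == set(res.fused_rank)
        assert good >= 9

    def test_linear_feature_outranks_quadratic_in_pearson(self):
        rng = np.random.default_rng(6)
        x1 = rng.uniform(-1, 1, 2000)
        x2 = rng.uniform(-1, 1, 2000)
        y = 2 * x1 + x2 ** 2 + 0.1 * rng.normal(size=2000)
        X = pd.DataFrame({"linear": x1, "quadratic": x2,
                          "dup": 2 * x1 + 0.01 * rng.normal(size=2000)})
        ranking = sel.pearson_baseline_rank(X, y)
        names = [c for c, _ in ranking]
        assert names.index("linear") < names.index("quadratic")
        assert names.index("quadratic") == len(names) - 1
        assert abs(names.index("dup") - names.index("linear")) == 1

    def test_constant_column_ranked_last(self):
        X = pd.DataFrame({"x": np.arange(100.0), "c": np.ones(100)})
        ranking = sel.pearson_baseline_rank(X, np.arange(100.0))
        assert ranking[-1][0] == "c" and np.isnan(ranking[-1][1])


class TestSklearnEstimators:
    def test_selector_in_pipeline(self, table_and_roles):
        X, y, roles = table_and_roles
        pipe = Pipeline([
            ("select", sel.HybridFeatureSelector(top_k=8)),
            ("model", ElasticNetRegressor(lam=1.0, alpha=0.5)),
        ])
        pipe.fit(X, y)
        pred = pipe.predict(X)
        assert pred.shape == (len(X),)
        support = pipe["select"].get_support()
        assert support.sum() == 8

    def test_clone_and_get_params(self):
        est = sel.HybridFeatureSelector(top_k=5, relieff_k=7)
        c = clone(est)
        assert c.get_params()["top_k"] == 5
        assert c.get_params()["relieff_k"] == 7

    def test_pearson_selector_transform_shape(self, table_and_roles):
        X, y, _ = table_and_roles
        est = sel.PearsonCorrelationSelector(top_k=4).fit(X, y)
        assert est.transform(X).shape == (len(X), 4)
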