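"""Multilevel GLM, variance partitioning and mediation inference."""

import numpy as np
import pytest

import painsig as ps
from painsig.inference import (
    zscore_within, apply_coding, multilevel_glm, MultilevelGLM,
    variance_partition, mediate_multilevel, mediate_three_path,
)


class TestZscoreWithin:
    def test_symmetric_three_point(self):
        out = zscore_within([[1.0, 2.0, 3.0]])
        assert np.allclose(out[0], [-1.0, 0.0, 1.0])

    def test_moments(self, rng):
        out = zscore_within([rng.standard_normal(50) * 3 + 7])[0]
        assert abs(out.mean()) < 1e-12
        assert np.isclose(out.std(ddof=1), 1.0)

    def test_constant_input_names_subject(self):
        with pytest.raises(ValueError, match="sub-07"):
            zscore_within([[1.0, 2.0], [3.0, 3.0]],
                          subject_ids=["sub-03", "sub-07"])

    def test_coding_map(self):
        codes = apply_coding(["LM", "HM", "LM"], {"LM": 1, "HM": -1})
        assert codes.tolist() == [1.0, -1.0, 1.0]
        with pytest.raises(ValueError, match="absent"):
            apply_coding(["LL"], {"LM": 1})


class TestMultilevelGLM:
    def test_exact_linear_relation(self, rng):
        X = [rng.standard_normal(20) for _ in range(5)]
        Y = [2.0 * x for x in X]
        res = multilevel_glm(X, Y, n_boot=999, seed=0)
        assert np.isclose(res.coef[0], 2.0)
        assert np.isclose(res.R2_full, 1.0)
        assert res.p_boot[0] <= 2.0 / 1000 + 1e-12

    def test_eb_degeneracy_equal_variances(self, rng):
        # equal first-level variances -> weighted mean == unweighted mean
        X, Y = [], []
        x0 = rng.standard_normal(30)
        for i in range(6):
            e = rng.standard_normal(30)
            e = e - e.mean()
            e = e - (e @ x0) / (x0 @ x0) * x0  # exactly orthogonal residual
            e /= e.std()
            Y.append((1.0 + 0.2 * i) * x0 + e)
            X.append(x0)
        res = multilevel_glm(X, Y, n_boot=50, seed=0)
        assert np.isclose(res.coef[0], res.subject_coefs[:, 0].mean(), atol=1e-8)

    def test_null_predictor_has_no_unique_variance(self, rng):
        u = []
        for _ in range(30):
            X = [np.column_stack([rng.standard_normal(40),
                                  rng.standard_normal(40)]) for _ in range(6)]
            Y = [0.8 * x[:, 0] + rng.standard_normal(40) for x in X]
            res = multilevel_glm(X, Y, n_boot=20, seed=0)
            u.append(res.unique_R2[1])
        assert np.mean(u) < 0.05
        assert np.mean(u) > 0  # dropping a fitted column always costs a bit

    def test_needs_three_subjects(self, rng):
        with pytest.raises(ValueError):
            multilevel_glm([rng.standard_normal(10)] * 2,
                           [rng.standard_normal(10)] * 2, n_boot=10)

    def test_estimator_reproducible(self, rng):
        X = [rng.standard_normal(15) for _ in range(4)]
        Y = [x + rng.standard_normal(15) for x in X]
        a = MultilevelGLM(n_boot=200, random_state=7).fit(X, Y)
        b = MultilevelGLM(n_boot=200, random_state=7).fit(X, Y)
        assert a.p_boot_ == pytest.approx(b.p_boot_)


class TestVariancePartition:
    def test_single_perfect_predictor(self, rng):
        X = [rng.standard_normal(20) for _ in range(4)]
        Y = [3.0 * x for x in X]
        vp = variance_partition(X, Y, n_perm=199, seed=0)
        assert np.isclose(vp["unique_R2"][0], 1.0)
        assert vp["perm_p"][0] <= 2.0 / 200 + 1e-12

    def test_shared_variance_has_no_unique_part(self, rng):
        X, Y = [], []
        for _ in range(4):
            x1 = rng.standard_normal(40)
            x2 = x1 + 1e-3 * rng.standard_normal(40)  # near-duplicate
            X.append(np.column_stack([x1, x2]))
            Y.append(x1 + 0.3 * rng.standard_normal(40))
        vp = variance_partition(X, Y, n_perm=99, seed=0)
        assert vp["R2_full"] > 0.8
        assert np.all(vp["unique_R2"] < 0.05)

    def test_permutation_null_distribution_brackets_null_stat(self, rng):
        # a genuinely null predictor's observed unique R2 is typical of its null
        X = [np.column_stack([rng.standard_normal(30),
                              rng.standard_normal(30)]) for _ in range(5)]
        Y = [x[:, 0] + rng.standard_normal(30) for x in X]
        vp = variance_partition(X, Y, predictors=[1], n_perm=200, seed=1)
        assert vp["perm_p"][1] > 0.05


def _orth(v, *others):
    v = v - v.mean()
    for o in others:
        v = v - (v @ o) / (o @ o) * o
    return v


class TestMediation:
    def _exact_chain_subject(self, seed):
        rng = np.random.default_rng(seed)
        X = np.tile([1.0, -1.0], 6)
        e = _orth(rng.standard_normal(12), X)
        M = X + 0.5 * e  # a = 1 exactly (e orthogonal to X)
        Y = 2.0 * M  # b = 2, c' = 0 exactly
        return X, M, Y

    def test_exact_chain_paths(self):
        subs = [self._exact_chain_subject(s) for s in range(3)]
        res = mediate_multilevel([s[0] for s in subs], [s[1] for s in subs],
                                 [s[2] for s in subs], n_boot=99, seed=0)
        assert np.isclose(res["a_1"].estimate, 1.0)
        assert np.isclose(res["b_1"].estimate, 2.0)
        assert np.isclose(res["c_prime"].estimate, 0.0, atol=1e-10)
        assert np.isclose(res["ab_1"].estimate, 2.0)
        assert np.isclose(res["c"].estimate, 2.0)

    def test_decomposition_identity_with_covariates(self, rng):
        X, M, Y, C = [], [], [], []
        for _ in range(6):
            x = rng.choice([-1.0, 1.0], 25)
            c = rng.standard_normal(25)
            m = 0.4 * x + 0.2 * c + rng.standard_normal(25)
            y = 0.5 * m + 0.3 * x + 0.1 * c + rng.standard_normal(25)
            X.append(x), M.append(m), Y.append(y), C.append(c)
        res = mediate_multilevel(X, M, Y, cov_list=C, n_boot=50, seed=0)
        gap = (res["c"].per_subject
               - res["c_prime"].per_subject - res["ab_1"].per_subject)
        assert np.abs(gap).max() < 1e-8

    def test_label_coding(self, rng):
        X = [np.array(["LM", "HM"] * 10, dtype=object) for _ in range(3)]
        M = [rng.standard_normal(20) for _ in range(3)]
        Y = [rng.standard_normal(20) for _ in range(3)]
        res = mediate_multilevel(X, M, Y, coding={"LM": 1, "HM": -1},
                                 n_boot=20, seed=0)
        assert "ab_1" in res.paths
        with pytest.raises(ValueError, match="absent"):
            mediate_multilevel(X, M, Y, coding={"LM": 1}, n_boot=20, seed=0)

    def test_null_mediator_group_ab_near_zero(self):
        estimates = []
        for s in range(30):
            rng = np.random.default_rng(s)
            X = [rng.choice([-1.0, 1.0], 30) for _ in range(10)]
            M = [rng.standard_normal(30) for _ in range(10)]
            Y = [rng.standard_normal(30) for _ in range(10)]
            res = mediate_multilevel(X, M, Y, n_boot=20, seed=s)
            estimates.append(res["ab_1"].estimate)
        est = np.array(estimates)
        assert abs(est.mean()) < 3 * est.std(ddof=1) / np.sqrt(30)

    def test_two_mediators_controlling_each_other(self, rng):
        X, M, Y = [], [], []
        for _ in range(8):
            x = rng.choice([-1.0, 1.0], 40)
            m1 = 0.8 * x + rng.standard_normal(40)
            m2 = rng.standard_normal(40)  # not on the causal path
            y = 0.7 * m1 + rng.standard_normal(40)
            X.append(x), M.append(np.column_stack([m1, m2])), Y.append(y)
        res = mediate_multilevel(X, M, Y, n_boot=500, seed=0)
        assert res["ab_1"].p_two < 0.05
        assert res["ab_2"].p_two > 0.05


class TestThreePathMediation:
    def test_deterministic_unit_chain(self):
        X_l, M1_l, M2_l, Y_l = [], [], [], []
        for s in range(3):
            rng = np.random.default_rng(s)
            X = np.tile([1.0, -1.0], 8)
            e1 = _orth(rng.standard_normal(16), X)
            e2 = _orth(rng.standard_normal(16), X, e1)
            e3 = _orth(rng.standard_normal(16), X, e1, e2)
            M1 = X + e1
            M2 = M1 + e2
            Y = M2 + e3
            X_l.append(X), M1_l.append(M1), M2_l.append(M2), Y_l.append(Y)
        res = mediate_three_path(X_l, M1_l, M2_l, Y_l, n_boot=99, seed=0)
        for name in ("a", "d_1", "b_1", "adb_1"):
            assert np.isclose(res[name].estimate, 1.0, atol=1e-8), name

    def test_broken_link_kills_indirect(self, rng):
        # d = 0: M2 unrelated to M1 -> indirect ~ 0 while a stays planted
        X_l, M1_l, M2_l, Y_l = [], [], [], []
        for _ in range(10):
            X = rng.choice([-1.0, 1.0], 40)
            M1 = 0.8 * X + 0.3 * rng.standard_normal(40)
            M2 = rng.standard_normal(40)
            Y = 0.5 * M2 + rng.standard_normal(40)
            X_l.append(X), M1_l.append(M1), M2_l.append(M2), Y_l.append(Y)
        res = mediate_three_path(X_l, M1_l, M2_l, Y_l, n_boot=500, seed=0)
        assert res["a"].p_two < 0.05
        assert res["b_1"].p_two < 0.05
        assert res["adb_1"].p_two > 0.05
        assert abs(res["adb_1"].estimate) < 3 * res["adb_1"].se

    def test_requires_m1(self, rng):
        est = ps.MultilevelMediation(three_path=True, n_boot=10)
        with pytest.raises(ValueError, match="M1_list"):
            est.fit([rng.standard_normal(10)] * 3,
                    [rng.standard_normal(10)] * 3,
                    [rng.standard_normal(10)] * 3)
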