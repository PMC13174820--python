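"""Statistical battery: regression, FDR, ANCOVA/Tukey, nonparametrics,
CV classification, DeLong, serial mediation, phenotype derivations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import glymphkit as gk
from glymphkit.exceptions import InputError
from glymphkit.stats import adjust_results, tukey_hsd
from glymphkit.synthetic import CohortSpec, make_cohort


def brute_force_bh(p):
    """Independent step-up oracle straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end  # 1-based rank of this p-value
        running_min = min(running_min, p[idx] * m / k)
        adj[idx] = running_min
    return adj


# --------------------------------------------------------------- regression

class TestStandardizedBeta:
    def test_identity_predictor(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 2, 100)
        df = pd.DataFrame({"y": y, "x": y})
        res = gk.standardized_beta("y", "x", [], df)
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.p < 1e-20

    def test_null_betas_small(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(50):
            df = pd.DataFrame({"y": rng.normal(size=200), "x": rng.normal(size=200)})
            pvals.append(gk.standardized_beta("y", "x", [], df).p)
        # p-values approximately uniform under the null
        ks = sps.kstest(pvals, "uniform").pvalue
        assert ks > 0.01

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(2)
        beta_true = 0.4
        hits = 0
        for _ in range(50):
            x = rng.normal(size=300)
            y = beta_true * x + rng.normal(0, np.sqrt(1 - beta_true**2), 300)
            df = pd.DataFrame({"y": y, "x": x})
            res = gk.standardized_beta("y", "x", [], df)
            se = 1.0 / np.sqrt(300)  # approximate SE on standardized scales
            if abs(res.beta - beta_true) < 2.5 * se:
                hits += 1
        assert hits >= 45

    def test_covariate_adjustment_removes_confounder(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=400)
        x = z + rng.normal(0, 0.5, 400)
        y = z + rng.normal(0, 0.5, 400)  # associated only through z
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        raw = gk.standardized_beta("y", "x", [], df)
        adj = gk.standardized_beta("y", "x", ["z"], df)
        assert abs(adj.beta) < abs(raw.beta) / 2

    def test_constant_predictor_raises(self):
        df = pd.DataFrame({"y": np.arange(30.0), "x": np.ones(30)})
        with pytest.raises(InputError):
            gk.standardized_beta("y", "x", [], df)

    def test_sign_consistency(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        df = pd.DataFrame({"y": -x + rng.normal(0, 0.1, 100), "x": x})
        res = gk.standardized_beta("y", "x", [], df)
        assert np.sign(res.beta) == np.sign(res.t) == -1


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(gk.bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert gk.bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_all_ones(self):
        np.testing.assert_array_equal(gk.bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_empty(self):
        assert gk.bh_fdr([]).size == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(gk.bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_geq_raw(self):
        rng = np.random.default_rng(6)
        p = rng.random(20)
        adj = gk.bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    def test_adjust_results_wrapper(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"y": rng.normal(size=50), "x": rng.normal(size=50)})
        results = [gk.standardized_beta("y", "x", [], df)] * 3
        out = adjust_results(results)
        assert all(r.p_adjusted >= r.p - 1e-12 for r in out)


# ------------------------------------------------------------------- ancova

class TestAncova:
    def _data(self, rng, offsets=(0.0, 0.0, 0.0), n=40):
        groups = np.repeat(["CN", "MCI", "AD"], n)
        age = rng.normal(70, 8, 3 * n)
        y = 0.02 * age + np.repeat(offsets, n) + rng.normal(0, 1, 3 * n)
        return pd.DataFrame({"y": y, "group": groups, "age": age})

    def test_no_covariates_equals_anova(self):
        rng = np.random.default_rng(8)
        df = self._data(rng, offsets=(0, 0.3, 0.8))
        res = gk.ancova("y", "group", [], df)
        F, p = sps.f_oneway(*[df.y[df.group == g] for g in ("AD", "CN", "MCI")])
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(9)
        pvals = [gk.ancova("y", "group", ["age"], self._data(rng)).p
                 for _ in range(60)]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_offset_detected(self):
        rng = np.random.default_rng(10)
        rejections = sum(
            gk.ancova("y", "group", ["age"],
                      self._data(rng, offsets=(0, 0, 1.0), n=50)).p < 0.05
            for _ in range(20))
        assert rejections >= 18  # power >> 5 %

    def test_matches_nested_rss_computation(self):
        rng = np.random.default_rng(11)
        df = self._data(rng, offsets=(0, 0.5, 1.0))
        res = gk.ancova("y", "group", ["age"], df)
        import statsmodels.formula.api as smf

        full = smf.ols("y ~ C(group) + age", df).fit()
        red = smf.ols("y ~ age", df).fit()
        F = ((red.ssr - full.ssr) / 2) / (full.ssr / full.df_resid)
        assert res.F == pytest.approx(F, rel=1e-10)

    def test_single_group_raises(self):
        df = pd.DataFrame({"y": np.arange(10.0), "group": ["a"] * 10})
        with pytest.raises(InputError):
            gk.ancova("y", "group", [], df)


class TestTukeyHsd:
    def test_two_groups_equals_t_test(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({
            "y": np.concatenate([rng.normal(0, 1, 30), rng.normal(0.9, 1, 30)]),
            "group": np.repeat(["a", "b"], 30)})
        res = gk.ancova("y", "group", [], df)
        tk = tukey_hsd(res)
        t, p = sps.ttest_ind(df.y[df.group == "a"], df.y[df.group == "b"])
        assert tk.p_adj[0] == pytest.approx(p, rel=1e-8)

    def test_identical_means_p_near_one(self):
        df = pd.DataFrame({"y": np.tile(np.arange(20.0), 3),
                           "group": np.repeat(["a", "b", "c"], 20)})
        tk = tukey_hsd(gk.ancova("y", "group", [], df))
        assert (tk.p_adj > 0.999).all()

    def test_only_shifted_group_significant(self):
        rng = np.random.default_rng(13)
        y = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50),
                            rng.normal(1.5, 1, 50)])
        df = pd.DataFrame({"y": y, "group": np.repeat(["a", "b", "c"], 50)})
        tk = tukey_hsd(gk.ancova("y", "group", [], df)).set_index(["group_a", "group_b"])
        assert tk.loc[("a", "c"), "p_adj"] < 0.01
        assert tk.loc[("b", "c"), "p_adj"] < 0.01
        assert tk.loc[("a", "b"), "p_adj"] > 0.05

    def test_matches_statsmodels_tukey(self):
        rng = np.random.default_rng(14)
        y = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.5, 1, 40),
                            rng.normal(1.0, 1, 40)])
        df = pd.DataFrame({"y": y, "group": np.repeat(["a", "b", "c"], 40)})
        tk = tukey_hsd(gk.ancova("y", "group", [], df))
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        sm_tk = pairwise_tukeyhsd(df.y, df.group)
        np.testing.assert_allclose(tk.p_adj.to_numpy(), sm_tk.pvalues, atol=1e-6)


class TestRankAncovaWilcoxon:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({
            "y": rng.lognormal(0, 1, 90),
            "group": np.repeat(["a", "b", "c"], 30),
            "age": rng.normal(70, 5, 90)})
        res1, _ = gk.rank_ancova_wilcoxon("y", "group", ["age"], df)
        df2 = df.assign(y=np.log(df.y))
        res2, _ = gk.rank_ancova_wilcoxon("y", "group", ["age"], df2)
        assert res1.F == pytest.approx(res2.F, rel=1e-10)

    def test_wilcoxon_exact_enumeration(self):
        # (1,2,3) vs (4,5,6): 1 of C(6,3)=20 assignments is as extreme
        df = pd.DataFrame({"y": [1, 2, 3, 4, 5, 6],
                           "group": ["a"] * 3 + ["b"] * 3})
        _, pairs = gk.rank_ancova_wilcoxon("y", "group", [], df, alternative="less")
        assert pairs.p[0] == pytest.approx(0.05, abs=1e-12)

    def test_heavy_tail_type_i_controlled(self):
        rng = np.random.default_rng(16)
        rejections = 0
        for _ in range(100):
            df = pd.DataFrame({"y": rng.standard_cauchy(60),
                               "group": np.repeat(["a", "b"], 30)})
            _, pairs = gk.rank_ancova_wilcoxon("y", "group", [], df)
            rejections += pairs.p[0] < 0.05
        assert rejections <= 12  # ~5 % nominal


# ----------------------------------------------------- classification + AUC

class TestCvClassify:
    def _xy(self, rng, n=100, sep=3.0):
        y = rng.integers(0, 2, n)
        X = np.column_stack([sep * y + rng.normal(0, 1, n), rng.normal(0, 1, n)])
        return X, y

    def test_separable_auc_near_one(self):
        rng = np.random.default_rng(17)
        X, y = self._xy(rng, sep=10.0)
        assert gk.cv_classify(X, y).auc > 0.99

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(18)
        aucs = []
        for _ in range(10):
            X = rng.normal(size=(120, 3))
            y = rng.integers(0, 2, 120)
            if y.sum() < 10 or y.sum() > 110:
                continue
            aucs.append(gk.cv_classify(X, y).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(19)
        X, y = self._xy(rng)
        r1 = gk.cv_classify(X, y, seed=42)
        r2 = gk.cv_classify(X, y, seed=42)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        np.testing.assert_array_equal(r1.fold_of_subject, r2.fold_of_subject)

    def test_single_class_raises(self):
        with pytest.raises(InputError):
            gk.cv_classify(np.random.rand(30, 2), np.ones(30))

    @pytest.mark.parametrize("model", ["svm-linear", "svm-rbf", "gboost"])
    def test_other_models_run(self, model):
        rng = np.random.default_rng(20)
        X, y = self._xy(rng, sep=5.0)
        assert gk.cv_classify(X, y, model=model).auc > 0.9


class TestDelong:
    def test_identical_scores(self):
        rng = np.random.default_rng(21)
        y = rng.integers(0, 2, 50)
        s = rng.normal(size=50)
        res = gk.delong_test(s, s, y)
        assert res.delta == 0.0
        assert res.p == 1.0

    def test_perfect_ranking_auc_one(self):
        y = np.array([0, 1] * 25)
        res = gk.delong_test(y.astype(float), np.random.default_rng(22).normal(size=50), y)
        assert res.auc_a == 1.0

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(23)
        n = 60
        y = rng.integers(0, 2, n)
        a = y + rng.normal(0, 1.0, n)
        b = y + rng.normal(0, 1.5, n)
        res = gk.delong_test(a, b, y)

        def auc(s):
            r = sps.rankdata(s)
            m = (y == 1).sum()
            return (r[y == 1].sum() - m * (m + 1) / 2) / (m * (n - m))

        obs = abs(auc(a) - auc(b))
        prng = np.random.default_rng(24)
        count = 0
        B = 10000
        for _ in range(B):
            swap = prng.random(n) < 0.5
            if abs(auc(np.where(swap, b, a)) - auc(np.where(swap, a, b))) >= obs - 1e-12:
                count += 1
        p_perm = count / B
        assert res.p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / B) + 0.01)

    def test_variance_approaches_hanley_mcneil(self):
        # independent scores: DeLong variance ~ closed-form for a single AUC
        rng = np.random.default_rng(25)
        n = 4000
        y = np.repeat([0, 1], n // 2)
        a = y * 0.5 + rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)  # unrelated -> near-zero covariance
        res = gk.delong_test(a, b, y)
        assert res.p < 1e-4  # real difference detected at this n


# ---------------------------------------------------------------- mediation

class TestSerialMediation:
    def _chain(self, n=2000, a1=0.5, a2=0.5, b=0.5, c_prime=0.0, sd=0.2, seed=0):
        ph, _, _ = make_cohort(CohortSpec(n=n, a1=a1, a2=a2, b=b, c_prime=c_prime,
                                          mediation_noise_sd=sd, seed=seed))
        return ph

    def test_planted_indirect_recovered(self):
        ph = self._chain()
        res = gk.serial_mediation("med_x", "med_m1", "med_m2", "med_y", ph,
                                  n_boot=500, seed=1)
        assert res.indirect == pytest.approx(0.125, abs=0.02)
        assert res.ci_low <= res.indirect <= res.ci_high
        assert res.significant

    def test_ols_decomposition_identity(self):
        ph = self._chain(n=300, seed=5)
        res = gk.serial_mediation("med_x", "med_m1", "med_m2", "med_y", ph,
                                  n_boot=100, seed=2)
        # total = direct + a1*d1 + a3*b + a1*a2*b, exact for nested OLS
        decomp = res.c_prime + res.a1 * res.d1 + res.a3 * res.b + res.a1 * res.a2 * res.b
        assert res.c == pytest.approx(decomp, abs=1e-10)

    def test_reproducible_bit_for_bit(self):
        ph = self._chain(n=400, seed=6)
        r1 = gk.serial_mediation("med_x", "med_m1", "med_m2", "med_y", ph,
                                 n_boot=200, seed=7)
        r2 = gk.serial_mediation("med_x", "med_m1", "med_m2", "med_y", ph,
                                 n_boot=200, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        np.testing.assert_array_equal(r1.boot_indirect, r2.boot_indirect)

    def test_null_ci_contains_zero_mostly(self):
        covered = 0
        reps = 40
        for s in range(reps):
            ph = self._chain(n=300, a1=0.0, sd=1.0, seed=100 + s)
            res = gk.serial_mediation("med_x", "med_m1", "med_m2", "med_y", ph,
                                      n_boot=300, seed=s)
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered >= int(0.85 * reps)

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (200, 3200):
            ph = self._chain(n=n, seed=8)
            res = gk.serial_mediation("med_x", "med_m1", "med_m2", "med_y", ph,
                                      n_boot=300, seed=9)
            widths.append(res.ci_high - res.ci_low)
        assert widths[1] < widths[0] / 2  # ~1/sqrt(16) ideally

    def test_small_sample_warns(self):
        ph = self._chain(n=30, seed=10)
        with pytest.warns(UserWarning, match="recommended"):
            gk.serial_mediation("med_x", "med_m1", "med_m2", "med_y", ph,
                                n_boot=120, seed=11)

    def test_standardize_flag(self):
        ph = self._chain(n=500, seed=12)
        res = gk.serial_mediation("med_x", "med_m1", "med_m2", "med_y", ph,
                                  n_boot=120, seed=13, standardize=True)
        assert np.isfinite(res.indirect)


# ----------------------------------------------------------- phenotype ops

class TestPhenotypeDerivations:
    def test_map_formula(self):
        assert gk.derive_map(120, 80) == pytest.approx(93.3333, abs=1e-3)

    def test_map_fixed_point(self):
        assert gk.derive_map(95.0, 95.0) == pytest.approx(95.0)

    def test_map_linearity(self):
        sys = np.array([110.0, 130.0])
        dia = np.array([70.0, 90.0])
        assert gk.derive_map(sys.mean(), dia.mean()) == pytest.approx(
            np.mean(gk.derive_map(sys, dia)))

    def test_map_rejects_nonpositive(self):
        with pytest.raises(InputError):
            gk.derive_map(0.0, 80.0)

    @pytest.mark.parametrize("suvr,tracer,expected", [
        (1.478, "FBB", False),   # strict inequality at the threshold
        (1.50, "FBB", True),
        (1.20, "AV45", True),
        (1.11, "AV45", False),
        (1.05, "AV45", False),
    ])
    def test_amyloid_thresholds(self, suvr, tracer, expected):
        assert gk.amyloid_positivity(suvr, tracer) is expected

    def test_unknown_tracer(self):
        with pytest.raises(InputError):
            gk.amyloid_positivity(1.5, "PIB")
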