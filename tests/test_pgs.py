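import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from rnsgwas import pgs as pgsmod
from rnsgwas import simulate as sim
from rnsgwas._utils import DegenerateInputError, RnsgwasError


def make_cohort(dosage, phenotype, covariates=None, freq=None):
    dosage = np.asarray(dosage)
    n, p = dosage.shape
    cov = covariates if covariates is not None else pd.DataFrame(
        {"sex": np.zeros(n)}
    )
    return sim.CohortData(
        dosage=dosage,
        phenotype=np.asarray(phenotype),
        covariates=cov,
        snp_ids=np.array([f"s{i}" for i in range(p)]),
        effect_allele=np.array(["G"] * p),
        freq=freq if freq is not None else np.full(p, 0.5),
    )


def random_cohort(n=300, p=20, seed=0, signal=0.0):
    rng = np.random.default_rng(seed)
    freq = rng.uniform(0.1, 0.9, size=p)
    dosage = rng.binomial(2, freq, size=(n, p))
    beta = rng.normal(0, signal, size=p) if signal else np.zeros(p)
    liab = dosage @ beta + rng.normal(size=n)
    pheno = (liab > np.median(liab)).astype(int)
    cov = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float),
                        "age": rng.normal(40, 10, n)})
    return make_cohort(dosage, pheno, cov, freq), beta


class TestComputePgs:
    def test_single_snp_definition(self):
        cohort = make_cohort([[2], [0]], [1, 0])
        w = pd.Series([np.log(1.5)], index=["s0"])
        raw = pgsmod.compute_pgs(cohort, w, standardize=False)
        assert np.isclose(raw[0], 2 * np.log(1.5)) and raw[1] == 0.0

    def test_zero_weights_standardization_error(self):
        cohort = make_cohort([[2, 1], [0, 1], [1, 0]], [1, 0, 1])
        w = pd.Series([0.0, 0.0], index=["s0", "s1"])
        with pytest.raises(DegenerateInputError):
            pgsmod.compute_pgs(cohort, w)
        raw = pgsmod.compute_pgs(cohort, w, allow_zero_variance=True)
        assert np.allclose(raw, 0.0)

    def test_sign_flip_negates_raw_scores(self):
        cohort, _ = random_cohort(n=50, p=10, seed=1)
        w = pd.Series(np.random.default_rng(2).normal(size=10),
                      index=[f"s{i}" for i in range(10)])
        a = pgsmod.compute_pgs(cohort, w, standardize=False)
        b = pgsmod.compute_pgs(cohort, -w, standardize=False)
        np.testing.assert_allclose(a, -b)

    def test_missing_dosage_mean_imputed(self):
        dosage = np.array([[2], [-1], [0]])
        cohort = make_cohort(dosage, [1, 0, 0], freq=np.array([0.25]))
        w = pd.Series([1.0], index=["s0"])
        raw = pgsmod.compute_pgs(cohort, w, standardize=False)
        assert np.isclose(raw[1], 2 * 0.25)

    def test_order_invariance_and_additivity(self):
        cohort, _ = random_cohort(n=40, p=8, seed=3)
        ids = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(4)
        w = pd.Series(rng.normal(size=8), index=ids)
        a = pgsmod.compute_pgs(cohort, w, standardize=False)
        b = pgsmod.compute_pgs(cohort, w.iloc[::-1], standardize=False)
        np.testing.assert_allclose(a, b)
        left = pgsmod.compute_pgs(cohort, w.iloc[:4], standardize=False)
        right = pgsmod.compute_pgs(cohort, w.iloc[4:], standardize=False)
        np.testing.assert_allclose(a, left + right)


def direct_nagelkerke(x, y):
    """Oracle: fit both logistic models by direct likelihood optimization."""

    def nll(params, design):
        eta = design @ params
        return np.sum(np.logaddexp(0, eta)) - np.sum(y * eta)

    n = len(y)
    ones = np.ones((n, 1))
    full = np.column_stack([ones, x])
    ll_null = -optimize.minimize(nll, x0=np.zeros(1), args=(ones,),
                                 method="BFGS").fun
    ll_full = -optimize.minimize(nll, x0=np.zeros(full.shape[1]), args=(full,),
                                 method="BFGS").fun
    cs = 1 - np.exp((2 / n) * (ll_null - ll_full))
    return cs / (1 - np.exp((2 / n) * ll_null))


class TestEvaluatePgs:
    @pytest.mark.parametrize("seed", range(6))
    def test_nagelkerke_matches_direct_optimization(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 31))
        x = rng.normal(size=n)
        y = (x + rng.normal(size=n) > 0).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        cohort = make_cohort(
            np.zeros((n, 1), dtype=int), y,
            covariates=pd.DataFrame({"c": np.zeros(n)}),
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = pgsmod.evaluate_pgs(x, cohort)
        expected = direct_nagelkerke(x, y)
        assert abs(ev.r2_full - expected) < 1e-6

    def test_null_score_increment_near_zero_p_uniformish(self):
        rng = np.random.default_rng(9)
        ps, incs = [], []
        for i in range(60):
            cohort, _ = random_cohort(n=200, p=5, seed=100 + i)
            score = rng.normal(size=200)
            ev = pgsmod.evaluate_pgs(score, cohort)
            ps.append(ev.p_assoc_pgs)
            incs.append(ev.pseudo_r2_increment)
        assert np.median(incs) < 0.01
        rate = np.mean(np.asarray(ps) < 0.05)
        assert rate <= 0.15

    def test_identical_likelihoods_zero_increment(self):
        """A score constant across samples adds no likelihood."""
        cohort, _ = random_cohort(n=120, p=5, seed=2)
        ev = pgsmod.evaluate_pgs(np.zeros(120), cohort)
        assert ev.pseudo_r2_increment < 1e-10

    def test_perfect_separation_flagged(self):
        n = 100
        y = np.array([0] * 50 + [1] * 50)
        score = np.concatenate([np.full(50, -3.0), np.full(50, 3.0)])
        cohort = make_cohort(np.zeros((n, 1), dtype=int), y,
                             covariates=pd.DataFrame({"c": np.zeros(n)}))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = pgsmod.evaluate_pgs(score, cohort)
        assert ev.r2_full > 0.95
        assert ev.separation_flag


def trend_table(n_snps, rng, weight_scale=0.1):
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n_snps)],
            "p_assoc": rng.uniform(0, 0.19, size=n_snps),
            "p_rns": rng.uniform(size=n_snps),
            "weight": rng.normal(0, weight_scale, size=n_snps),
        }
    )


class TestQuantileTrend:
    def test_bins_partition_input(self):
        rng = np.random.default_rng(0)
        tab = trend_table(205, rng)
        cohort, _ = random_cohort(n=200, p=205, seed=5)
        trend = pgsmod.quantile_trend(tab, cohort, n_quantiles=20, p_t=0.2,
                                      min_per_bin=10)
        sizes = [e.n_snps for e in trend.per_quantile]
        assert sum(sizes) == 205
        assert sizes[:-1] == [10] * 19 and sizes[-1] == 15

    def test_too_few_snps_rejected(self):
        rng = np.random.default_rng(1)
        tab = trend_table(50, rng)
        cohort, _ = random_cohort(n=100, p=50, seed=6)
        with pytest.raises(RnsgwasError):
            pgsmod.quantile_trend(tab, cohort, n_quantiles=20, p_t=0.2)

    def test_signal_concentrated_in_low_p_rns_gives_negative_slope(self):
        """SNPs with small p_rns carry the causal weights: the pseudo-R^2
        declines across quantiles."""
        rng = np.random.default_rng(12)
        n, p = 500, 200
        freq = rng.uniform(0.2, 0.8, size=p)
        dosage = rng.binomial(2, freq, size=(n, p))
        beta = np.zeros(p)
        causal = np.arange(40)           # the low-p_rns SNPs
        beta[causal] = rng.normal(0, 0.25, size=40)
        liab = (dosage - 2 * freq) @ beta + rng.normal(size=n) * 1.0
        pheno = (liab > np.quantile(liab, 0.5)).astype(int)
        cohort = make_cohort(dosage, pheno,
                             pd.DataFrame({"c": rng.normal(size=n)}), freq)
        tab = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(p)],
                "p_assoc": rng.uniform(0, 0.19, size=p),
                "p_rns": np.concatenate([
                    rng.uniform(0, 0.05, 40), rng.uniform(0.2, 1.0, p - 40)
                ]),
                "weight": beta + rng.normal(0, 0.02, size=p),
            }
        )
        trend = pgsmod.quantile_trend(tab, cohort, n_quantiles=10, p_t=0.2)
        assert trend.slope < 0 and trend.t_stat < 0


class TestMatchedNullPgs:
    def test_target_above_all_nulls_gets_minimal_p(self):
        rng = np.random.default_rng(3)
        n, p = 300, 60
        freq = rng.uniform(0.2, 0.8, size=p)
        dosage = rng.binomial(2, freq, size=(n, p))
        beta = np.zeros(p)
        beta[:10] = 0.8
        liab = (dosage - 2 * freq) @ beta + rng.normal(size=n)
        pheno = (liab > np.median(liab)).astype(int)
        cohort = make_cohort(dosage, pheno,
                             pd.DataFrame({"c": np.zeros(n)}), freq)
        weights = pd.Series(beta + rng.normal(0, 0.01, p),
                            index=[f"s{i}" for i in range(p)])
        target = [f"s{i}" for i in range(10)]
        nulls = [
            [f"s{j}" for j in rng.choice(np.arange(10, p), 10, replace=False)]
            for _ in range(19)
        ]
        res = pgsmod.matched_null_pgs(target, nulls, cohort, weights)
        assert res.empirical_p == 1 / 20

    def test_no_sets_rejected(self):
        cohort, _ = random_cohort(n=100, p=10, seed=7)
        w = pd.Series(np.ones(10), index=[f"s{i}" for i in range(10)])
        with pytest.raises(RnsgwasError):
            pgsmod.matched_null_pgs(["s0"], [], cohort, w)


class TestDirectionStratified:
    def make_inputs(self, seed=0, n=240, p=120):
        rng = np.random.default_rng(seed)
        freq = rng.uniform(0.2, 0.8, size=p)
        dosage = rng.binomial(2, freq, size=(n, p))
        pheno = rng.integers(0, 2, size=n)
        cohort = make_cohort(dosage, pheno,
                             pd.DataFrame({"c": np.zeros(n)}), freq)
        ids = np.array([f"s{i}" for i in range(p)])
        weights = pd.Series(rng.normal(0, 0.1, p), index=ids)
        strata = {
            ("marker", "protective"): list(ids[:30]),
            ("marker", "risk"): list(ids[30:60]),
            ("non_marker", "protective"): list(ids[60:90]),
            ("non_marker", "risk"): list(ids[90:]),
        }
        return strata, cohort, weights

    def test_same_seed_identical_distributions(self):
        strata, cohort, weights = self.make_inputs()
        a = pgsmod.direction_stratified_pgs(strata, cohort, weights,
                                            n_draws=5, n_snps_per_draw=10,
                                            seed=4)
        b = pgsmod.direction_stratified_pgs(strata, cohort, weights,
                                            n_draws=5, n_snps_per_draw=10,
                                            seed=4)
        for k in a.r2_distributions:
            np.testing.assert_array_equal(a.r2_distributions[k],
                                          b.r2_distributions[k])

    def test_exchangeable_strata_have_similar_medians(self):
        strata, cohort, weights = self.make_inputs(seed=5)
        res = pgsmod.direction_stratified_pgs(strata, cohort, weights,
                                              n_draws=40, n_snps_per_draw=15,
                                              seed=6)
        meds = list(res.medians.values())
        assert max(meds) - min(meds) < 0.05

    def test_small_stratum_rejected(self):
        strata, cohort, weights = self.make_inputs()
        strata[("marker", "risk")] = strata[("marker", "risk")][:3]
        with pytest.raises(RnsgwasError, match="marker"):
            pgsmod.direction_stratified_pgs(strata, cohort, weights,
                                            n_draws=5, n_snps_per_draw=10,
                                            seed=1)

    def test_planted_larger_risk_effects_win(self):
        """When risk-derived marker SNPs carry true effects and protective ones
        do not, the risk stratum's median pseudo-R^2 is higher."""
        rng = np.random.default_rng(21)
        n, p = 400, 120
        freq = rng.uniform(0.2, 0.8, size=p)
        dosage = rng.binomial(2, freq, size=(n, p))
        beta = np.zeros(p)
        beta[30:60] = 0.35          # the "risk" marker stratum is causal
        liab = (dosage - 2 * freq) @ beta + rng.normal(size=n) * 2
        pheno = (liab > np.median(liab)).astype(int)
        cohort = make_cohort(dosage, pheno,
                             pd.DataFrame({"c": np.zeros(n)}), freq)
        ids = np.array([f"s{i}" for i in range(p)])
        weights = pd.Series(beta + rng.normal(0, 0.02, p), index=ids)
        strata = {
            ("marker", "protective"): list(ids[:30]),
            ("marker", "risk"): list(ids[30:60]),
            ("non_marker", "protective"): list(ids[60:90]),
            ("non_marker", "risk"): list(ids[90:]),
        }
        res = pgsmod.direction_stratified_pgs(strata, cohort, weights,
                                              n_draws=30, n_snps_per_draw=15,
                                              seed=2)
        assert res.medians["marker_risk"] > res.medians["marker_protective"]
        assert res.wilcoxon_p["marker_risk_vs_protective"] < 0.01
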