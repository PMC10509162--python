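"""Polygenic scoring and selection-stratified score evaluation.

A polygenic score is the per-individual sum of effect-allele dosages
weighted by discovery-GWAS log-odds. Its explanatory value on a
case-control cohort is the increment in Nagelkerke's pseudo-R^2 between a
logistic model with covariates only and one adding the standardized score,

    R^2_N = [1 - exp((2/n)(ll0 - ll1))] / [1 - exp((2/n) ll0)],

with ll0 the intercept-only log-likelihood. The stratified analyses slice
the SNP set by selection evidence (p_RNS quantiles, matched-SNP empirical
nulls, derived-risk vs derived-protective resampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import DegenerateInputError, RnsgwasError, rng_for
from .simulate import CohortData


@dataclass
class PgsEvaluation:
    snp_set_id: str
    n_snps: int
    pseudo_r2_increment: float
    p_assoc_pgs: float
    beta_pgs: float               # log-odds per SD of score
    r2_full: float = np.nan
    r2_covariates: float = np.nan
    separation_flag: bool = False


@dataclass
class QuantileTrend:
    n_quantiles: int
    per_quantile: list[PgsEvaluation]
    slope: float
    t_stat: float
    p_trend: float


@dataclass
class MatchedNullPgs:
    target: PgsEvaluation
    null_r2: np.ndarray
    empirical_p: float
    n_failed: int


@dataclass
class StratifiedPgs:
    r2_distributions: dict[str, np.ndarray]
    medians: dict[str, float]
    wilcoxon_p: dict[str, float]


def compute_pgs(
    cohort: CohortData,
    weights: pd.Series,
    standardize: bool = True,
    allow_zero_variance: bool = False,
) -> np.ndarray:
    """Score = sum over SNPs of dosage x log(OR), standardized across cohort.

    ``weights`` are log-odds indexed by snp_id, oriented to the cohort's
    counted (effect) allele — harmonize first. Missing dosages contribute
    their mean 2*freq*logOR.
    """
    ids = weights.index.to_numpy()
    pos = {s: i for i, s in enumerate(cohort.snp_ids)}
    missing = [s for s in ids if s not in pos]
    if missing:
        raise RnsgwasError(f"weight SNPs absent from cohort: {missing[:10]}")
    cols = np.array([pos[s] for s in ids])
    d = cohort.dosage[:, cols].astype(float)
    f = cohort.freq[cols]
    d = np.where(d < 0, 2.0 * f[None, :], d)
    w = weights.to_numpy(dtype=float)
    raw = d @ w
    if not standardize:
        return raw
    sd = raw.std()
    if sd == 0:
        if allow_zero_variance:
            return raw - raw.mean()
        raise DegenerateInputError("zero-variance score cannot be standardized")
    return (raw - raw.mean()) / sd


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke's rescaled pseudo-R^2 of a model vs the intercept-only null."""
    cs = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    denom = 1.0 - np.exp((2.0 / n) * ll_null)
    if denom <= 0:
        return 0.0
    return float(np.clip(cs / denom, 0.0, 1.0))


class _LogisticEvaluator:
    """Caches the covariate-only and intercept-only fits for repeated scoring.

    Refitting the covariate model for every one of thousands of candidate
    SNP sets would dominate runtime; only the full model depends on the
    score, so the two baselines are fit once.
    """

    def __init__(self, cohort: CohortData, warn_small: bool = True):
        import statsmodels.api as sm

        self._sm = sm
        y = np.asarray(cohort.phenotype, dtype=float)
        n_cases = int(y.sum())
        n_ctrl = int(len(y) - n_cases)
        if warn_small and (n_cases < 50 or n_ctrl < 50):
            warnings.warn(
                f"small cohort ({n_cases} cases / {n_ctrl} controls): "
                "pseudo-R^2 estimates will be noisy"
            )
        self.y = y
        self.n = len(y)
        cov = cohort.covariates.to_numpy(dtype=float)
        # constant covariates are collinear with the intercept
        keep = cov.std(axis=0) > 0
        self.x_cov = sm.add_constant(cov[:, keep], has_constant="add")

        null_model = sm.Logit(y, np.ones((self.n, 1))).fit(disp=0)
        self.ll_null = float(null_model.llf)
        cov_model = self._fit(self.x_cov)
        self.ll_cov = float(cov_model.llf)
        self.r2_cov = nagelkerke_r2(self.ll_cov, self.ll_null, self.n)

    def _fit(self, x):
        sm = self._sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return sm.Logit(self.y, x).fit(disp=0, maxiter=200)
            except Exception:
                return sm.Logit(self.y, x).fit(disp=0, maxiter=500,
                                               method="bfgs")

    def evaluate(self, score: np.ndarray, snp_set_id: str = "",
                 n_snps: int = 0) -> PgsEvaluation:
        sm = self._sm
        x = np.column_stack([self.x_cov, score])
        separation = False
        try:
            fit = self._fit(x)
            if not np.all(np.isfinite(fit.bse)):
                separation = True
            else:
                # (quasi-)separation: probabilities saturated at 0/1 with a
                # perfectly classifying score
                eta = x @ fit.params
                if np.abs(eta).min() > 10 and np.all((eta > 0) == (self.y == 1)):
                    separation = True
        except Exception as exc:
            raise RnsgwasError(
                f"logistic fit failed for set {snp_set_id!r}: {exc}"
            ) from exc
        r2_full = nagelkerke_r2(float(fit.llf), self.ll_null, self.n)
        beta = float(fit.params[-1])
        p = float(fit.pvalues[-1]) if np.isfinite(fit.bse[-1]) else np.nan
        return PgsEvaluation(
            snp_set_id=snp_set_id,
            n_snps=n_snps,
            pseudo_r2_increment=max(r2_full - self.r2_cov, 0.0),
            p_assoc_pgs=p,
            beta_pgs=beta,
            r2_full=r2_full,
            r2_covariates=self.r2_cov,
            separation_flag=separation,
        )


def evaluate_pgs(score: np.ndarray, cohort: CohortData,
                 snp_set_id: str = "pgs", n_snps: int = 0) -> PgsEvaluation:
    """Nagelkerke pseudo-R^2 increment and Wald p of one score on the cohort."""
    return _LogisticEvaluator(cohort).evaluate(score, snp_set_id, n_snps)


def quantile_trend(
    snp_table: pd.DataFrame,
    cohort: CohortData,
    n_quantiles: int = 20,
    p_t: float = 0.2,
    min_per_bin: int = 10,
) -> QuantileTrend:
    """Pseudo-R^2 trend across p_RNS quantiles of the sub-threshold SNPs.

    ``snp_table`` needs columns snp_id, p_assoc, p_rns and weight (log-odds
    oriented to the cohort's counted allele), already restricted to
    LD-independent SNPs. SNPs with p_assoc < p_t are sorted by p_rns and cut
    into ``n_quantiles`` contiguous equal-size bins (remainder to the last);
    each bin is scored and evaluated, and the per-bin pseudo-R^2 increment
    is regressed on the bin rank by OLS.
    """
    sub = snp_table[snp_table["p_assoc"] < p_t].copy()
    if len(sub) < n_quantiles * min_per_bin:
        raise RnsgwasError(
            f"{len(sub)} SNPs below p_t={p_t}: need >= {n_quantiles * min_per_bin}"
        )
    sub = sub.sort_values("p_rns", kind="mergesort").reset_index(drop=True)
    size = len(sub) // n_quantiles
    evaluator = _LogisticEvaluator(cohort)
    evals: list[PgsEvaluation] = []
    for q in range(n_quantiles):
        start = q * size
        end = (q + 1) * size if q < n_quantiles - 1 else len(sub)
        bin_snps = sub.iloc[start:end]
        weights = pd.Series(
            bin_snps["weight"].to_numpy(), index=bin_snps["snp_id"].to_numpy()
        )
        try:
            score = compute_pgs(cohort, weights)
            ev = evaluator.evaluate(score, snp_set_id=f"q{q + 1}", n_snps=len(bin_snps))
        except RnsgwasError as exc:
            raise RnsgwasError(f"quantile bin {q + 1} failed: {exc}") from exc
        evals.append(ev)

    ranks = np.arange(1, n_quantiles + 1, dtype=float)
    r2 = np.array([e.pseudo_r2_increment for e in evals])
    if np.allclose(r2, r2[0]):
        slope, t_stat, p_trend = 0.0, 0.0, 1.0
    else:
        reg = stats.linregress(ranks, r2)
        slope = float(reg.slope)
        t_stat = float(reg.slope / reg.stderr) if reg.stderr > 0 else 0.0
        p_trend = float(reg.pvalue)
    return QuantileTrend(
        n_quantiles=n_quantiles, per_quantile=evals, slope=slope,
        t_stat=t_stat, p_trend=p_trend,
    )


def matched_null_pgs(
    target_ids: list[str],
    matched_sets: list[list[str]],
    cohort: CohortData,
    weights: pd.Series,
    max_failure_frac: float = 0.05,
) -> MatchedNullPgs:
    """Empirical p of the target set's pseudo-R^2 against matched-set nulls.

    Each matched set (same size as the target, matched on genomic
    properties) is scored and evaluated on the same cohort;
    empirical p = (1 + #{null R^2 >= target}) / (n_sets + 1).
    """
    if len(matched_sets) < 1:
        raise RnsgwasError("need at least one matched set")
    evaluator = _LogisticEvaluator(cohort)
    target_score = compute_pgs(cohort, weights.loc[list(target_ids)])
    target_ev = evaluator.evaluate(target_score, "target", len(target_ids))

    null_r2 = []
    n_failed = 0
    for i, snp_set in enumerate(matched_sets):
        try:
            score = compute_pgs(cohort, weights.loc[list(snp_set)])
            ev = evaluator.evaluate(score, f"null_{i}", len(snp_set))
            null_r2.append(ev.pseudo_r2_increment)
        except RnsgwasError:
            n_failed += 1
    if n_failed > max_failure_frac * len(matched_sets):
        raise RnsgwasError(
            f"{n_failed}/{len(matched_sets)} matched sets failed evaluation"
        )
    null_r2 = np.asarray(null_r2)
    emp_p = (1 + int((null_r2 >= target_ev.pseudo_r2_increment).sum())) / (
        len(null_r2) + 1
    )
    return MatchedNullPgs(
        target=target_ev, null_r2=null_r2, empirical_p=float(emp_p),
        n_failed=n_failed,
    )


STRATA = (
    ("marker", "protective"),
    ("marker", "risk"),
    ("non_marker", "protective"),
    ("non_marker", "risk"),
)


def direction_stratified_pgs(
    strata_ids: dict[tuple[str, str], list[str]],
    cohort: CohortData,
    weights: pd.Series,
    n_draws: int = 1000,
    n_snps_per_draw: int = 1000,
    seed: int = 0,
) -> StratifiedPgs:
    """Pseudo-R^2 distributions over random same-size SNP draws per stratum.

    Strata are (marker status) x (derived allele direction). Within a draw,
    SNPs are sampled without replacement; draws are independent and share
    SNPs — the resulting distributions are therefore dependent across draws
    and the Wilcoxon comparisons (risk vs protective within each marker
    status) are descriptive rather than exactly calibrated.
    """
    for key in STRATA:
        ids = strata_ids.get(key, [])
        if len(ids) < n_snps_per_draw:
            raise RnsgwasError(
                f"stratum {key} has {len(ids)} SNPs; needs >= {n_snps_per_draw}"
            )
    evaluator = _LogisticEvaluator(cohort)
    rng = rng_for(seed, "direction-strata")
    dists: dict[str, np.ndarray] = {}
    for key in STRATA:
        name = f"{key[0]}_{key[1]}"
        ids = np.asarray(strata_ids[key])
        r2 = np.empty(n_draws)
        for i in range(n_draws):
            draw = rng.choice(ids, size=n_snps_per_draw, replace=False)
            score = compute_pgs(cohort, weights.loc[list(draw)])
            r2[i] = evaluator.evaluate(score).pseudo_r2_increment
        dists[name] = r2

    wilcoxon = {}
    for status in ("marker", "non_marker"):
        a = dists[f"{status}_risk"]
        b = dists[f"{status}_protective"]
        wilcoxon[f"{status}_risk_vs_protective"] = float(
            stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        )
    medians = {k: float(np.median(v)) for k, v in dists.items()}
    return StratifiedPgs(r2_distributions=dists, medians=medians, wilcoxon_p=wilcoxon)
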