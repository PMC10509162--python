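"""RNS-marker definition and the enrichment statistics cascade.

Markers are the top q% (default 5%) of LD-independent SNPs by selection
p-value. Their relationship with GWAS association is quantified three ways:
Fisher's exact 2x2 tests across association-p thresholds, one-sample
Kolmogorov-Smirnov uniformity tests, and a MAF-adjusted partial Spearman
correlation between -log10 association p and -log10 selection p with a
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import DegenerateInputError, RnsgwasError, rng_for
from .ld_matching import ClumpedSet

#: association-p cutoffs used for the enrichment cascade
DEFAULT_THRESHOLDS = (
    5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5,
)


@dataclass
class RnsAnnotation:
    """Marker flags over the LD-independent SNP set."""

    is_marker: pd.Series        # bool, indexed by index-SNP id
    top_fraction: float
    p_rns: pd.Series

    @property
    def marker_ids(self) -> list[str]:
        return list(self.is_marker.index[self.is_marker])

    @property
    def non_marker_ids(self) -> list[str]:
        return list(self.is_marker.index[~self.is_marker])


@dataclass
class FisherResult:
    p: float
    odds_ratio: float           # sample OR (ad/bc); inf or nan when undefined
    ci_low: float
    ci_high: float
    wald_ci: tuple[float, float] = (np.nan, np.nan)
    degenerate: bool = False    # an all-zero margin: p = 1, OR undefined


@dataclass
class EnrichmentResult:
    threshold: float
    table: tuple[int, int, int, int]   # (a, b, c, d) marker x below-threshold
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_fisher: float
    underpowered: bool = False


@dataclass
class CorrelationResult:
    rho: float
    p_asymptotic: float
    p_perm: float
    n_perm: int
    perm_rhos: np.ndarray = field(repr=False, default=None)


def define_rns_markers(
    clumped: ClumpedSet, p_rns: pd.Series, top_fraction: float = 0.05
) -> RnsAnnotation:
    """Flag the floor(q * N) index SNPs with the smallest selection p.

    Boundary ties are broken by genomic order of the SNP id as it appears
    in ``p_rns``'s index ordering (chrom,pos ordering upstream).
    """
    if not 0 < top_fraction < 1:
        raise RnsgwasError("top_fraction must be in (0,1) exclusive")
    ids = list(clumped.index_snps)
    missing = [s for s in ids if s not in p_rns.index]
    if missing:
        raise RnsgwasError(f"index SNPs without p_rns: {missing[:10]}")
    sub = p_rns.loc[ids]
    # stable ordering: p first, genomic appearance order breaks ties
    appearance = {s: i for i, s in enumerate(p_rns.index)}
    order = sorted(ids, key=lambda s: (sub[s], appearance[s]))
    n_markers = int(np.floor(top_fraction * len(ids)))
    markers = set(order[:n_markers])
    flags = pd.Series([s in markers for s in order], index=order)
    return RnsAnnotation(is_marker=flags, top_fraction=top_fraction, p_rns=sub.loc[order])


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two_sided"
) -> FisherResult:
    """Exact hypergeometric test on the table [[a, b], [c, d]].

    Two-sided p sums point probabilities <= the observed one. The point
    estimate is the sample odds ratio ad/(bc); the 95% CI inverts the
    noncentral hypergeometric tail (exact conditional CI), and a Wald CI on
    the log sample OR is reported alongside.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise RnsgwasError("table entries must be nonnegative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(
        alternative
    )
    if alt is None:
        raise RnsgwasError(f"unknown alternative {alternative!r}")

    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        return FisherResult(p=1.0, odds_ratio=np.nan, ci_low=np.nan,
                            ci_high=np.nan, degenerate=True)

    _, p = stats.fisher_exact(table, alternative=alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = np.divide(a * d, b * c) if b * c > 0 else np.inf
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    if min(a, b, c, d) > 0:
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_or = np.log(sample_or)
        wald = (float(np.exp(log_or - 1.959964 * se)),
                float(np.exp(log_or + 1.959964 * se)))
    else:
        wald = (np.nan, np.nan)
    return FisherResult(
        p=float(p),
        odds_ratio=float(sample_or),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        wald_ci=wald,
    )


def threshold_enrichment(
    annotation: RnsAnnotation,
    p_assoc: pd.Series,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> list[EnrichmentResult]:
    """Marker-vs-association 2x2 enrichment at each GWAS threshold.

    At each cutoff t, the table splits the LD-independent SNPs into
    markers/non-markers x below/above t. A threshold where no marker falls
    below t is flagged underpowered (OR = 0), not fatal.
    """
    if list(thresholds) != sorted(thresholds):
        raise RnsgwasError("thresholds must be sorted ascending")
    ids = annotation.is_marker.index
    missing = [s for s in ids if s not in p_assoc.index]
    if missing:
        raise RnsgwasError(f"index SNPs without association p: {missing[:10]}")
    p = p_assoc.loc[ids].to_numpy()
    is_m = annotation.is_marker.to_numpy()

    out = []
    for t in thresholds:
        below = p < t
        a = int((is_m & below).sum())
        b = int((is_m & ~below).sum())
        c = int((~is_m & below).sum())
        d = int((~is_m & ~below).sum())
        fr = fisher_exact_2x2(a, b, c, d, alternative="two_sided")
        underpowered = (a + c == 0) or a == 0
        or_val = fr.odds_ratio
        if a == 0 and c > 0:
            or_val = 0.0
        out.append(
            EnrichmentResult(
                threshold=float(t),
                table=(a, b, c, d),
                odds_ratio=or_val,
                ci95_low=fr.ci_low,
                ci95_high=fr.ci_high,
                p_fisher=fr.p,
                underpowered=underpowered,
            )
        )
    return out


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "THRESHOLD": [r.threshold for r in results],
            "A": [r.table[0] for r in results],
            "B": [r.table[1] for r in results],
            "C": [r.table[2] for r in results],
            "D": [r.table[3] for r in results],
            "OR": [r.odds_ratio for r in results],
            "CI_LO": [r.ci95_low for r in results],
            "CI_HI": [r.ci95_high for r in results],
            "P": [r.p_fisher for r in results],
        }
    )


def ks_uniformity(p_values: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of p-values against Uniform(0,1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise RnsgwasError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise RnsgwasError("p-values must lie in (0, 1]")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def _rank_residuals(v_rank: np.ndarray, c_rank: np.ndarray) -> np.ndarray:
    """Residual of ranks after regressing on covariate ranks (+ intercept)."""
    x = np.column_stack([np.ones_like(c_rank), c_rank])
    coef, *_ = np.linalg.lstsq(x, v_rank, rcond=None)
    return v_rank - x @ coef


def partial_spearman_perm(
    x: np.ndarray,
    y: np.ndarray,
    covar: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    add_one: bool = True,
    chunk: int = 500,
) -> CorrelationResult:
    """Partial Spearman correlation of x and y given covar, permutation null.

    All three vectors are rank-transformed (average ranks); x- and y-ranks
    are residualized on the covariate ranks, and the Pearson correlation of
    the residuals is the partial Spearman rho. The asymptotic p uses the t
    approximation with n-3 df (two-sided). The permutation null permutes x
    against the fixed (y, covar) pairs and is one-sided in the enrichment
    direction: p_perm = (1 + #{perm rho >= rho}) / (n_perm + 1); with
    ``add_one=False`` the plain ratio r/N is reported instead.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    covar = np.asarray(covar, float)
    n = len(x)
    if not (len(y) == len(covar) == n) or n < 10:
        raise RnsgwasError("x, y, covar must have equal length >= 10")
    if n_perm < 1:
        raise RnsgwasError("n_perm must be >= 1")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = stats.rankdata(covar)
    ex = _rank_residuals(rx, rc)
    ey = _rank_residuals(ry, rc)
    if np.allclose(ex, 0) or np.allclose(ey, 0):
        raise DegenerateInputError("zero residual rank variance: covariate "
                                   "duplicates x or y in ranks")
    ex_n = ex / np.linalg.norm(ex)
    ey_n = ey / np.linalg.norm(ey)
    rho = float(ex_n @ ey_n)

    tval = rho * np.sqrt((n - 3) / max(1e-300, 1 - rho**2))
    p_asym = float(2 * stats.t.sf(abs(tval), df=n - 3))

    # projection onto the complement of span{1, rc}
    c = np.column_stack([np.ones(n), rc])
    cinv = np.linalg.pinv(c)
    rng = rng_for(seed, "spearman-perm")
    count = 0
    perm_rhos = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.empty((m, n))
        for i in range(m):
            perms[i] = rx[rng.permutation(n)]
        resid = perms - (perms @ cinv.T) @ c.T
        norms = np.linalg.norm(resid, axis=1)
        norms[norms == 0] = np.inf
        rhos = (resid @ ey_n) / norms
        perm_rhos[done : done + m] = rhos
        count += int((rhos >= rho).sum())
        done += m
    if add_one:
        p_perm = (1 + count) / (n_perm + 1)
    else:
        p_perm = max(count, 0) / n_perm
    return CorrelationResult(
        rho=rho, p_asymptotic=p_asym, p_perm=float(p_perm), n_perm=n_perm,
        perm_rhos=perm_rhos,
    )
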