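"""Per-SNP recent-natural-selection statistics.

Two complementary scans:

* a PCA outlier scan: each SNP's scaled dosage vector is regressed on the
  leading K principal-component scores; the length-K z-score vector is
  summarized by its squared Mahalanobis distance from a robust center and
  scatter, rescaled by the genomic inflation factor lambda and converted to
  a chi-square(K) upper-tail p-value (``p_rns``);
* a Weir-Cockerham F_ST scan between two labelled populations, with a
  trimmed maximum-likelihood chi-square fit to the bulk of the theta-hat
  distribution providing right-tail outlier p-values.

Large differentiation between populations — the footprint of recent
selection acting since populations separated — shows up as small p in both.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._utils import DegenerateInputError, RnsgwasError, child_seed, standardize_dosage
from .formats_io import MISSING, GenotypePanel


@dataclass
class PcaModel:
    """Principal components of the (LD-thinned) standardized genotype matrix."""

    K: int
    scores: np.ndarray          # samples x K
    singular_values: np.ndarray
    var_explained: np.ndarray   # per retained component, fraction of total
    thin_mask: np.ndarray       # per-SNP bool: used in the PCA fit


@dataclass
class SelectionScanResult:
    z: np.ndarray             # SNPs x K regression z-scores
    d2: np.ndarray            # squared Mahalanobis distance per SNP
    lambda_gc: float
    p_rns: np.ndarray
    robust_center: np.ndarray
    robust_scatter: np.ndarray


@dataclass
class FstResult:
    theta: np.ndarray
    dfprime: float | None = None
    fst_mean: float | None = None
    p_fst: np.ndarray | None = None


def _ld_thin_mask(z_norm: np.ndarray, chrom: np.ndarray, window_snps: int,
                  r2_max: float) -> np.ndarray:
    """Greedy sliding-window thinning on unit-norm genotype columns.

    A SNP is kept unless its r^2 with an already-retained SNP within the
    previous ``window_snps`` positions (SNP count, same chromosome) reaches
    ``r2_max``.
    """
    p = z_norm.shape[1]
    keep = np.zeros(p, dtype=bool)
    if r2_max >= 1.0:
        return np.ones(p, dtype=bool)
    start = 0
    for c in _unique_ordered(chrom):
        idx = np.nonzero(chrom == c)[0]
        kept: deque[int] = deque()
        for j in idx:
            while kept and j - kept[0] >= window_snps:
                kept.popleft()
            if kept:
                r = z_norm[:, list(kept)].T @ z_norm[:, j]
                if np.max(r * r) >= r2_max:
                    continue
            keep[j] = True
            kept.append(j)
        start += len(idx)
    return keep


def _unique_ordered(values: np.ndarray) -> list:
    """Unique values in order of first appearance."""
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


def _cattell_k(var_explained: np.ndarray, elbow_tol: float, k_max: int) -> int:
    """Elbow (scree) rule: retain components above the eigenvalue plateau.

    The first component m (>= 2) whose drop to its successor, relative to the
    leading component, falls below ``elbow_tol`` is taken as the start of the
    noise plateau; K = m - 1. Capped at ``k_max``.
    """
    ve = np.asarray(var_explained, dtype=float)
    for m in range(1, min(len(ve) - 1, k_max + 1)):
        if (ve[m] - ve[m + 1]) / ve[0] < elbow_tol:
            return m
    return k_max


def fit_pca(
    panel: GenotypePanel,
    k: int | str = 3,
    thin_window_snps: int = 200,
    thin_r2: float = 0.1,
    seed: int = 0,
    elbow_tol: float = 0.05,
    k_max: int = 10,
) -> PcaModel:
    """Fit the PCA stage of the scan.

    Dosages are mean-imputed and standardized, LD-thinned with a sliding
    window (``thin_window_snps`` SNPs, pairwise r^2 < ``thin_r2``), and
    decomposed by SVD. With ``k="auto"`` the number of retained components
    follows the scree-elbow rule; otherwise ``k`` components are kept
    (pipeline default 3).
    """
    if panel.n_samples < 2:
        raise DegenerateInputError("need at least 2 samples for PCA")
    z, _, poly = standardize_dosage(panel.dosage, missing=MISSING)
    if not poly.any():
        raise DegenerateInputError("all SNPs monomorphic: no variation to decompose")

    norms = np.linalg.norm(z - z.mean(axis=0, keepdims=True), axis=0)
    zn = np.zeros_like(z)
    nz = norms > 0
    zn[:, nz] = (z[:, nz] - z[:, nz].mean(axis=0, keepdims=True)) / norms[nz]
    chrom = panel.snps["chrom"].to_numpy()
    # monomorphic SNPs are all-zero columns: harmless in the SVD, and they
    # never absorb a polymorphic neighbor in the thinning pass
    thin = _ld_thin_mask(zn, chrom, thin_window_snps, thin_r2)

    x = z[:, thin]
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise DegenerateInputError("zero total variance after thinning")
    var_explained = s**2 / total

    rank = int(np.sum(s > s[0] * 1e-9))
    if k == "auto":
        kk = min(_cattell_k(var_explained, elbow_tol, k_max), rank)
    else:
        kk = int(k)
        if kk < 1 or kk > rank:
            raise RnsgwasError(f"k={kk} outside [1, rank={rank}]")
    scores = u[:, :kk] * s[:kk]
    return PcaModel(
        K=kk,
        scores=scores,
        singular_values=s,
        var_explained=var_explained[:kk],
        thin_mask=thin,
    )


def _robust_center_scatter(z: np.ndarray, robust: bool, seed: int):
    """Location/scatter of the z rows: MCD when robust, classical otherwise.

    For K=1 the median and (scaled) MAD^2 replace the MCD.
    """
    k = z.shape[1]
    if not robust:
        center = z.mean(axis=0)
        scatter = np.cov(z, rowvar=False).reshape(k, k)
        return center, scatter
    if k == 1:
        med = np.median(z)
        mad = np.median(np.abs(z - med)) * 1.4826
        if mad <= 0:
            raise DegenerateInputError("zero MAD of z-scores")
        return np.array([med]), np.array([[mad**2]])
    from sklearn.covariance import MinCovDet

    mcd = MinCovDet(support_fraction=0.75, random_state=child_seed(seed, "mcd"))
    mcd.fit(z)
    return mcd.location_, mcd.covariance_


def scan_pvalues(
    panel: GenotypePanel,
    model: PcaModel,
    robust: bool = True,
    seed: int = 0,
) -> SelectionScanResult:
    """Compute per-SNP z-scores, Mahalanobis D^2 and inflation-corrected p.

    Every SNP (thinned or not) is regressed on the K component scores; the
    coefficient/SE vector is the SNP's z row. D^2 is its squared Mahalanobis
    distance under a robust center/scatter; lambda is median(D^2) over the
    chi-square(K) median, and ``p_rns`` the chi-square(K) upper tail at
    D^2/lambda. Monomorphic SNPs get p_rns = 1 so downstream joins keep them.
    """
    if model.K < 1:
        raise RnsgwasError("model has K=0 components")
    if model.scores.shape[0] != panel.n_samples:
        raise RnsgwasError("PCA model was fit on a different sample set")

    y, _, poly = standardize_dosage(panel.dosage, missing=MISSING)
    x = model.scores  # centered columns
    n, k = x.shape
    if n <= k:
        raise RnsgwasError("need more samples than components for regression SEs")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)          # K x p
    resid = y - x @ beta
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / (n - k)
    diag = np.diag(xtx_inv)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2[None, :] * diag[:, None])
        z = np.where(se > 0, beta / se, 0.0).T  # p x K

    z[~poly] = 0.0
    center, scatter = _robust_center_scatter(z[poly], robust=robust, seed=seed)
    try:
        prec = np.linalg.inv(scatter)
    except np.linalg.LinAlgError:
        warnings.warn("singular robust scatter; falling back to diagonal")
        d = np.diag(scatter).copy()
        d[d <= 0] = 1.0
        prec = np.diag(1.0 / d)
    dev = z - center[None, :]
    d2 = np.einsum("ij,jk,ik->i", dev, prec, dev)
    d2 = np.clip(d2, 0.0, None)

    lam = float(np.median(d2[poly]) / stats.chi2.median(df=k))
    if lam <= 0:
        raise DegenerateInputError("non-positive inflation factor")
    p = stats.chi2.sf(d2 / lam, df=k)
    p[~poly] = 1.0
    d2[~poly] = 0.0
    return SelectionScanResult(
        z=z, d2=d2, lambda_gc=lam, p_rns=p,
        robust_center=np.asarray(center), robust_scatter=np.asarray(scatter),
    )


def wc_fst(panel: GenotypePanel, pop_a: str, pop_b: str) -> FstResult:
    """Weir-Cockerham (1984) per-SNP theta-hat between two populations.

    Uses the standard a/b/c variance components for r=2 populations of
    diploids, with the observed heterozygote frequencies. SNPs monomorphic
    in both populations get theta = nan.
    """
    pops = panel.population
    res = []
    for label in (pop_a, pop_b):
        m = pops == label
        if m.sum() < 2:
            raise RnsgwasError(f"population {label!r} absent or has < 2 samples")
        res.append(panel.dosage[m])
    theta = np.full(panel.n_snps, np.nan)

    stats_per_pop = []
    for d in res:
        obs = d != MISSING
        n_i = obs.sum(axis=0).astype(float)                  # individuals observed
        dd = np.where(obs, d, 0)
        p_i = np.where(n_i > 0, dd.sum(axis=0) / (2 * n_i), np.nan)
        h_i = np.where(n_i > 0, (np.where(obs, d == 1, False)).sum(axis=0) / n_i, np.nan)
        stats_per_pop.append((n_i, p_i, h_i))

    (n1, p1, h1), (n2, p2, h2) = stats_per_pop
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        ok = np.isfinite(denom) & (np.abs(denom) > 0)
        theta[ok] = a[ok] / denom[ok]
    mono = (pbar == 0) | (pbar == 1)
    theta[mono] = np.nan
    return FstResult(theta=theta)


def fst_outlier_fit(
    theta: np.ndarray, trim_fraction: float = 0.05, max_iter: int = 500
) -> FstResult:
    """Fit a chi-square null to the trimmed bulk of theta-hat values.

    After discarding the lowest and highest ``trim_fraction`` of finite
    theta values, the core is modelled as theta * df' / mean ~ chi2(df')
    (a Gamma(df'/2, 2*mean/df') density truncated to the trim bounds, fit
    by maximum likelihood). Right-tail p-values are then computed for every
    SNP under the fitted null; negative theta maps to p = 1.
    """
    th = np.asarray(theta, dtype=float)
    finite = np.isfinite(th)
    vals = th[finite]
    if len(vals) < 100:
        raise RnsgwasError(f"need >= 100 finite theta values, got {len(vals)}")
    if np.allclose(vals, vals[0]):
        raise DegenerateInputError("all theta values identical")

    lo_q, hi_q = np.quantile(vals, [trim_fraction, 1 - trim_fraction])
    core = vals[(vals >= lo_q) & (vals <= hi_q) & (vals > 0)]
    if len(core) < 50 or core.var() == 0:
        raise DegenerateInputError("trimmed theta core is degenerate")

    mu0 = float(core.mean())
    var0 = float(core.var())
    df0 = max(2.0 * mu0**2 / var0, 0.6)
    lo = max(lo_q, 0.0)

    def nll(params):
        dfp, mu = params
        shape = dfp / 2.0
        scale = 2.0 * mu / dfp
        logpdf = stats.gamma.logpdf(core, shape, scale=scale)
        z = stats.gamma.cdf(hi_q, shape, scale=scale) - stats.gamma.cdf(
            lo, shape, scale=scale
        )
        if z <= 0 or not np.all(np.isfinite(logpdf)):
            return 1e12
        return -(logpdf.sum() - len(core) * np.log(z))

    result = optimize.minimize(
        nll,
        x0=[df0, mu0],
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-8, "fatol": 1e-8},
    )
    if not result.success and result.fun >= 1e12:
        raise RnsgwasError(f"null fit failed to converge; last iterate {result.x}")
    dfp, mu = float(result.x[0]), float(result.x[1])

    p = np.full_like(th, np.nan)
    p[finite] = stats.chi2.sf(np.clip(th[finite], 0, None) * dfp / mu, df=dfp)
    return FstResult(theta=th, dfprime=dfp, fst_mean=mu, p_fst=p)


def scan_table(panel: GenotypePanel, scan: SelectionScanResult,
               fst: FstResult | None = None):
    """Tabulate scan output (SNP, CHR, BP, D2, P_RNS[, THETA, P_FST])."""
    import pandas as pd

    t = pd.DataFrame(
        {
            "SNP": panel.snps["snp_id"],
            "CHR": panel.snps["chrom"],
            "BP": panel.snps["pos"],
            "D2": scan.d2,
            "P_RNS": scan.p_rns,
        }
    )
    if fst is not None:
        t["THETA"] = fst.theta
        if fst.p_fst is not None:
            t["P_FST"] = fst.p_fst
    return t
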