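"""LD clumping, per-SNP genomic properties, and matched-SNP null sets.

r^2 throughout is the squared Pearson correlation of dosage vectors
(composite LD, no phasing required); missing genotypes are mean-imputed
before correlating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import MatchingInfeasibleError, RnsgwasError, rng_for, standardize_dosage
from .formats_io import MISSING, GenotypePanel, RegionSet


@dataclass
class ClumpedSet:
    """Result of greedy LD clumping."""

    index_snps: list[str]          # retained ids, in selection (p-value) order
    removed_by: dict[str, str]     # absorbed id -> absorbing index id
    ranking_p: str                 # which p-value column drove the ranking


def _normalized_dosage(panel: GenotypePanel) -> np.ndarray:
    z, _, _ = standardize_dosage(panel.dosage, missing=MISSING)
    z = z - z.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(z, axis=0)
    nz = norms > 0
    z[:, nz] /= norms[nz]
    return z


def ld_clump(
    snps: pd.DataFrame,
    panel: GenotypePanel,
    r2_max: float = 0.1,
    window_kb: int = 500,
    p_col: str = "p",
    ranking_p: str | None = None,
) -> ClumpedSet:
    """Greedy p-value-ranked clumping (index SNPs absorb correlated neighbors).

    ``snps`` needs columns snp_id, chrom, pos and ``p_col``. Repeatedly the
    unabsorbed SNP with the smallest p (ties broken by genomic order) becomes
    an index SNP and absorbs every unabsorbed SNP within +/- ``window_kb``
    on the same chromosome whose r^2 with it is >= ``r2_max``.
    """
    ids = snps["snp_id"].to_numpy()
    panel_pos = {s: i for i, s in enumerate(panel.snps["snp_id"])}
    missing_ids = [s for s in ids if s not in panel_pos]
    if missing_ids:
        raise RnsgwasError(f"SNPs absent from panel: {missing_ids[:10]}")

    cols = np.array([panel_pos[s] for s in ids])
    zn = _normalized_dosage(panel.subset_snps(cols))
    chrom = snps["chrom"].to_numpy().astype(str)
    pos = snps["pos"].to_numpy().astype(np.int64)
    pvals = snps[p_col].to_numpy().astype(float)

    order = np.lexsort((pos, chrom, pvals))  # p, then chrom, then pos
    window = int(window_kb) * 1000

    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        by_chrom[c] = idx[np.argsort(pos[idx], kind="mergesort")]

    absorbed = np.zeros(len(ids), dtype=bool)
    index_snps: list[str] = []
    removed_by: dict[str, str] = {}
    for i in order:
        if absorbed[i]:
            continue
        absorbed[i] = True
        index_snps.append(ids[i])
        neigh_sorted = by_chrom[chrom[i]]
        npos = pos[neigh_sorted]
        lo = np.searchsorted(npos, pos[i] - window, side="left")
        hi = np.searchsorted(npos, pos[i] + window, side="right")
        cand = neigh_sorted[lo:hi]
        cand = cand[~absorbed[cand]]
        if len(cand) == 0:
            continue
        r = zn[:, cand].T @ zn[:, i]
        hit = cand[r * r >= r2_max]
        absorbed[hit] = True
        for j in hit:
            removed_by[ids[j]] = ids[i]
    return ClumpedSet(index_snps=index_snps, removed_by=removed_by,
                      ranking_p=ranking_p or p_col)


def clump_table(clumped: ClumpedSet, pvals: pd.Series) -> pd.DataFrame:
    """Tabular clump output: INDEX_SNP, P, N_ABSORBED, ABSORBED_IDS."""
    absorbed_of: dict[str, list[str]] = {s: [] for s in clumped.index_snps}
    for snp, index in clumped.removed_by.items():
        absorbed_of[index].append(snp)
    return pd.DataFrame(
        {
            "INDEX_SNP": clumped.index_snps,
            "P": [pvals[s] for s in clumped.index_snps],
            "N_ABSORBED": [len(absorbed_of[s]) for s in clumped.index_snps],
            "ABSORBED_IDS": [",".join(absorbed_of[s]) for s in clumped.index_snps],
        }
    )


def annotate_properties(
    panel: GenotypePanel,
    genes: RegionSet | None = None,
    buddy_r2: float = 0.5,
    buddy_window_kb: int = 500,
    density_window_kb: int = 100,
) -> pd.DataFrame:
    """Per-SNP matching covariates, indexed by snp_id.

    Columns: ``maf``; ``ld_buddies`` (count of SNPs with r^2 >= buddy_r2
    within +/- buddy_window_kb); ``gene_dist`` (bp to the nearest gene
    interval, 0 inside, inf when no genes); ``gene_density`` (gene intervals
    overlapping +/- density_window_kb).
    """
    snps = panel.snps
    zn = _normalized_dosage(panel)
    pos = snps["pos"].to_numpy().astype(np.int64)
    chrom = snps["chrom"].to_numpy().astype(str)
    window = int(buddy_window_kb) * 1000

    buddies = np.zeros(panel.n_snps, dtype=int)
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        cpos = pos[idx]
        block = 512
        for b0 in range(0, len(idx), block):
            b = idx[b0 : b0 + block]
            lo = np.searchsorted(cpos, pos[b[0]] - window, side="left")
            hi = np.searchsorted(cpos, pos[b[-1]] + window, side="right")
            neigh = idx[lo:hi]
            r = zn[:, b].T @ zn[:, neigh]          # block x neighborhood
            close = (
                np.abs(pos[neigh][None, :] - pos[b][:, None]) <= window
            )
            hits = (r * r >= buddy_r2) & close
            # exclude self; monomorphic SNPs (zero column) match nothing
            buddies[b] = np.clip(hits.sum(axis=1) - 1, 0, None)

    gene_dist = np.full(panel.n_snps, np.inf)
    gene_density = np.zeros(panel.n_snps, dtype=int)
    if genes is not None and len(genes):
        dwin = int(density_window_kb) * 1000
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in genes.intervals:
            by_chrom.setdefault(str(c), []).append((s, e))
        for c, ivals in by_chrom.items():
            m = chrom == c
            if not m.any():
                continue
            p0 = pos[m] - 1  # 0-based point coordinate
            starts = np.array(sorted(s for s, _ in ivals))
            ends_sorted = np.array(sorted(e for _, e in ivals))
            dists = np.full(m.sum(), np.inf)
            for s, e in ivals:
                d = np.where(p0 < s, s - p0, np.where(p0 >= e, p0 - (e - 1), 0))
                dists = np.minimum(dists, d)
            gene_dist[m] = dists
            n_start_before = np.searchsorted(starts, p0 + dwin, side="right")
            n_end_before = np.searchsorted(ends_sorted, p0 - dwin, side="right")
            gene_density[m] = n_start_before - n_end_before

    return pd.DataFrame(
        {
            "maf": panel.maf(),
            "ld_buddies": buddies,
            "gene_dist": gene_dist,
            "gene_density": gene_density,
        },
        index=pd.Index(snps["snp_id"], name="snp_id"),
    )


def _candidate_mask(
    target: pd.Series,
    pool: pd.DataFrame,
    maf_tol: float,
    rel_tol: float,
    count_slack: int,
) -> np.ndarray:
    ok = np.abs(pool["maf"].to_numpy() - target["maf"]) <= maf_tol

    for col, is_count in (("ld_buddies", True), ("gene_dist", False),
                          ("gene_density", True)):
        t = target[col]
        v = pool[col].to_numpy()
        if np.isinf(t):
            within = np.isinf(v)
        elif t == 0:
            within = v == 0
        else:
            within = (v >= (1 - rel_tol) * t) & (v <= (1 + rel_tol) * t)
        if is_count:
            within = within | (np.abs(v - t) <= count_slack)
        ok &= within
    return ok


def draw_matched_sets(
    target_ids: list[str],
    pool_ids: list[str],
    props: pd.DataFrame,
    n_sets: int,
    seed: int,
    maf_tol: float = 0.05,
    rel_tol: float = 0.5,
    count_slack: int = 1,
) -> list[list[str]]:
    """Draw ``n_sets`` pool subsets matched SNP-by-SNP to the targets.

    For each target SNP, a candidate pool SNP must have MAF within
    ``maf_tol`` (absolute) and LD-buddy count, gene distance and gene
    density within ``rel_tol`` (relative; a zero target accepts only zero,
    and counts get an absolute slack of ``count_slack``). Each set draws
    uniformly, without replacement within the set; sets are independent and
    reproducible under ``seed``.
    """
    if n_sets < 1:
        raise RnsgwasError("n_sets must be >= 1")
    overlap = set(target_ids) & set(pool_ids)
    if overlap:
        raise RnsgwasError(f"pool overlaps targets: {sorted(overlap)[:5]}")
    pool = props.loc[list(pool_ids)]
    pool_arr = np.asarray(pool_ids)

    candidates: list[np.ndarray] = []
    for t in target_ids:
        mask = _candidate_mask(props.loc[t], pool, maf_tol, rel_tol, count_slack)
        cand = np.nonzero(mask)[0]
        if len(cand) == 0:
            raise MatchingInfeasibleError(
                f"no matched candidate for target SNP {t} under tolerances"
            )
        candidates.append(cand)

    rng = rng_for(seed, "matched-sets")
    sets: list[list[str]] = []
    for _ in range(n_sets):
        used: set[int] = set()
        chosen: list[str] = []
        for t, cand in zip(target_ids, candidates):
            free = cand[~np.isin(cand, list(used))] if used else cand
            if len(free) == 0:
                raise MatchingInfeasibleError(
                    f"candidates for target SNP {t} exhausted within a set; "
                    "widen tolerances or enlarge the pool"
                )
            pick = int(rng.choice(free))
            used.add(pick)
            chosen.append(str(pool_arr[pick]))
        sets.append(chosen)
    return sets
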