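"""Synthetic multi-population genotype, GWAS and cohort data with ground truth.

The generator emulates the pipeline's three real-world inputs:

* a structured genotype panel — K populations drifted apart under the
  Balding-Nichols model (population frequency ~ Beta around an ancestral
  frequency p0 with drift parameter F), with ``n_selected`` planted
  high-differentiation loci (a frequency shift of ``delta_sel`` in one
  designated population) standing in for recent-selection targets;
* discovery GWAS summary statistics — per-SNP log-odds estimates drawn
  around planted true effects, a configurable fraction of causal loci
  overlapping the selected set, and a bias ``pi_prot`` toward the derived
  allele being protective at selected-causal loci;
* an independent liability-threshold case-control cohort for polygenic
  score evaluation, drawn from one population's frequencies.

Every planted quantity is returned in :class:`GroundTruth` so recovery
tests can compare estimates against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import RnsgwasError, rng_for
from .formats_io import MISSING, GenotypePanel, GwasSummary, RegionSet

_BASES = "ACGT"


@dataclass
class SimConfig:
    """All knobs of the generator, with desk-scale defaults.

    ``fst_drift`` may be a scalar (shared F) or one value per population.
    ``overlap_frac`` is the fraction of causal loci drawn from the selected
    set; ``pi_prot`` the probability that the derived allele of a
    selected-causal locus is protective (negative log-odds).
    """

    n_pops: int = 4
    n_per_pop: int = 100
    n_snps: int = 20_000
    fst_drift: float | tuple = 0.1
    p0_low: float = 0.05
    p0_high: float = 0.95
    n_selected: int = 100
    delta_sel: float = 0.3
    sel_pop: int = 0
    n_causal: int = 200
    overlap_frac: float = 0.5
    beta_sd: float = 0.08
    pi_prot: float = 0.8
    h2_liability: float = 0.3
    prevalence: float = 0.01
    seed: int = 0
    # genome layout
    n_chrom: int = 4
    bp_spacing: int = 2500
    ld_block: int = 5
    block_freq_jitter: float = 0.03
    gene_length: int = 10_000
    gene_spacing: int = 50_000
    # ancestral-allele bookkeeping
    aa_lowercase_frac: float = 0.05
    aa_missing_frac: float = 0.02
    # GWAS noise
    info_low_frac: float = 0.05

    def __post_init__(self):
        if not 0 <= self.overlap_frac <= 1:
            raise RnsgwasError("overlap_frac must be in [0,1]")
        if not 0 <= self.pi_prot <= 1:
            raise RnsgwasError("pi_prot must be in [0,1]")
        if not 0 < self.h2_liability < 1:
            raise RnsgwasError("h2_liability must be in (0,1)")


@dataclass
class GroundTruth:
    selected_ids: list[str]
    causal_ids: list[str]
    beta_true: pd.Series          # derived-allele log-odds, indexed by snp_id
    derived_is_alt: pd.Series     # bool per snp_id

    def beta_alt(self) -> pd.Series:
        """Planted log-odds oriented to the panel alt allele."""
        sign = np.where(self.derived_is_alt.reindex(self.beta_true.index), 1.0, -1.0)
        return self.beta_true * sign


def scenario_config(name: str, **overrides) -> SimConfig:
    """Named study conditions.

    ``planted``: selected loci overlap causal loci with a derived-protective
    bias (the alternative the pipeline should detect). ``null``: selected
    loci exist but are independent of the GWAS and direction is unbiased.
    ``neutral``: no planted selection at all (scan calibration).
    """
    presets = {
        "planted": {},
        "null": {"overlap_frac": 0.0, "pi_prot": 0.5},
        "neutral": {"overlap_frac": 0.0, "pi_prot": 0.5, "n_selected": 0},
    }
    if name not in presets:
        raise RnsgwasError(f"unknown scenario {name!r}")
    params = dict(presets[name])
    params.update(overrides)
    return SimConfig(**params)


def _drift_vector(cfg: SimConfig) -> np.ndarray:
    f = np.broadcast_to(np.asarray(cfg.fst_drift, dtype=float), (cfg.n_pops,)).copy()
    if np.any((f <= 0) | (f >= 1)):
        raise RnsgwasError("fst_drift must lie in (0,1)")
    return f


def simulate_populations(cfg: SimConfig) -> tuple[GenotypePanel, GroundTruth, RegionSet]:
    """Draw the genotype panel, its ground truth, and a synthetic gene map.

    Adjacent SNPs come in LD blocks of ``cfg.ld_block``: a block shares one
    ancestral frequency (plus per-SNP jitter) and, within an individual,
    both haploid copies of a block are generated from a single latent
    uniform, which makes nearby SNPs strongly correlated — enough structure
    for clumping and LD-buddy logic to act on.
    """
    rng = rng_for(cfg.seed, "populations")
    p = cfg.n_snps
    n_blocks = int(np.ceil(p / max(cfg.ld_block, 1)))
    block_of = np.repeat(np.arange(n_blocks), max(cfg.ld_block, 1))[:p]

    p0_block = rng.uniform(cfg.p0_low, cfg.p0_high, size=n_blocks)
    # a per-SNP offset shared by every population: differentiates SNPs
    # within a block without adding between-population differentiation
    delta = rng.normal(0, cfg.block_freq_jitter, size=p)
    p0 = np.clip(p0_block[block_of] + delta, 0.02, 0.98)

    drift = _drift_vector(cfg)
    pop_freq = np.empty((cfg.n_pops, p))
    for j, f in enumerate(drift):
        a = p0_block * (1 - f) / f
        b = (1 - p0_block) * (1 - f) / f
        bn_block = rng.beta(a, b)        # one drift draw per LD block
        pop_freq[j] = np.clip(bn_block[block_of] + delta, 1e-3, 1 - 1e-3)

    # planted high-differentiation loci: shift the designated population
    sel_idx = np.sort(rng.choice(p, size=cfg.n_selected, replace=False)) if cfg.n_selected else np.array([], dtype=int)
    if cfg.n_selected:
        sign = rng.choice([-1.0, 1.0], size=cfg.n_selected)
        shifted = np.clip(pop_freq[cfg.sel_pop, sel_idx] + sign * cfg.delta_sel, 0.01, 0.99)
        if np.allclose(shifted, pop_freq[cfg.sel_pop, sel_idx]):
            raise RnsgwasError("delta_sel produces no feasible frequency shift")
        pop_freq[cfg.sel_pop, sel_idx] = shifted

    # genotypes: one latent uniform per (individual, block, haploid copy)
    dosages = []
    for j in range(cfg.n_pops):
        u = rng.uniform(size=(cfg.n_per_pop, n_blocks, 2))
        u_snp = u[:, block_of, :]                       # n x p x 2
        geno = (u_snp < pop_freq[j][None, :, None]).sum(axis=2)
        dosages.append(geno.astype(np.int16))
    dosage = np.vstack(dosages)

    # genome layout: contiguous chromosome chunks, fixed spacing
    per_chrom = int(np.ceil(p / cfg.n_chrom))
    chrom = np.array([str(1 + i // per_chrom) for i in range(p)])
    pos = np.empty(p, dtype=np.int64)
    for c in np.unique(chrom):
        m = chrom == c
        pos[m] = (np.arange(m.sum()) + 1) * cfg.bp_spacing

    ref_i = rng.integers(0, 4, size=p)
    alt_i = (ref_i + rng.integers(1, 4, size=p)) % 4
    ref = np.array([_BASES[i] for i in ref_i])
    alt = np.array([_BASES[i] for i in alt_i])

    derived_is_alt = rng.uniform(size=p) < 0.5
    ancestral = np.where(derived_is_alt, ref, alt).astype(object)
    low_conf = rng.uniform(size=p) < cfg.aa_lowercase_frac
    aa_missing = rng.uniform(size=p) < cfg.aa_missing_frac
    ancestral[aa_missing] = None
    low_conf = low_conf & ~aa_missing

    snp_ids = np.array([f"rs{i + 1}" for i in range(p)])
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "ancestral": ancestral,
            "aa_low_conf": low_conf,
        }
    )
    sample_ids = np.array(
        [f"pop{j}_{i:04d}" for j in range(cfg.n_pops) for i in range(cfg.n_per_pop)]
    )
    population = np.array(
        [f"pop{j}" for j in range(cfg.n_pops) for _ in range(cfg.n_per_pop)]
    )
    panel = GenotypePanel(snps=snps, dosage=dosage, sample_ids=sample_ids,
                          population=population)

    # causal loci: a fixed share from the selected set, the rest neutral
    n_from_sel = int(round(cfg.overlap_frac * cfg.n_causal))
    if n_from_sel > cfg.n_selected:
        raise RnsgwasError("overlap_frac * n_causal exceeds n_selected")
    causal_sel = rng.choice(sel_idx, size=n_from_sel, replace=False) if n_from_sel else np.array([], dtype=int)
    non_sel = np.setdiff1d(np.arange(p), sel_idx)
    causal_non = rng.choice(non_sel, size=cfg.n_causal - n_from_sel, replace=False)
    causal_idx = np.sort(np.concatenate([causal_sel, causal_non]).astype(int))

    beta = pd.Series(0.0, index=snp_ids)
    mags = np.abs(rng.normal(0, cfg.beta_sd, size=len(causal_idx)))
    in_sel = np.isin(causal_idx, sel_idx)
    prot = np.where(
        in_sel,
        rng.uniform(size=len(causal_idx)) < cfg.pi_prot,
        rng.uniform(size=len(causal_idx)) < 0.5,
    )
    beta.iloc[causal_idx] = np.where(prot, -mags, mags)

    truth = GroundTruth(
        selected_ids=list(snp_ids[sel_idx]),
        causal_ids=list(snp_ids[causal_idx]),
        beta_true=beta,
        derived_is_alt=pd.Series(derived_is_alt, index=snp_ids),
    )

    genes = _gene_map(snps, cfg)
    return panel, truth, genes


def _gene_map(snps: pd.DataFrame, cfg: SimConfig) -> RegionSet:
    """Regular synthetic gene intervals tiling each chromosome."""
    intervals = []
    for c, grp in snps.groupby("chrom", sort=False):
        span = int(grp["pos"].max())
        start = cfg.gene_spacing // 2
        while start < span:
            intervals.append((str(c), start, start + cfg.gene_length))
            start += cfg.gene_spacing
    return RegionSet(intervals, label="synthetic genes")


def simulate_gwas_summary(
    cfg: SimConfig,
    truth: GroundTruth,
    panel: GenotypePanel,
    n_eff: float = 100_000,
    stream: str = "gwas",
) -> GwasSummary:
    """Discovery GWAS summary statistics around the planted effects.

    The estimated log-odds for each SNP is Normal(beta_true, se^2) with
    se = 1/sqrt(2 p (1-p) n_eff) at the panel allele frequency — the usual
    large-sample variance of a log-odds estimate at effective sample size
    ``n_eff``. The effect allele is the panel alt or ref at random, so
    downstream harmonization is exercised.
    """
    if n_eff <= 0:
        raise RnsgwasError("n_eff must be positive")
    rng = rng_for(cfg.seed, stream)
    freq_alt = panel.alt_freq()
    freq_alt = np.clip(freq_alt, 0.01, 0.99)
    beta_alt = truth.beta_alt().to_numpy()

    se = 1.0 / np.sqrt(2.0 * freq_alt * (1.0 - freq_alt) * n_eff)
    est_alt = rng.normal(beta_alt, se)
    zscore = est_alt / se
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(zscore)), 1e-300, 1.0)

    effect_is_alt = rng.uniform(size=panel.n_snps) < 0.5
    a1 = np.where(effect_is_alt, panel.snps["alt"], panel.snps["ref"])
    a2 = np.where(effect_is_alt, panel.snps["ref"], panel.snps["alt"])
    est_a1 = np.where(effect_is_alt, est_alt, -est_alt)
    freq_a1 = np.where(effect_is_alt, freq_alt, 1.0 - freq_alt)

    low = rng.uniform(size=panel.n_snps) < cfg.info_low_frac
    info = np.where(low, rng.uniform(0.5, 0.9, size=panel.n_snps),
                    rng.uniform(0.905, 1.0, size=panel.n_snps))

    table = pd.DataFrame(
        {
            "snp_id": panel.snps["snp_id"],
            "chrom": panel.snps["chrom"],
            "pos": panel.snps["pos"],
            "a1": a1,
            "a2": a2,
            "or_effect": np.exp(est_a1),
            "se": se,
            "p_assoc": pvals,
            "info": info,
            "freq_a1": freq_a1,
        }
    )
    return GwasSummary(table=table)


@dataclass
class CohortData:
    """An evaluation case-control cohort: genotypes, phenotype, covariates."""

    dosage: np.ndarray            # samples x SNPs (alt-allele counts)
    phenotype: np.ndarray         # 0/1
    covariates: pd.DataFrame
    snp_ids: np.ndarray
    effect_allele: np.ndarray     # allele the dosage counts (panel alt)
    freq: np.ndarray              # population frequency for mean imputation
    sample_ids: np.ndarray = None

    def __post_init__(self):
        if not np.isin(np.unique(self.phenotype), [0, 1]).all():
            raise ValueError("phenotype must be binary 0/1")
        if self.covariates.isna().any().any():
            raise ValueError("covariates must be complete")
        if self.sample_ids is None:
            self.sample_ids = np.array(
                [f"ind_{i:05d}" for i in range(len(self.phenotype))]
            )


def simulate_target_cohort(
    cfg: SimConfig,
    truth: GroundTruth,
    panel: GenotypePanel,
    n_cases: int = 1927,
    n_controls: int = 1561,
    n_covariate_pcs: int = 10,
    max_batches: int = 400,
) -> CohortData:
    """Liability-threshold case-control cohort from one population.

    Individuals are drawn from the designated population's allele
    frequencies; liability = genetic score (standardized, weight
    ``h2_liability``) + Gaussian noise; cases exceed the
    prevalence-determined threshold. Sampling proceeds in batches until the
    requested numbers of cases and controls are collected. Covariates are
    sex, age, and the leading genotype principal components.
    """
    rng = rng_for(cfg.seed, "cohort")
    pop_mask = panel.population == f"pop{cfg.sel_pop}"
    if not pop_mask.any():
        raise RnsgwasError(f"designated population pop{cfg.sel_pop} not in panel")
    from ._utils import allele_frequency

    # the designated population's empirical frequencies are the sampling law
    freq = allele_frequency(panel.dosage[pop_mask], missing=MISSING)
    freq = np.clip(np.nan_to_num(freq, nan=0.5), 0.005, 0.995)
    beta_alt = truth.beta_alt().to_numpy()
    var_g = float(np.sum(2 * freq * (1 - freq) * beta_alt**2))
    if var_g <= 0:
        var_g = 1.0  # no signal: liability is pure noise
    mean_g = float(np.sum(2 * freq * beta_alt))
    thresh = stats.norm.isf(cfg.prevalence)

    batch = max(2000, n_cases + n_controls)
    cases, controls = [], []
    for _ in range(max_batches):
        g = rng.binomial(2, freq[None, :], size=(batch, panel.n_snps)).astype(np.int16)
        score = (g @ beta_alt - mean_g) / np.sqrt(var_g)
        liab = np.sqrt(cfg.h2_liability) * score + np.sqrt(
            1 - cfg.h2_liability
        ) * rng.normal(size=batch)
        is_case = liab > thresh
        need_cases = n_cases - sum(len(c) for c in cases)
        need_ctrls = n_controls - sum(len(c) for c in controls)
        if need_cases > 0:
            cases.append(g[is_case][:need_cases])
        if need_ctrls > 0:
            controls.append(g[~is_case][:need_ctrls])
        if (
            sum(len(c) for c in cases) >= n_cases
            and sum(len(c) for c in controls) >= n_controls
        ):
            break
    else:
        raise RnsgwasError(
            "could not collect the requested cases within the iteration cap; "
            "prevalence may be too low for this cohort size"
        )

    geno = np.vstack([np.vstack(cases), np.vstack(controls)])
    pheno = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])

    n = len(pheno)
    cov = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age": rng.normal(45.0, 10.0, size=n),
        }
    )
    if n_covariate_pcs > 0:
        from ._utils import standardize_dosage

        z, _, _ = standardize_dosage(geno, missing=MISSING)
        z -= z.mean(axis=0, keepdims=True)
        k = min(n_covariate_pcs, min(z.shape) - 1)
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        for i in range(k):
            cov[f"PC{i + 1}"] = u[:, i] * s[i]

    return CohortData(
        dosage=geno,
        phenotype=pheno,
        covariates=cov,
        snp_ids=panel.snps["snp_id"].to_numpy(),
        effect_allele=panel.snps["alt"].to_numpy(),
        freq=freq,
    )


def write_cohort_tsv(cohort: CohortData, path) -> None:
    """Phenotype/covariate table: IID, PHENO, then covariate columns."""
    out = pd.DataFrame({"IID": cohort.sample_ids, "PHENO": cohort.phenotype})
    for c in cohort.covariates.columns:
        out[c.upper()] = cohort.covariates[c].to_numpy()
    out.to_csv(path, sep="\t", index=False)
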