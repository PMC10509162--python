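"""End-to-end orchestration: config validation and the two analysis flows.

The pipeline chains: harmonize -> selection scan -> LD clump (by
association p, by selection p, or both) -> marker definition -> enrichment
cascade -> derived-allele direction bias -> (when a cohort is present)
selection-stratified polygenic scoring. Every stage persists its table
under the output directory, and a JSON report collects every statistic,
the config hash and the seeds, so a run is reproducible stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import MatchingInfeasibleError, RnsgwasError, child_seed
from . import enrichment as enr
from . import formats_io as fio
from . import ld_matching as ldm
from . import pgs as pgsmod
from . import polarization as pol
from . import selection_scan as scan
from . import simulate as sim

_DEFAULTS: dict = {
    "seed": None,
    "flow": "both",                    # clump_by_assoc | clump_by_rns | both
    "data": {
        "genotypes": None,             # VCF path
        "gwas": None,                  # summary TSV path
        "gwas_discovery": None,        # optional separate discovery TSV for PGS
        "genes": None,                 # BED
        "excludes": None,              # BED (MHC, long-range LD, ...)
        "cohort_vcf": None,
        "cohort_pheno": None,
    },
    "simulate": {
        "enabled": False,
        "scenario": "planted",
        "overrides": {},
        "n_eff": 100_000,
        "cohort_cases": 500,
        "cohort_controls": 500,
    },
    "filters": {"info_min": 0.9, "maf_min": 0.05},
    "scan": {"k": 3, "thin_window_snps": 200, "thin_r2": 0.1, "robust": True,
             "fst_pops": None},
    "clump": {"r2": 0.1, "window_kb": 500},
    "markers": {"top_fraction": 0.05},
    "enrichment": {"thresholds": list(enr.DEFAULT_THRESHOLDS), "n_perm": 10_000,
                   "spearman_p_max": 0.05},
    "polarization": {"thresholds": list(pol.DIRECTION_THRESHOLDS)},
    "pgs": {"p_t": 0.2, "n_quantiles": 20, "n_sets": 1000, "n_draws": 1000,
            "n_snps_per_draw": 1000, "n_covariate_pcs": 10},
}


@dataclass
class PipelineConfig:
    """Validated configuration; see ``_DEFAULTS`` for the schema."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def hash(self) -> str:
        canon = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _merge_checked(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    unknown = [k for k in given if k not in defaults]
    if unknown:
        raise RnsgwasError(f"unknown config key(s) at {path or 'top level'}: {unknown}")
    for key, dval in defaults.items():
        gval = given.get(key, None)
        if isinstance(dval, dict) and key != "overrides":
            out[key] = _merge_checked(dval, gval or {}, f"{path}{key}.")
        else:
            out[key] = gval if key in given else dval
    return out


def validate_config(source: str | os.PathLike | dict) -> PipelineConfig:
    """Parse and validate a YAML config (or an equivalent dict).

    Unknown keys are rejected; defaults are filled in. A seed is mandatory
    (every stage with randomness derives its own stream from it). In
    non-simulation mode the genotype and GWAS paths must exist.
    """
    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise RnsgwasError(f"config {source} does not parse to a mapping")
    values = _merge_checked(_DEFAULTS, raw)

    if values["seed"] is None:
        raise RnsgwasError("config must set a seed (stochastic stages require one)")
    values["seed"] = int(values["seed"])
    if values["flow"] not in ("clump_by_assoc", "clump_by_rns", "both"):
        raise RnsgwasError(f"unknown flow {values['flow']!r}")

    if not values["simulate"]["enabled"]:
        missing = [
            k for k in ("genotypes", "gwas") if not values["data"][k]
        ]
        if missing:
            raise RnsgwasError(f"missing mandatory data paths: {missing}")
        for key, p in values["data"].items():
            if p and not Path(p).exists():
                raise RnsgwasError(f"data.{key} path does not exist: {p}")
    return PipelineConfig(values=values)


def _load_inputs(cfg: PipelineConfig, out_dir: Path):
    """Either simulate the study inputs or read them from disk."""
    v = cfg.values
    if v["simulate"]["enabled"]:
        simcfg = sim.scenario_config(
            v["simulate"]["scenario"],
            seed=child_seed(v["seed"], "simulate"),
            **(v["simulate"]["overrides"] or {}),
        )
        panel, truth, genes = sim.simulate_populations(simcfg)
        gwas = sim.simulate_gwas_summary(simcfg, truth, panel,
                                         n_eff=v["simulate"]["n_eff"])
        gwas_disc = sim.simulate_gwas_summary(
            simcfg, truth, panel, n_eff=v["simulate"]["n_eff"],
            stream="gwas-discovery",
        )
        cohort = sim.simulate_target_cohort(
            simcfg, truth, panel,
            n_cases=v["simulate"]["cohort_cases"],
            n_controls=v["simulate"]["cohort_controls"],
            n_covariate_pcs=v["pgs"]["n_covariate_pcs"],
        )
        excludes = None
        return panel, gwas, gwas_disc, genes, excludes, cohort, truth

    d = v["data"]
    excludes = fio.RegionSet.from_bed(d["excludes"]) if d["excludes"] else None
    panel = fio.read_genotypes(d["genotypes"], region_excludes=excludes)
    gwas = fio.read_gwas(d["gwas"], info_min=v["filters"]["info_min"])
    gwas_disc = (
        fio.read_gwas(d["gwas_discovery"], info_min=v["filters"]["info_min"])
        if d["gwas_discovery"]
        else None
    )
    genes = fio.RegionSet.from_bed(d["genes"]) if d["genes"] else None
    cohort = None
    if d["cohort_vcf"] and d["cohort_pheno"]:
        cohort = _read_cohort(d["cohort_vcf"], d["cohort_pheno"])
    return panel, gwas, gwas_disc, genes, excludes, cohort, None


def _read_cohort(vcf_path, pheno_path) -> sim.CohortData:
    panel = fio.read_genotypes(vcf_path)
    pheno = pd.read_csv(pheno_path, sep="\t")
    pheno = pheno.set_index("IID").loc[panel.sample_ids]
    covs = pheno.drop(columns=["PHENO"])
    covs.columns = [c.lower() for c in covs.columns]
    return sim.CohortData(
        dosage=panel.dosage,
        phenotype=pheno["PHENO"].to_numpy(int),
        covariates=covs.reset_index(drop=True),
        snp_ids=panel.snps["snp_id"].to_numpy(),
        effect_allele=panel.snps["alt"].to_numpy(),
        freq=np.nan_to_num(panel.alt_freq(), nan=0.5),
        sample_ids=panel.sample_ids,
    )


def draw_matched_sets_widening(
    target_ids, pool_ids, props, n_sets, seed,
    maf_tol=0.05, rel_tol=0.5, count_slack=1, max_widenings=4,
):
    """Matched-set sampling with stepwise tolerance widening on failure."""
    for step in range(max_widenings + 1):
        try:
            return (
                ldm.draw_matched_sets(
                    target_ids, pool_ids, props, n_sets=n_sets, seed=seed,
                    maf_tol=maf_tol * (1.5**step),
                    rel_tol=min(rel_tol * (1.5**step), 10.0),
                    count_slack=count_slack + 2 * step,
                ),
                step,
            )
        except MatchingInfeasibleError:
            if step == max_widenings:
                raise
    raise AssertionError("unreachable")


def run_pipeline(cfg: PipelineConfig, out_dir: str | os.PathLike) -> dict:
    """Execute the configured flow end to end; returns the report dict."""
    v = cfg.values
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = v["seed"]
    report: dict = {
        "version": __version__,
        "config_hash": cfg.hash(),
        "seed": seed,
        "stages": {},
    }

    stage = "load"
    try:
        panel, gwas, gwas_disc, genes, excludes, cohort, truth = _load_inputs(cfg, out)
        harmonized, harm_report = fio.harmonize(
            panel, gwas, maf_min=v["filters"]["maf_min"]
        )
        report["stages"]["harmonize"] = asdict(harm_report)
        hpanel = panel.subset_snps(harmonized["panel_idx"].to_numpy())

        stage = "scan"
        sc = v["scan"]
        model = scan.fit_pca(
            hpanel, k=sc["k"], thin_window_snps=sc["thin_window_snps"],
            thin_r2=sc["thin_r2"], seed=child_seed(seed, "pca"),
        )
        result = scan.scan_pvalues(
            hpanel, model, robust=sc["robust"], seed=child_seed(seed, "scan")
        )
        fst = None
        if sc["fst_pops"]:
            pa, pb = sc["fst_pops"]
            fst = scan.wc_fst(hpanel, pa, pb)
            fst = scan.fst_outlier_fit(fst.theta)
        scan_tab = scan.scan_table(hpanel, result, fst)
        scan_tab.to_csv(out / "scan.tsv", sep="\t", index=False)
        report["stages"]["scan"] = {
            "K": model.K,
            "lambda_gc": result.lambda_gc,
            "var_explained": list(map(float, model.var_explained)),
            "n_thinned": int(model.thin_mask.sum()),
            "fst_dfprime": None if fst is None else fst.dfprime,
        }

        snp_table = pd.DataFrame(
            {
                "snp_id": hpanel.snps["snp_id"].to_numpy(),
                "chrom": hpanel.snps["chrom"].to_numpy(),
                "pos": hpanel.snps["pos"].to_numpy(),
                "p_rns": result.p_rns,
                "p_assoc": harmonized["p_assoc"].to_numpy(),
            }
        )
        p_rns = pd.Series(result.p_rns, index=snp_table["snp_id"].to_numpy())
        p_assoc = pd.Series(
            harmonized["p_assoc"].to_numpy(), index=snp_table["snp_id"].to_numpy()
        )

        flows = {
            "clump_by_assoc": "p_assoc",
            "clump_by_rns": "p_rns",
        }
        run_flows = (
            list(flows) if v["flow"] == "both" else [v["flow"]]
        )
        marker_sets: dict[str, set] = {}
        for flow_name in run_flows:
            stage = flow_name
            p_col = flows[flow_name]
            clumped = ldm.ld_clump(
                snp_table, hpanel, r2_max=v["clump"]["r2"],
                window_kb=v["clump"]["window_kb"], p_col=p_col,
            )
            ldm.clump_table(
                clumped, snp_table.set_index("snp_id")[p_col]
            ).to_csv(out / f"clump_{flow_name}.tsv", sep="\t", index=False)

            annotation = enr.define_rns_markers(
                clumped, p_rns, top_fraction=v["markers"]["top_fraction"]
            )
            marker_sets[flow_name] = set(annotation.marker_ids)

            enrich = enr.threshold_enrichment(
                annotation, p_assoc, thresholds=tuple(v["enrichment"]["thresholds"])
            )
            enr.enrichment_table(enrich).to_csv(
                out / f"enrichment_{flow_name}.tsv", sep="\t", index=False
            )
            ks_stat, ks_p = enr.ks_uniformity(
                p_rns.loc[annotation.is_marker.index].to_numpy()
            )

            idx = annotation.is_marker.index
            nominal = p_assoc.loc[idx] < v["enrichment"]["spearman_p_max"]
            corr = None
            if nominal.sum() >= 10:
                maf = (
                    harmonized.set_index("snp_id")["maf"].loc[idx[nominal]].to_numpy()
                )
                corr = enr.partial_spearman_perm(
                    -np.log10(p_assoc.loc[idx[nominal]].to_numpy()),
                    -np.log10(p_rns.loc[idx[nominal]].to_numpy()),
                    maf,
                    n_perm=v["enrichment"]["n_perm"],
                    seed=child_seed(seed, "perm", flow_name),
                )

            pol_tab = pol.polarize_to_derived(harmonized)
            bias = pol.direction_bias_tests(
                pol_tab, annotation, p_assoc,
                thresholds=tuple(v["polarization"]["thresholds"]),
            )
            pol.direction_bias_table(bias).to_csv(
                out / f"direction_bias_{flow_name}.tsv", sep="\t", index=False
            )

            report["stages"][flow_name] = {
                "n_index_snps": len(clumped.index_snps),
                "n_markers": len(annotation.marker_ids),
                "ks_statistic": ks_stat,
                "ks_p": ks_p,
                "enrichment": [
                    {"threshold": r.threshold, "or": r.odds_ratio, "p": r.p_fisher,
                     "table": list(r.table), "underpowered": r.underpowered}
                    for r in enrich
                ],
                "spearman": None
                if corr is None
                else {"rho": corr.rho, "p_asymptotic": corr.p_asymptotic,
                      "p_perm": corr.p_perm, "n_perm": corr.n_perm},
                "unpolarizable_frac": float(
                    (pol_tab["polarization_status"] == "unpolarizable").mean()
                ),
            }

            if flow_name == "clump_by_assoc" and cohort is not None:
                stage = "pgs"
                report["stages"]["pgs"] = _pgs_stage(
                    v, seed, out, harmonized, annotation, pol_tab,
                    p_rns, p_assoc, clumped, cohort, gwas_disc, hpanel, genes,
                )

        if len(run_flows) == 2:
            report["marker_overlap"] = len(
                marker_sets["clump_by_assoc"] & marker_sets["clump_by_rns"]
            )
    except RnsgwasError as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _pgs_stage(v, seed, out, harmonized, annotation, pol_tab, p_rns, p_assoc,
               clumped, cohort, gwas_disc, hpanel, genes) -> dict:
    """Quantile trend, matched-null and direction-stratified PGS analyses."""
    pcfg = v["pgs"]
    harm = harmonized.set_index("snp_id")
    # discovery weights oriented to the cohort's counted (alt) allele
    if gwas_disc is not None:
        disc = gwas_disc.table.set_index("snp_id")
        shared = harm.index.intersection(disc.index)
        sign = np.where(harm.loc[shared, "alt"] == disc.loc[shared, "a1"], 1.0, -1.0)
        weight_alt = pd.Series(
            np.log(disc.loc[shared, "or_effect"].to_numpy()) * sign, index=shared
        )
    else:
        sign = np.where(harm["effect_is_alt"], 1.0, -1.0)
        weight_alt = pd.Series(np.log(harm["or_effect"].to_numpy()) * sign,
                               index=harm.index)

    index_ids = [s for s in clumped.index_snps if s in weight_alt.index]
    cohort_ids = set(cohort.snp_ids)
    index_ids = [s for s in index_ids if s in cohort_ids]
    snp_table = pd.DataFrame(
        {
            "snp_id": index_ids,
            "p_assoc": p_assoc.loc[index_ids].to_numpy(),
            "p_rns": p_rns.loc[index_ids].to_numpy(),
            "weight": weight_alt.loc[index_ids].to_numpy(),
        }
    )
    result: dict = {}

    trend = pgsmod.quantile_trend(
        snp_table, cohort, n_quantiles=pcfg["n_quantiles"], p_t=pcfg["p_t"]
    )
    pd.DataFrame(
        {
            "QUANTILE": np.arange(1, trend.n_quantiles + 1),
            "N_SNPS": [e.n_snps for e in trend.per_quantile],
            "R2_INCREMENT": [e.pseudo_r2_increment for e in trend.per_quantile],
            "P": [e.p_assoc_pgs for e in trend.per_quantile],
        }
    ).to_csv(out / "quantile_trend.tsv", sep="\t", index=False)
    result["quantile_trend"] = {
        "slope": trend.slope, "t": trend.t_stat, "p": trend.p_trend,
        "n_quantiles": trend.n_quantiles,
    }

    sub = snp_table[snp_table["p_assoc"] < pcfg["p_t"]].sort_values("p_rns")
    size = len(sub) // pcfg["n_quantiles"]
    first_q = list(sub["snp_id"].iloc[:size])
    pool = list(sub["snp_id"].iloc[size:])
    props = ldm.annotate_properties(hpanel, genes)
    try:
        sets, widenings = draw_matched_sets_widening(
            first_q, pool, props, n_sets=pcfg["n_sets"],
            seed=child_seed(seed, "matched"),
        )
        null = pgsmod.matched_null_pgs(first_q, sets, cohort, weight_alt)
        result["matched_null"] = {
            "target_r2": null.target.pseudo_r2_increment,
            "null_r2_median": float(np.median(null.null_r2)),
            "empirical_p": null.empirical_p,
            "n_sets": len(null.null_r2),
            "tolerance_widenings": widenings,
        }
    except MatchingInfeasibleError as exc:
        result["matched_null"] = {"skipped": str(exc)}

    pol_idx = pol_tab.set_index("snp_id")
    strata: dict[tuple[str, str], list[str]] = {k: [] for k in pgsmod.STRATA}
    for s in index_ids:
        if s not in pol_idx.index:
            continue
        row = pol_idx.loc[s]
        if row["polarization_status"] == "unpolarizable" or row["derived_or"] == 1:
            continue
        status = "marker" if annotation.is_marker.get(s, False) else "non_marker"
        direction = "protective" if row["derived_or"] < 1 else "risk"
        strata[(status, direction)].append(s)
    n_per_draw = min(
        pcfg["n_snps_per_draw"], *(len(ids) for ids in strata.values())
    )
    if n_per_draw >= 10:
        strat = pgsmod.direction_stratified_pgs(
            strata, cohort, weight_alt, n_draws=pcfg["n_draws"],
            n_snps_per_draw=n_per_draw, seed=child_seed(seed, "strata"),
        )
        result["direction_stratified"] = {
            "medians": strat.medians,
            "wilcoxon_p": strat.wilcoxon_p,
            "n_snps_per_draw": n_per_draw,
        }
    else:
        result["direction_stratified"] = {
            "skipped": f"smallest stratum has {n_per_draw} SNPs"
        }
    return result


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
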