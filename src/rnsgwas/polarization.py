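"""Derived-allele polarization of GWAS effects and direction-bias tests.

The ancestral allele (the state of the human-primate common ancestor)
identifies which allele is derived — the one that arose during human
evolution. Re-orienting each odds ratio to the derived allele
(``derived_or``) lets the direction of selection-associated effects be
read directly: derived_or < 1 means the new allele protects, > 1 means it
confers risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import RnsgwasError
from .enrichment import RnsAnnotation, fisher_exact_2x2

#: association-p cutoffs for the direction-bias cascade (extends the
#: enrichment grid down to genome-wide-significant-and-beyond)
DIRECTION_THRESHOLDS = (
    5e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5,
)


def polarize_to_derived(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Re-orient each record's OR to the derived allele.

    ``harmonized`` needs columns snp_id, a1, a2, or_effect, ancestral and
    aa_low_conf (as produced by :func:`rnsgwas.formats_io.harmonize`).
    When the ancestral allele is the non-effect allele, the effect allele is
    derived and derived_or = or_effect; when the ancestral allele IS the
    effect allele, derived_or = 1/or_effect. A missing ancestral call, or
    one matching neither allele, leaves the record unpolarizable
    (derived_or = nan). Lowercase ancestral calls are accepted
    case-insensitively and flagged low-confidence.
    """
    a1 = harmonized["a1"].astype(str).str.upper().to_numpy()
    a2 = harmonized["a2"].astype(str).str.upper().to_numpy()
    anc_raw = harmonized["ancestral"].to_numpy(dtype=object)
    orv = harmonized["or_effect"].astype(float).to_numpy()

    anc = np.array(
        [str(v).upper() if isinstance(v, str) and str(v).strip() else None
         for v in anc_raw],
        dtype=object,
    )
    anc = np.where([v in ("A", "C", "G", "T") if v else False for v in anc], anc, None)
    low_src = np.array(
        [isinstance(v, str) and v.islower() for v in anc_raw]
    )
    if "aa_low_conf" in harmonized.columns:
        low_src = low_src | harmonized["aa_low_conf"].fillna(False).to_numpy(bool)

    effect_is_derived = anc == a2
    effect_is_ancestral = anc == a1
    status = np.where(
        effect_is_derived,
        "effect_is_derived",
        np.where(effect_is_ancestral, "effect_is_ancestral", "unpolarizable"),
    )
    derived_or = np.where(
        effect_is_derived, orv, np.where(effect_is_ancestral, 1.0 / orv, np.nan)
    )
    with np.errstate(invalid="ignore"):
        log10_dor = np.log10(derived_or)
    return pd.DataFrame(
        {
            "snp_id": harmonized["snp_id"].to_numpy(),
            "derived_or": derived_or,
            "log10_dor": log10_dor,
            "polarization_status": status,
            "low_confidence": low_src & (status != "unpolarizable"),
        }
    )


@dataclass
class DirectionBiasResult:
    threshold: float
    group: str                      # "marker" or "non_marker"
    n_protective: int
    n_risk: int
    n_neutral: int                  # derived_or exactly 1
    mean_log10_dor: float
    ci95: tuple[float, float]
    p_t_one_sample: float
    p_t_two_sample: float
    p_chisq_proportions: float
    underpowered: bool = False
    zero_variance: bool = False
    chisq_used_fisher: bool = False


def _cell_stats(vals: np.ndarray) -> tuple[float, tuple[float, float], float, bool]:
    """Mean log10 derived-OR with t-based 95% CI and one-sample t vs 0."""
    n = len(vals)
    mean = float(vals.mean()) if n else np.nan
    if n < 2:
        return mean, (np.nan, np.nan), np.nan, False
    sd = vals.std(ddof=1)
    if sd == 0:
        return mean, (mean, mean), np.nan, True
    half = stats.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n)
    t_res = stats.ttest_1samp(vals, 0.0)
    return mean, (mean - half, mean + half), float(t_res.pvalue), False


def direction_bias_tests(
    polarized: pd.DataFrame,
    annotation: RnsAnnotation,
    p_assoc: pd.Series,
    thresholds: tuple[float, ...] = DIRECTION_THRESHOLDS,
    min_cell: int = 2,
) -> list[DirectionBiasResult]:
    """Protection-vs-risk bias inside and outside the marker set.

    Per (threshold, group) cell: protective/risk counts (derived_or exactly
    1 tracked separately), mean log10 derived-OR with 95% CI — a CI
    containing 0 means no direction bias — a one-sample t-test against 0, a
    Welch two-sample t-test marker vs non-marker at the same threshold, and
    a chi-square test on the risk-proportion 2x2 (Fisher's exact when any
    expected count is below 5).
    """
    pol = polarized.set_index("snp_id")
    ids = [s for s in annotation.is_marker.index if s in pol.index]
    pol = pol.loc[ids]
    polarizable = pol["polarization_status"] != "unpolarizable"
    dor = pol["derived_or"].to_numpy()
    ldor = pol["log10_dor"].to_numpy()
    is_marker = annotation.is_marker.loc[ids].to_numpy()
    p = p_assoc.loc[ids].to_numpy()
    usable = polarizable.to_numpy()

    out: list[DirectionBiasResult] = []
    for t in thresholds:
        below = p < t
        cells = {}
        for group, gmask in (("marker", is_marker), ("non_marker", ~is_marker)):
            m = usable & below & gmask
            cells[group] = {
                "vals": ldor[m],
                "n_prot": int((dor[m] < 1).sum()),
                "n_risk": int((dor[m] > 1).sum()),
                "n_neut": int((dor[m] == 1).sum()),
            }
        # Welch t between groups
        v_m, v_n = cells["marker"]["vals"], cells["non_marker"]["vals"]
        if len(v_m) >= 2 and len(v_n) >= 2 and (v_m.std() > 0 or v_n.std() > 0):
            p_two = float(stats.ttest_ind(v_m, v_n, equal_var=False).pvalue)
        else:
            p_two = np.nan
        # proportion-of-risk 2x2 across groups
        tab = np.array(
            [
                [cells["marker"]["n_risk"], cells["marker"]["n_prot"]],
                [cells["non_marker"]["n_risk"], cells["non_marker"]["n_prot"]],
            ]
        )
        used_fisher = False
        if tab.sum() == 0 or (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            p_chi = np.nan
        else:
            expected = stats.contingency.expected_freq(tab)
            if (expected < 5).any():
                p_chi = fisher_exact_2x2(*tab.ravel(), alternative="two_sided").p
                used_fisher = True
            else:
                p_chi = float(stats.chi2_contingency(tab, correction=False)[1])

        for group in ("marker", "non_marker"):
            cell = cells[group]
            mean, ci, p_one, zero_var = _cell_stats(cell["vals"])
            out.append(
                DirectionBiasResult(
                    threshold=float(t),
                    group=group,
                    n_protective=cell["n_prot"],
                    n_risk=cell["n_risk"],
                    n_neutral=cell["n_neut"],
                    mean_log10_dor=mean,
                    ci95=ci,
                    p_t_one_sample=p_one,
                    p_t_two_sample=p_two,
                    p_chisq_proportions=p_chi,
                    underpowered=len(cell["vals"]) < min_cell,
                    zero_variance=zero_var,
                    chisq_used_fisher=used_fisher,
                )
            )
    return out


def direction_bias_table(results: list[DirectionBiasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "THRESHOLD": [r.threshold for r in results],
            "GROUP": [r.group for r in results],
            "N_PROTECTIVE": [r.n_protective for r in results],
            "N_RISK": [r.n_risk for r in results],
            "N_NEUTRAL": [r.n_neutral for r in results],
            "MEAN_LOG10_DOR": [r.mean_log10_dor for r in results],
            "CI_LO": [r.ci95[0] for r in results],
            "CI_HI": [r.ci95[1] for r in results],
            "P_T_ONE_SAMPLE": [r.p_t_one_sample for r in results],
            "P_T_TWO_SAMPLE": [r.p_t_two_sample for r in results],
            "P_CHISQ_PROP": [r.p_chisq_proportions for r in results],
            "UNDERPOWERED": [r.underpowered for r in results],
        }
    )
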