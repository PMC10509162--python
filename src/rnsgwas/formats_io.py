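"""Reading, writing and harmonizing the pipeline's file formats.

Genotypes come in as VCF (with the 1000 Genomes-style ancestral-allele ``AA``
INFO tag), GWAS summary statistics as tab-separated text, and exclusion
regions / gene annotations as BED. Coordinates follow each format's native
convention: VCF and GWAS positions are 1-based, BED intervals are 0-based
half-open.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import (
    EmptyPanelError,
    FormatError,
    SchemaError,
    allele_frequency,
)

MISSING = -1

#: default header names for GWAS summary text files
DEFAULT_GWAS_COLUMNS = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "or_effect": "OR",
    "se": "SE",
    "p_assoc": "P",
    "info": "INFO",
    "freq_a1": "FRQ",
}

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class RegionSet:
    """A labelled set of genomic intervals, 0-based half-open."""

    intervals: list[tuple[str, int, int]]
    label: str = ""

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals, key=lambda t: (str(t[0]), t[1], t[2]))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, start, end in self.intervals:
            self._by_chrom.setdefault(str(chrom), ([], []))  # type: ignore[arg-type]
        for chrom in self._by_chrom:
            starts = [s for c, s, e in self.intervals if str(c) == chrom]
            ends = [e for c, s, e in self.intervals if str(c) == chrom]
            self._by_chrom[chrom] = (np.asarray(starts), np.asarray(ends))

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: np.ndarray | list, pos_1based: np.ndarray | list) -> np.ndarray:
        """Vectorized membership test for 1-based point positions."""
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos_1based, dtype=np.int64) - 1
        out = np.zeros(len(pos0), dtype=bool)
        for c, (starts, ends) in self._by_chrom.items():
            m = chrom == c
            if not m.any():
                continue
            p = pos0[m]
            # an interval covers p iff start <= p < end; intervals may overlap
            hit = np.zeros(len(p), dtype=bool)
            for s, e in zip(starts, ends):
                hit |= (p >= s) & (p < e)
            out[m] = hit
        return out

    @classmethod
    def from_bed(cls, path: str | os.PathLike, label: str = "") -> "RegionSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"bad BED line in {path}: {line!r}")
                rows.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(rows, label=label or str(path))

    def to_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass
class GenotypePanel:
    """Samples x SNPs dosage matrix with per-SNP and per-sample metadata.

    ``snps`` has columns snp_id, chrom, pos, ref, alt, ancestral (uppercase
    base or None) and aa_low_conf (True when the source AA call was
    lowercase, the 1000 Genomes convention for low-confidence alignments).
    ``dosage`` counts copies of the alt allele; missing genotypes are the
    sentinel ``MISSING`` (-1).
    """

    snps: pd.DataFrame
    dosage: np.ndarray
    sample_ids: np.ndarray
    population: np.ndarray

    def __post_init__(self):
        self.snps = self.snps.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage)
        self.sample_ids = np.asarray(self.sample_ids)
        self.population = np.asarray(self.population)
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError("dosage shape does not match sample/SNP metadata")
        vals = np.unique(self.dosage)
        if not np.isin(vals, [MISSING, 0, 1, 2]).all():
            raise ValueError("dosage values must be in {0,1,2} or missing")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be sorted within chromosome")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def alt_freq(self) -> np.ndarray:
        return allele_frequency(self.dosage, missing=MISSING)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, mask_or_index) -> "GenotypePanel":
        idx = np.arange(self.n_snps)[mask_or_index]
        return GenotypePanel(
            snps=self.snps.iloc[idx],
            dosage=self.dosage[:, idx],
            sample_ids=self.sample_ids,
            population=self.population,
        )

    def subset_samples(self, mask_or_index) -> "GenotypePanel":
        idx = np.arange(self.n_samples)[mask_or_index]
        return GenotypePanel(
            snps=self.snps,
            dosage=self.dosage[idx, :],
            sample_ids=self.sample_ids[idx],
            population=self.population[idx],
        )


@dataclass
class GwasSummary:
    """Per-SNP GWAS association records.

    ``table`` columns: snp_id, chrom, pos, a1 (effect allele), a2,
    or_effect (odds ratio for a1), se (SE of log-odds), p_assoc, info,
    freq_a1. Rows are sorted by (chrom, pos).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = list(DEFAULT_GWAS_COLUMNS)
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise SchemaError(f"GwasSummary missing columns: {missing}")
        bad = t.loc[~(t["or_effect"] > 0), "snp_id"].tolist()
        if bad:
            raise SchemaError(f"non-positive OR for SNPs: {bad[:10]}")
        bad = t.loc[~((t["p_assoc"] > 0) & (t["p_assoc"] <= 1)), "snp_id"].tolist()
        if bad:
            raise SchemaError(f"p_assoc outside (0,1] for SNPs: {bad[:10]}")
        if (t["a1"] == t["a2"]).any():
            raise SchemaError("records with identical effect/other allele")
        self.table = (
            t.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.table)


def _parse_aa(raw) -> tuple[str | None, bool]:
    """Parse a 1000 Genomes-style AA INFO value.

    Values look like "a", "G" or "G|||"; the first field's first character
    is the call. Lowercase marks a low-confidence alignment. Anything
    outside ACGT (".", "N", "-") is treated as missing.
    """
    if raw is None:
        return None, False
    s = str(raw).split("|")[0].strip()
    if not s:
        return None, False
    base = s[0]
    if base.upper() in "ACGT":
        return base.upper(), base.islower()
    return None, False


def read_genotypes(
    vcf_path: str | os.PathLike,
    region_excludes: RegionSet | None = None,
    populations: dict[str, str] | None = None,
) -> GenotypePanel:
    """Load a VCF into a :class:`GenotypePanel`.

    Only biallelic SNPs are kept (indels and multi-allelic records are
    dropped), and any record falling inside ``region_excludes`` is removed.
    Sample population labels come from ``populations`` (sample id -> label);
    when absent, the prefix of the sample id before the first underscore is
    used.
    """
    try:
        from cyvcf2 import VCF
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # unreadable / not a VCF
        raise FormatError(f"cannot read VCF {vcf_path}: {exc}") from exc

    samples = np.asarray(vcf.samples)
    snp_rows = []
    dos_cols = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            continue
        anc, low = _parse_aa(var.INFO.get("AA"))
        # gts012: 0/1/2 alt-allele count, 3 = missing
        g = np.asarray(var.gt_types, dtype=np.int16)
        g[g == 3] = MISSING
        snp_rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": ref,
                "alt": alt,
                "ancestral": anc,
                "aa_low_conf": low,
            }
        )
        dos_cols.append(g)
    vcf.close()

    if not snp_rows:
        raise EmptyPanelError(f"no biallelic SNPs in {vcf_path}")
    snps = pd.DataFrame(snp_rows)
    dosage = np.column_stack(dos_cols) if dos_cols else np.empty((len(samples), 0))

    if region_excludes is not None and len(region_excludes):
        inside = region_excludes.contains(snps["chrom"].to_numpy(), snps["pos"].to_numpy())
        snps = snps.loc[~inside]
        dosage = dosage[:, ~inside]
    if len(snps) == 0:
        raise EmptyPanelError("no SNPs left after region exclusion")

    if populations is not None:
        pops = np.asarray([populations.get(s, "unknown") for s in samples])
    else:
        pops = np.asarray([s.split("_")[0] for s in samples])
    return GenotypePanel(snps=snps, dosage=dosage, sample_ids=samples, population=pops)


def write_vcf(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Write a panel back out as uncompressed VCF 4.2 with GT and INFO/AA."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in dict.fromkeys(panel.snps["chrom"].astype(str)):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(map(str, panel.sample_ids)) + "\n")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, row in enumerate(panel.snps.itertuples(index=False)):
        anc = row.ancestral
        if anc is None or (isinstance(anc, float) and np.isnan(anc)):
            info = "."
        else:
            info = f"AA={anc.lower() if row.aa_low_conf else anc}"
        gts = "\t".join(gt_map[int(v)] for v in panel.dosage[:, j])
        buf.write(
            f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
            f"\t.\t.\t{info}\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_gwas(
    tsv_path: str | os.PathLike,
    info_min: float = 0.9,
    column_map: dict[str, str] | None = None,
) -> GwasSummary:
    """Read tab-separated GWAS summary statistics.

    Records with imputation quality ``info <= info_min`` are removed.
    The effect column may be an odds ratio (``OR``) or a log-odds ``BETA``
    (converted via OR = exp(BETA)). Header names can be remapped through
    ``column_map`` (canonical field -> file header).
    """
    cmap = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(tsv_path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot read GWAS table {tsv_path}: {exc}") from exc

    have_or = cmap["or_effect"] in raw.columns
    have_beta = "BETA" in raw.columns
    required = {k: v for k, v in cmap.items() if k != "or_effect"}
    missing = [v for v in required.values() if v not in raw.columns]
    if not (have_or or have_beta):
        missing.append(f"{cmap['or_effect']} (or BETA)")
    if missing:
        raise SchemaError(f"GWAS table {tsv_path} missing columns: {missing}")

    t = pd.DataFrame(
        {
            field: raw[header].to_numpy()
            for field, header in required.items()
        }
    )
    if have_or:
        t["or_effect"] = raw[cmap["or_effect"]].astype(float).to_numpy()
    else:
        t["or_effect"] = np.exp(raw["BETA"].astype(float).to_numpy())
    t["chrom"] = t["chrom"].astype(str)
    t["pos"] = t["pos"].astype(int)
    for col in ("se", "p_assoc", "info", "freq_a1"):
        t[col] = t[col].astype(float)
    for col in ("a1", "a2"):
        t[col] = t[col].astype(str).str.upper()
    t = t[t["info"] > info_min].reset_index(drop=True)
    return GwasSummary(table=t)


def write_gwas(gwas: GwasSummary, path: str | os.PathLike,
               column_map: dict[str, str] | None = None) -> None:
    cmap = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        cmap.update(column_map)
    out = gwas.table.rename(columns=cmap)
    out.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizeReport:
    n_panel: int
    n_gwas: int
    n_joined: int
    n_allele_mismatch: int
    n_maf_filtered: int
    n_ambiguous_kept: int
    n_ambiguous_dropped: int


def harmonize(
    panel: GenotypePanel,
    gwas: GwasSummary,
    maf_min: float = 0.05,
    drop_ambiguous: bool = False,
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Inner-join panel and GWAS records on (chrom, pos) and align alleles.

    A joined SNP is kept when {a1,a2} equals {ref,alt} regardless of order;
    ``effect_is_alt`` records whether the GWAS effect allele is the panel
    alt allele, so dosages (alt counts) and ORs can be put on one scale.
    Strand-ambiguous A/T and C/G SNPs are flagged and kept by default.
    SNPs with panel MAF below ``maf_min`` are removed.
    """
    psnps = panel.snps.copy()
    psnps["panel_idx"] = np.arange(len(psnps))
    psnps["maf"] = panel.maf()
    psnps["alt_freq"] = panel.alt_freq()
    merged = psnps.merge(
        gwas.table, on=["chrom", "pos"], how="inner", suffixes=("", "_gwas")
    )

    same = (merged["a1"] == merged["alt"]) & (merged["a2"] == merged["ref"])
    flipped = (merged["a1"] == merged["ref"]) & (merged["a2"] == merged["alt"])
    match = same | flipped
    n_mismatch = int((~match).sum())
    merged = merged[match].copy()
    merged["effect_is_alt"] = same[match].to_numpy()

    merged["ambiguous"] = [
        frozenset((r, a)) in _AMBIGUOUS_PAIRS
        for r, a in zip(merged["ref"], merged["alt"])
    ]
    n_amb = int(merged["ambiguous"].sum())
    n_amb_dropped = 0
    if drop_ambiguous:
        n_amb_dropped = n_amb
        merged = merged[~merged["ambiguous"]]

    low_maf = merged["maf"] < maf_min
    n_maf = int(low_maf.sum())
    merged = merged[~low_maf].reset_index(drop=True)

    report = HarmonizeReport(
        n_panel=panel.n_snps,
        n_gwas=len(gwas),
        n_joined=len(merged),
        n_allele_mismatch=n_mismatch,
        n_maf_filtered=n_maf,
        n_ambiguous_kept=0 if drop_ambiguous else n_amb,
        n_ambiguous_dropped=n_amb_dropped,
    )
    return merged, report
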