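import numpy as np
import pandas as pd
import pytest

from rnsgwas.formats_io import GenotypePanel, RegionSet


def make_panel(dosage, chrom=None, pos=None, ref=None, alt=None,
               ancestral=None, populations=None):
    """Build a GenotypePanel from a samples x SNPs array with defaults."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, p = dosage.shape
    chrom = chrom if chrom is not None else ["1"] * p
    pos = pos if pos is not None else list(range(1000, 1000 + 1000 * p, 1000))
    ref = ref if ref is not None else ["A"] * p
    alt = alt if alt is not None else ["G"] * p
    anc = ancestral if ancestral is not None else [None] * p
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(p)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "ancestral": anc,
            "aa_low_conf": [False] * p,
        }
    )
    pops = populations if populations is not None else ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return GenotypePanel(
        snps=snps,
        dosage=dosage,
        sample_ids=np.array([f"s{i}" for i in range(n)]),
        population=np.array(pops),
    )


def hwe_panel(p1, p2, n1, n2, n_snps=1, rng=None):
    """Two populations with exact-as-possible HWE genotype counts."""
    def hwe_column(p, n):
        n_hom_alt = int(round(n * p * p))
        n_het = int(round(n * 2 * p * (1 - p)))
        n_hom_ref = n - n_hom_alt - n_het
        return np.array([2] * n_hom_alt + [1] * n_het + [0] * n_hom_ref)

    cols = [np.concatenate([hwe_column(p1, n1), hwe_column(p2, n2)])
            for _ in range(n_snps)]
    return make_panel(np.column_stack(cols),
                      populations=["A"] * n1 + ["B"] * n2)


@pytest.fixture(scope="session")
def planted_scan():
    """One strong-selection scenario with its scan, shared across tests."""
    from rnsgwas import selection_scan as scan
    from rnsgwas import simulate as sim

    cfg = sim.scenario_config(
        "planted", n_snps=5000, n_per_pop=50, fst_drift=0.05, delta_sel=0.45,
        seed=11,
    )
    panel, truth, genes = sim.simulate_populations(cfg)
    model = scan.fit_pca(panel, k=3, seed=11)
    result = scan.scan_pvalues(panel, model, seed=11)
    return cfg, panel, truth, genes, model, result
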