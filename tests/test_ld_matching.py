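import numpy as np
import pandas as pd
import pytest

from rnsgwas import ld_matching as ldm
from rnsgwas import simulate as sim
from rnsgwas._utils import MatchingInfeasibleError, RnsgwasError
from rnsgwas.formats_io import RegionSet
from conftest import make_panel


def brute_force_clump(snp_tab, r2, r2_max, window):
    """Independent reference: explicit greedy loop over a precomputed r2
    matrix (no shared code with ld_clump)."""
    ids = list(snp_tab["snp_id"])
    order = sorted(
        range(len(ids)),
        key=lambda i: (snp_tab["p"].iloc[i], snp_tab["chrom"].iloc[i],
                       snp_tab["pos"].iloc[i]),
    )
    absorbed = set()
    index = []
    for i in order:
        if i in absorbed:
            continue
        index.append(ids[i])
        absorbed.add(i)
        for j in range(len(ids)):
            if j in absorbed:
                continue
            same_chrom = snp_tab["chrom"].iloc[i] == snp_tab["chrom"].iloc[j]
            close = abs(snp_tab["pos"].iloc[i] - snp_tab["pos"].iloc[j]) <= window
            if same_chrom and close and r2[i, j] >= r2_max:
                absorbed.add(j)
    return index


def pairwise_r2(panel):
    z, _, _ = __import__("rnsgwas._utils", fromlist=["standardize_dosage"]).standardize_dosage(
        panel.dosage
    )
    z = z - z.mean(axis=0)
    norms = np.linalg.norm(z, axis=0)
    norms[norms == 0] = 1.0
    zn = z / norms
    return (zn.T @ zn) ** 2


def snp_table_for(panel, pvals):
    return pd.DataFrame(
        {
            "snp_id": panel.snps["snp_id"].to_numpy(),
            "chrom": panel.snps["chrom"].to_numpy(),
            "pos": panel.snps["pos"].to_numpy(),
            "p": pvals,
        }
    )


class TestLdClump:
    def test_single_snp_is_its_own_index(self):
        panel = make_panel([[0], [1], [2], [1]])
        res = ldm.ld_clump(snp_table_for(panel, [0.5]), panel)
        assert res.index_snps == ["snp0"] and res.removed_by == {}

    def test_perfect_ld_pair_absorbed_by_smaller_p(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0]])
        panel = make_panel(g, pos=[1000, 11000])
        res = ldm.ld_clump(snp_table_for(panel, [1e-8, 1e-4]), panel,
                           r2_max=0.1, window_kb=500)
        assert res.index_snps == ["snp0"]
        assert res.removed_by == {"snp1": "snp0"}

    def test_three_snp_partial_ld_case(self):
        """A (p=1e-8) absorbs B (r2=0.5 with A); C independent stays."""
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, size=200)
        noise = rng.integers(0, 3, size=200)
        b = np.where(rng.uniform(size=200) < 0.75, a, noise)  # correlated
        c = rng.integers(0, 3, size=200)                      # independent
        panel = make_panel(np.column_stack([a, b, c]),
                           pos=[1000, 2000, 3000])
        r2 = pairwise_r2(panel)
        assert r2[0, 1] > 0.3 and r2[0, 2] < 0.05
        res = ldm.ld_clump(snp_table_for(panel, [1e-8, 1e-4, 1e-3]), panel,
                           r2_max=0.1, window_kb=500)
        assert res.index_snps == ["snp0", "snp2"]
        assert res.removed_by == {"snp1": "snp0"}

    def test_missing_snp_in_panel_rejected(self):
        panel = make_panel([[0], [1], [2]])
        tab = pd.DataFrame(
            {"snp_id": ["ghost"], "chrom": ["1"], "pos": [5], "p": [0.1]}
        )
        with pytest.raises(RnsgwasError, match="ghost"):
            ldm.ld_clump(tab, panel)

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence_random_instances(self, seed):
        """Greedy result equals an independent brute force on <= 20 SNPs."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 21))
        n = 40
        base = rng.integers(0, 3, size=(n, p))
        # induce random correlation by copying columns with noise
        for j in range(1, p):
            if rng.uniform() < 0.5:
                src = rng.integers(0, j)
                mask = rng.uniform(size=n) < 0.8
                base[:, j] = np.where(mask, base[:, src], base[:, j])
        pos = np.sort(rng.choice(np.arange(1, 2001) * 1000, size=p, replace=False))
        panel = make_panel(base, pos=list(pos))
        pvals = rng.uniform(size=p)
        tab = snp_table_for(panel, pvals)
        window_kb = int(rng.choice([100, 500, 1000]))
        r2_max = float(rng.choice([0.1, 0.3, 0.8]))

        res = ldm.ld_clump(tab, panel, r2_max=r2_max, window_kb=window_kb)
        expected = brute_force_clump(tab, pairwise_r2(panel), r2_max,
                                     window_kb * 1000)
        assert res.index_snps == expected

    def test_every_snp_indexed_or_absorbed_once(self, planted_scan):
        _, panel, _, _, _, res = planted_scan
        sub = panel.subset_snps(np.arange(600))
        tab = snp_table_for(sub, res.p_rns[:600])
        clumped = ldm.ld_clump(tab, sub, r2_max=0.1, window_kb=100)
        covered = set(clumped.index_snps) | set(clumped.removed_by)
        assert covered == set(sub.snps["snp_id"])
        assert not (set(clumped.index_snps) & set(clumped.removed_by))

    def test_index_snps_mutually_quasi_independent(self, planted_scan):
        _, panel, _, _, _, res = planted_scan
        sub = panel.subset_snps(np.arange(400))
        tab = snp_table_for(sub, res.p_rns[:400])
        clumped = ldm.ld_clump(tab, sub, r2_max=0.1, window_kb=100)
        r2 = pairwise_r2(sub)
        idx = {s: i for i, s in enumerate(sub.snps["snp_id"])}
        pos = sub.snps.set_index("snp_id")["pos"]
        for a in clumped.index_snps:
            for b in clumped.index_snps:
                if a < b and abs(pos[a] - pos[b]) <= 100_000:
                    assert r2[idx[a], idx[b]] < 0.1


class TestAnnotateProperties:
    def test_gene_distance_zero_inside_and_positive_outside(self):
        panel = make_panel(np.random.default_rng(0).integers(0, 3, size=(30, 3)),
                           pos=[500, 1500, 5001])
        genes = RegionSet([("1", 1000, 2000)])
        props = ldm.annotate_properties(panel, genes)
        assert props.loc["snp1", "gene_dist"] == 0
        assert props.loc["snp0", "gene_dist"] == 1000 - (500 - 1)
        assert props.loc["snp2", "gene_dist"] == (5001 - 1) - (2000 - 1)

    def test_no_genes_gives_infinite_distance_zero_density(self):
        panel = make_panel(np.random.default_rng(0).integers(0, 3, size=(30, 2)))
        props = ldm.annotate_properties(panel, None)
        assert np.isinf(props["gene_dist"]).all()
        assert (props["gene_density"] == 0).all()

    def test_independent_snps_have_no_buddies(self):
        rng = np.random.default_rng(3)
        panel = make_panel(rng.integers(0, 3, size=(500, 10)))
        props = ldm.annotate_properties(panel)
        assert (props["ld_buddies"] == 0).all()

    def test_maf_folds_above_half(self):
        # alt freq 0.7 -> maf 0.3
        col = np.array([2] * 5 + [1] * 4 + [0] * 1)
        panel = make_panel(col[:, None])
        props = ldm.annotate_properties(panel)
        assert np.isclose(props["maf"].iloc[0], 0.3)

    def test_block_structure_counted_as_buddies(self):
        cfg = sim.scenario_config("neutral", n_pops=2, n_per_pop=100,
                                  n_snps=300, ld_block=5, seed=4)
        panel, _, _ = sim.simulate_populations(cfg)
        props = ldm.annotate_properties(panel)
        assert props["ld_buddies"].median() >= 2


class TestDrawMatchedSets:
    def make_props(self, rows, ids=None):
        ids = ids or [f"t{i}" for i in range(len(rows))]
        return pd.DataFrame(
            rows, index=pd.Index(ids, name="snp_id"),
            columns=["maf", "ld_buddies", "gene_dist", "gene_density"],
        )

    def test_exact_copies_always_feasible(self):
        targets = self.make_props([[0.2, 3, 1000, 2], [0.4, 0, 0, 1]],
                                  ids=["t0", "t1"])
        pool = self.make_props([[0.2, 3, 1000, 2], [0.4, 0, 0, 1]],
                               ids=["p0", "p1"])
        props = pd.concat([targets, pool])
        sets = ldm.draw_matched_sets(["t0", "t1"], ["p0", "p1"], props,
                                     n_sets=5, seed=1)
        assert all(sorted(s) == ["p0", "p1"] for s in sets)

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(2)
        base = np.column_stack([
            rng.uniform(0.05, 0.5, 5), rng.integers(0, 5, 5),
            rng.integers(0, 5000, 5), rng.integers(0, 4, 5)]).astype(float)
        # pool rows jitter the targets slightly, so matching stays feasible
        rows = np.vstack([base] + [base + [0.01, 0, 0, 0]] * 7)
        props = self.make_props(rows, ids=[f"s{i}" for i in range(40)])
        targets = [f"s{i}" for i in range(5)]
        pool = [f"s{i}" for i in range(5, 40)]
        a = ldm.draw_matched_sets(targets, pool, props, n_sets=3, seed=9)
        b = ldm.draw_matched_sets(targets, pool, props, n_sets=3, seed=9)
        assert a == b

    def test_maf_tolerance_boundary(self):
        props = self.make_props(
            [[0.10, 0, 0, 0], [0.14, 0, 0, 0], [0.16, 0, 0, 0]],
            ids=["t", "ok", "far"],
        )
        sets = ldm.draw_matched_sets(["t"], ["ok", "far"], props, n_sets=20,
                                     seed=0)
        assert all(s == ["ok"] for s in sets)

    def test_infeasible_target_named_in_error(self):
        props = self.make_props([[0.1, 0, 0, 0], [0.4, 0, 0, 0]],
                                ids=["t", "p"])
        with pytest.raises(MatchingInfeasibleError, match="t"):
            ldm.draw_matched_sets(["t"], ["p"], props, n_sets=1, seed=0)

    def test_mean_maf_of_sets_close_to_targets(self):
        rng = np.random.default_rng(8)
        n_t, n_p = 20, 400
        t_rows = np.column_stack([
            rng.uniform(0.1, 0.4, n_t), np.zeros(n_t), np.zeros(n_t),
            np.zeros(n_t)])
        p_rows = np.column_stack([
            rng.uniform(0.05, 0.5, n_p), np.zeros(n_p), np.zeros(n_p),
            np.zeros(n_p)])
        ids_t = [f"t{i}" for i in range(n_t)]
        ids_p = [f"p{i}" for i in range(n_p)]
        props = pd.concat([self.make_props(t_rows, ids_t),
                           self.make_props(p_rows, ids_p)])
        sets = ldm.draw_matched_sets(ids_t, ids_p, props, n_sets=10, seed=3)
        target_mean = props.loc[ids_t, "maf"].mean()
        for s in sets:
            assert abs(props.loc[s, "maf"].mean() - target_mean) <= 0.05
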