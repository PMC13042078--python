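import numpy as np
import pandas as pd
import pytest

from paleostack.fstats import (f_stat, jackknife, per_snp_contributions,
                               run_battery)
from paleostack.genio import BlockAssignment, Dataset
from paleostack.simdata import DriftGraphSpec, default_map, simulate_freq_graph
from tests.conftest import build_dataset


# ---------------------------------------------------------------------------
# brute-force oracle: naive per-SNP loops on raw genotype calls
# ---------------------------------------------------------------------------

def oracle_counts(ds, pop):
    groups = ds.ind["group"].to_numpy()
    idx = np.flatnonzero(groups == pop)
    pseudo = ds.is_pseudohaploid()
    x = np.zeros(ds.n_snp)
    n = np.zeros(ds.n_snp)
    for j in range(ds.n_snp):
        for i in idx:
            g = ds.geno[i, j]
            if g == 9:
                continue
            if pseudo[i]:
                x[j] += g // 2
                n[j] += 1
            else:
                x[j] += g
                n[j] += 2
    return x, n


def oracle_terms(ds, kind, pops):
    counts = [oracle_counts(ds, p) for p in pops]
    terms = np.zeros(ds.n_snp)
    mask = np.zeros(ds.n_snp, bool)
    for j in range(ds.n_snp):
        if any(n[j] == 0 for _, n in counts):
            continue
        mask[j] = True
        p = [x[j] / n[j] for x, n in counts]
        h = [x[j] * (n[j] - x[j]) / (n[j] ** 2 * (n[j] - 1)) if n[j] > 1 else 0.0
             for x, n in counts]
        if kind == "f4":
            terms[j] = (p[0] - p[1]) * (p[2] - p[3])
        elif kind == "f3":
            terms[j] = (p[0] - p[1]) * (p[0] - p[2]) - h[0]
        else:
            terms[j] = (p[0] - p[1]) ** 2 - h[0] - h[1]
    return terms, mask


class TestPerSnpContributions:
    def test_f4_identical_last_pops_is_zero(self, tiny_dataset):
        ds, _ = tiny_dataset
        terms, mask = per_snp_contributions(ds, "f4", ["A", "B", "C", "C"])
        assert np.allclose(terms[mask], 0.0)

    def test_hand_computed_f4(self):
        # two SNPs with fixed sample frequencies via constructed genotypes
        a, b, c, d = (0.5, 0.2), (0.1, 0.4), (0.9, 0.1), (0.3, 0.5)
        n = 10  # pseudohaploid haploids per pop
        geno_rows = []
        ind_rows = []
        for pop, fr in zip("ABCD", (a, b, c, d)):
            for i in range(n):
                row = [2 if i < fr[j] * n else 0 for j in range(2)]
                geno_rows.append(row)
                ind_rows.append((f"{pop}{i}", "U", pop))
        snp = pd.DataFrame({"id": ["s0", "s1"], "chrom": "1",
                            "gpos": [0.0, 0.01], "ppos": [1, 2],
                            "ref": "A", "alt": "G"})
        ds = Dataset(np.array(geno_rows, dtype=np.int8), snp,
                     pd.DataFrame(ind_rows, columns=["id", "sex", "group"]))
        terms, mask = per_snp_contributions(ds, "f4", ["A", "B", "C", "D"])
        np.testing.assert_allclose(terms, [0.24, 0.08], atol=1e-12)

    @pytest.mark.parametrize("kind,pops", [
        ("f2", ["A", "B"]),
        ("f3", ["C", "A", "B"]),
        ("f4", ["A", "B", "C", "A"]),
    ])
    def test_matches_brute_force_oracle(self, tiny_dataset, kind, pops):
        ds, _ = tiny_dataset
        terms, mask = per_snp_contributions(ds, kind, pops)
        oterms, omask = oracle_terms(ds, kind, pops)
        np.testing.assert_array_equal(mask, omask)
        np.testing.assert_allclose(terms[mask], oterms[omask], atol=1e-12)

    def test_oracle_equivalence_with_missingness(self, clade_panel):
        ds = build_dataset(clade_panel, [("P1", 4), ("P2", 5), ("O1", 3)],
                           missing=0.3, seed=11)
        ds = Dataset(ds.geno[:, :200], ds.snp.iloc[:200].reset_index(drop=True), ds.ind)
        for kind, pops in [("f2", ["P1", "P2"]), ("f3", ["O1", "P1", "P2"]),
                           ("f4", ["P1", "P2", "O1", "P1"])]:
            terms, mask = per_snp_contributions(ds, kind, pops)
            oterms, omask = oracle_terms(ds, kind, pops)
            np.testing.assert_allclose(terms[mask], oterms[omask], atol=1e-12)

    def test_f4_additivity(self, tiny_dataset):
        ds, _ = tiny_dataset  # fully observed, shared masks exact
        t1, _ = per_snp_contributions(ds, "f4", ["A", "B", "C", "A"])
        t2, _ = per_snp_contributions(ds, "f4", ["A", "B", "C", "B"])
        t3, _ = per_snp_contributions(ds, "f4", ["A", "B", "B", "A"])
        np.testing.assert_allclose(t1, t2 + t3, atol=1e-12)

    def test_f3_of_duplicate_source_relates_to_f2(self, tiny_dataset):
        # algebraically f3(X;A,A) = f2(X,A) + h_A (the source's sampling
        # correction is only subtracted in f2)
        ds, _ = tiny_dataset
        from paleostack.fstats import pop_counts, _het_correction
        f3_terms, _ = per_snp_contributions(ds, "f3", ["C", "A", "A"])
        f2_terms, _ = per_snp_contributions(ds, "f2", ["C", "A"])
        x, n = pop_counts(ds, ["A"])
        h_a = _het_correction(x, n)[0]
        np.testing.assert_allclose(f3_terms, f2_terms + h_a, atol=1e-12)

    def test_unresolvable_label(self, tiny_dataset):
        ds, _ = tiny_dataset
        with pytest.raises(KeyError, match="nosuchpop"):
            per_snp_contributions(ds, "f2", ["A", "nosuchpop"])


class TestJackknife:
    def test_equal_block_means_give_zero_se(self):
        blocks = BlockAssignment(np.repeat(np.arange(5), 10))
        values = np.ones(50) * 0.3
        jk = jackknife(values, np.ones(50, bool), blocks)
        assert jk.estimate == pytest.approx(0.3)
        assert jk.se == pytest.approx(0.0, abs=1e-15)

    def test_matches_classic_unweighted_formula_for_equal_blocks(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=80)
        blocks = BlockAssignment(np.repeat(np.arange(8), 10))
        jk = jackknife(values, np.ones(80, bool), blocks)
        # classic delete-one jackknife
        g = 8
        loo = np.array([values[np.repeat(np.arange(8), 10) != b].mean()
                        for b in range(g)])
        se = np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2))
        assert jk.se == pytest.approx(se, rel=1e-10)

    def test_empty_block_does_not_change_estimate(self):
        values = np.arange(30, dtype=float)
        mask = np.ones(30, bool)
        b1 = BlockAssignment(np.repeat([0, 1, 2], 10))
        idx = np.repeat([0, 1, 3], 10)  # block 2 empty
        b2 = BlockAssignment(idx)
        jk1 = jackknife(values, mask, b1)
        jk2 = jackknife(values, mask, b2)
        assert jk1.estimate == pytest.approx(jk2.estimate)
        assert jk1.se == pytest.approx(jk2.se)

    def test_fewer_than_two_blocks_rejected(self):
        blocks = BlockAssignment(np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            jackknife(np.ones(10), np.ones(10, bool), blocks)


class TestBattery:
    def test_null_clade_not_significant(self, clade_dataset):
        ds, blocks = clade_dataset
        table = run_battery(ds, [("f4", ["O1", t, "P1", "P2"])
                                 for t in ["O2", "O3", "O4"]], blocks)
        assert not table["significant"].any()

    def test_gene_flow_detected(self):
        # P2 receives admixture from D: f4(O, D; P1, P2) deviates from 0
        spec = DriftGraphSpec(
            nodes=["root", "C", "P1", "P2x", "P2", "D", "O"],
            edges=[("root", "C", 0.05), ("C", "P1", 0.02), ("C", "P2x", 0.01),
                   ("root", "D", 0.15), ("root", "O", 0.15)],
            admixture_events=[("P2", "P2x", "D", 0.7)],
        )
        snp = default_map(50_000, n_chrom=10, seed=50)
        panel = simulate_freq_graph(spec, 50_000, seed=50, snp=snp)
        ds = build_dataset(panel, [("P1", 10), ("P2", 10), ("D", 10), ("O", 10)],
                           missing=0.05, seed=51)
        from paleostack.genio import assign_blocks
        table = run_battery(ds, [("f4", ["O", "D", "P1", "P2"])],
                            assign_blocks(ds.snp))
        assert table["significant"].all()
        assert table["z"].iloc[0] > 3  # P2 shares drift with D

    def test_empty_battery(self, clade_dataset):
        ds, blocks = clade_dataset
        assert run_battery(ds, [], blocks).empty

    def test_z_significance_calibration(self, clade_panel):
        """Under a simulated null clade, |Z|>3 is rare (<~1%)."""
        from paleostack.genio import assign_blocks
        hits = 0
        n_rep = 120
        for rep in range(n_rep):
            ds = build_dataset(clade_panel, [("P1", 5), ("P2", 5), ("O1", 5),
                                             ("O2", 5)], missing=0.0, seed=1000 + rep)
            r = f_stat(ds, "f4", ["O1", "O2", "P1", "P2"], assign_blocks(ds.snp))
            hits += abs(r.z) > 3
        assert hits / n_rep <= 0.03
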