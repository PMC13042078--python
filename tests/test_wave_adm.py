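import numpy as np
import pandas as pd
import pytest

from paleostack.genio import Dataset, assign_blocks
from paleostack.scenarios import (REFERENCES, admixture_graph,
                                  fit_admixture_weights,
                                  simulate_admixture_cohort_dataset)
from paleostack.simdata import default_map, simulate_freq_graph
from paleostack.wave_adm import (build_f4_matrix, group_by_cladality,
                                 qpadm_fit, rank_test)
from tests.conftest import build_dataset

RIGHT = ["O1", "O2", "O3", "O4", "O5"]


class TestF4Matrix:
    def test_duplicate_left_population_gives_zero_entries(self, clade_dataset):
        ds, blocks = clade_dataset
        # left_1 literally the same sample set as left_0
        m = build_f4_matrix(ds, ["P1", "P1"], RIGHT, blocks)
        np.testing.assert_allclose(m.X, 0.0, atol=1e-15)

    def test_entries_match_fstats(self, clade_dataset):
        from paleostack.fstats import f_stat
        ds, blocks = clade_dataset
        m = build_f4_matrix(ds, ["P1", "P2"], RIGHT, blocks)
        for j in range(1, len(RIGHT)):
            r = f_stat(ds, "f4", ["P2", "P1", RIGHT[j], RIGHT[0]], blocks,
                       inbreed=False)
            assert m.X[0, j - 1] == pytest.approx(r.estimate, rel=1e-10)

    def test_covariance_matches_block_resampling_oracle(self, clade_dataset):
        from paleostack.fstats import per_snp_contributions
        ds, blocks = clade_dataset
        m = build_f4_matrix(ds, ["P1", "P2"], ["O1", "O2", "O3"], blocks)
        # oracle: delete-one-block estimates computed directly per entry
        nb = blocks.n_blocks
        ents = []
        for right_pop in ["O2", "O3"]:
            terms, mask = per_snp_contributions(
                ds, "f4", ["P2", "P1", right_pop, "O1"], inbreed=False)
            s = np.bincount(blocks.block_index, np.where(mask, terms, 0.0), minlength=nb)
            w = np.bincount(blocks.block_index, mask.astype(float), minlength=nb)
            ents.append(((s.sum() - s) / (w.sum() - w), w))
        # variances from the simple delete-one jackknife should be within a
        # small factor of the Busing-weighted covariance diagonal
        for e, (loo, w) in enumerate(ents):
            g = len(loo)
            var_simple = (g - 1) / g * np.sum((loo - loo.mean()) ** 2)
            assert m.cov[e, e] == pytest.approx(var_simple, rel=0.2)

    def test_dimensions(self, clade_dataset):
        ds, blocks = clade_dataset
        m = build_f4_matrix(ds, ["P1", "P2", "O1"], RIGHT[1:], blocks)
        assert m.X.shape == (2, 3)
        assert m.cov.shape == (6, 6)


class TestRankTest:
    def test_zero_matrix_gives_p_one(self, clade_dataset):
        ds, blocks = clade_dataset
        m = build_f4_matrix(ds, ["P1", "P2"], RIGHT, blocks)
        m.X = np.zeros_like(m.X)
        m.cov = np.eye(m.cov.shape[0]) * 1e-8
        chi2, df, p = rank_test(m, 0)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 4

    def test_clade_null_calibration(self, clade_panel):
        """Rank-0 p-values for a true clade reject at most ~alpha of the time."""
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            ds = build_dataset(clade_panel, [("P1", 8), ("P2", 8)]
                               + [(o, 8) for o in RIGHT], missing=0.05,
                               seed=2000 + rep)
            blocks = assign_blocks(ds.snp)
            m = build_f4_matrix(ds, ["P1", "P2"], RIGHT, blocks)
            _, _, p = rank_test(m, 0)
            rejections += p < 0.05
        assert rejections / n_rep <= 0.10

    def test_non_clade_detected_with_power(self):
        """An admixed left member is rejected as cladal with high power."""
        spec = admixture_graph(w=0.5)
        hits = 0
        n_rep = 6
        for rep in range(n_rep):
            snp = default_map(50_000, n_chrom=10, seed=300 + rep)
            panel = simulate_freq_graph(spec, 50_000, seed=300 + rep, snp=snp)
            ds = build_dataset(panel, [("Target", 12), ("Chibchan", 12)]
                               + [(r, 10) for r in REFERENCES], missing=0.05,
                               seed=301 + rep)
            blocks = assign_blocks(ds.snp)
            m = build_f4_matrix(ds, ["Target", "Chibchan"], REFERENCES, blocks)
            _, _, p = rank_test(m, 0)
            hits += p < 0.05
        assert hits >= 5

    def test_rank0_invariant_to_left_swap(self, clade_dataset):
        ds, blocks = clade_dataset
        c1 = rank_test(build_f4_matrix(ds, ["P1", "P2"], RIGHT, blocks), 0)[0]
        c2 = rank_test(build_f4_matrix(ds, ["P2", "P1"], RIGHT, blocks), 0)[0]
        assert c1 == pytest.approx(c2, rel=1e-6)

    def test_rank_out_of_range(self, clade_dataset):
        ds, blocks = clade_dataset
        m = build_f4_matrix(ds, ["P1", "P2"], RIGHT, blocks)
        with pytest.raises(ValueError):
            rank_test(m, 3)


class TestGrouping:
    def test_single_population_forms_one_group(self, clade_panel):
        ds = build_dataset(clade_panel, [("P1", 6)] + [(o, 8) for o in RIGHT],
                           missing=0.0, seed=70)
        # treat each P1 individual as its own unit
        inds = [f"P1_{i}" for i in range(4)]
        groups, amb = group_by_cladality(ds, inds, RIGHT, assign_blocks(ds.snp))
        assert len(groups) == 1 and sorted(groups[0]) == sorted(inds)
        assert amb == []

    def test_two_distant_populations_split(self, clade_panel):
        # C is ancestral to P1 only, so it separates P1 from O4 in f4 space
        ds = build_dataset(clade_panel, [("P1", 6), ("O4", 6), ("C", 8)]
                           + [(o, 8) for o in ["O1", "O2", "O3", "O5"]],
                           missing=0.0, seed=73)
        units = [f"P1_{i}" for i in range(4)] + [f"O4_{i}" for i in range(4)]
        groups, amb = group_by_cladality(ds, units, ["C", "O1", "O2", "O3", "O5"],
                                         assign_blocks(ds.snp))
        membership = {u: i for i, g in enumerate(groups) for u in g}
        # all P1 individuals grouped together, all O4 together, never mixed
        assert len({membership[f"P1_{i}"] for i in range(4)}) == 1
        assert len({membership[f"O4_{i}"] for i in range(4)}) == 1
        assert membership["P1_0"] != membership["O4_0"]

    def test_single_individual_is_singleton(self, clade_dataset):
        ds, blocks = clade_dataset
        groups, amb = group_by_cladality(ds, ["P1_0"], RIGHT, blocks)
        assert groups == [["P1_0"]] and amb == []


class TestQpAdm:
    @pytest.fixture(scope="class")
    def fitted(self):
        ds, blocks = simulate_admixture_cohort_dataset(seed=123, n_snps=60_000)
        return fit_admixture_weights(ds, blocks)

    def test_recovers_simulated_weight(self, fitted):
        assert fitted.weights[0] == pytest.approx(0.539, abs=2.5 * fitted.weight_se[0])
        assert fitted.weights.sum() == pytest.approx(1.0)

    def test_model_not_rejected(self, fitted):
        assert fitted.p > 0.05

    def test_degenerate_single_source_target(self):
        # target generated identical to source_1: weights (1, 0)
        ds, blocks = simulate_admixture_cohort_dataset(seed=55, w=1.0,
                                                       n_snps=40_000)
        model = fit_admixture_weights(ds, blocks)
        assert model.weights[0] == pytest.approx(1.0, abs=2.5 * model.weight_se[0])

    def test_one_source_model_rejected_for_two_source_target(self):
        ds, blocks = simulate_admixture_cohort_dataset(seed=77, w=0.5,
                                                       n_snps=60_000)
        model = qpadm_fit(ds, "Target", ["Chibchan"], REFERENCES, blocks)
        assert model.p < 0.05

    def test_weights_equivariant_to_source_relabeling(self):
        ds, blocks = simulate_admixture_cohort_dataset(seed=88, n_snps=30_000)
        m1 = qpadm_fit(ds, "Target", ["Chibchan", "AmazonianNorth"], REFERENCES, blocks)
        m2 = qpadm_fit(ds, "Target", ["AmazonianNorth", "Chibchan"], REFERENCES, blocks)
        np.testing.assert_allclose(m1.weights, m2.weights[::-1], atol=1e-8)

    def test_invariant_to_reference_base_choice(self):
        ds, blocks = simulate_admixture_cohort_dataset(seed=99, n_snps=30_000)
        m1 = qpadm_fit(ds, "Target", ["Chibchan", "AmazonianNorth"], REFERENCES, blocks)
        rolled = REFERENCES[1:] + REFERENCES[:1]
        m2 = qpadm_fit(ds, "Target", ["Chibchan", "AmazonianNorth"], rolled, blocks)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=0.02)

    def test_too_few_references_rejected(self, clade_dataset):
        ds, blocks = clade_dataset
        with pytest.raises(ValueError, match="reference"):
            qpadm_fit(ds, "P1", ["P2", "O1"], ["O2", "O3"], blocks)

    def test_weight_grid_recovery(self):
        """Mean absolute error across a grid of true mixture weights is small."""
        errs = []
        for k, w in enumerate([0.1, 0.3, 0.5, 0.7, 0.9]):
            ds, blocks = simulate_admixture_cohort_dataset(
                seed=400 + k, w=w, n_snps=60_000, n_target=20)
            model = fit_admixture_weights(ds, blocks)
            errs.append(abs(model.weights[0] - w))
        assert np.mean(errs) < 0.03
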