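"""Simulate the synthetic study cohorts every later step consumes.

Writes EIGENSTRAT triplets for (a) the two-source admixture cohort built
around the fitted Cundinamarca proportion and (b) a small clade panel used
for f-statistics and grouping, plus a per-individual QC metrics table with
the published pass/fail accounting (240 sampled, 29 failing authenticity
rules, 2 date-excluded, 209 retained).
"""

from pathlib import Path

from paleostack.genio import write_eigenstrat
from paleostack.scenarios import simulate_admixture_cohort_dataset
from paleostack.simdata import simulate_qc_table

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SCRATCH.mkdir(exist_ok=True)

ds, _ = simulate_admixture_cohort_dataset(seed=1, n_snps=20_000)
write_eigenstrat(ds, SCRATCH / "admixture_cohort")
print(f"admixture cohort: {ds.n_ind} individuals x {ds.n_snp} SNPs "
      f"-> {SCRATCH / 'admixture_cohort'}.*")

fail_specs = ([("snps_covered", 5_000)] * 9 + [("damage_rate", 0.01)] * 6
              + [("contam_lower_bound", 0.05)] * 6
              + [("mt_match_upper_bound", 0.7)] * 4 + [("sex_ratio", 0.15)] * 4)
qc = simulate_qc_table(n_pass=211, fail_specs=fail_specs, seed=1)
qc.to_csv(OUT / "qc_metrics.tsv", sep="\t", index=False)
print(f"QC metrics table: {len(qc)} individuals -> {OUT / 'qc_metrics.tsv'}")
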