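"""Apply the authenticity/QC thresholds to the simulated metrics table.

Reproduces the study's accounting: of 240 sampled individuals, 29 fail
coverage/authenticity rules and 2 are excluded for radiocarbon dates
inconsistent with their archaeological context, retaining 209.
"""

from pathlib import Path

import pandas as pd

from paleostack.pullcall import apply_qc

OUT = Path(__file__).resolve().parent.parent / "results"
table = pd.read_csv(OUT / "qc_metrics.tsv", sep="\t")
ids, fails = apply_qc(table, date_excluded=["pass209", "pass210"])
fails.to_csv(OUT / "qc_failures.tsv", sep="\t", index=False)
print(f"{len(table)} individuals -> {len(ids)} pass, {len(fails)} excluded")
print(fails["reasons"].value_counts().to_string())
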