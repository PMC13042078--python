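"""f-statistics and the outgroup-f3 NJ tree on the simulated cohort.

Computes an f4 battery testing cladality patterns, then the pairwise
outgroup-f3 matrix, inverts it to distances, builds a neighbor-joining
tree rooted on the most diverged reference, and writes the Grafen-
transformed Newick.
"""

import itertools
from pathlib import Path

import pandas as pd

from paleostack.f3tree import (f3_to_distance, neighbor_joining,
                               root_and_transform, to_newick)
from paleostack.fstats import f_stat, run_battery
from paleostack.genio import assign_blocks, read_eigenstrat

OUT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
ds = read_eigenstrat(SCRATCH / "admixture_cohort")
blocks = assign_blocks(ds.snp)

battery = [("f4", ["Ref1", "Target", "Chibchan", "AmazonianNorth"]),
           ("f4", ["Ref1", "Ref2", "Chibchan", "AmazonianNorth"]),
           ("f4", ["Ref1", "Chibchan", "Target", "AmazonianNorth"])]
table = run_battery(ds, battery, blocks)
table.to_csv(OUT / "f4_battery.tsv", sep="\t", index=False)
print(table.to_string(index=False))

pops = ["Target", "Chibchan", "AmazonianNorth", "Ref3", "Ref4", "Ref5",
        "Ref6", "Ref7", "Ref8"]
rows = [(a, b, f_stat(ds, "f3", [ "Ref1", a, b], blocks).estimate)
        for a, b in itertools.combinations(pops, 2)]
f3 = pd.DataFrame(rows, columns=["pop_a", "pop_b", "f3"])
f3.to_csv(OUT / "outgroup_f3.tsv", sep="\t", index=False)

tree = neighbor_joining(f3_to_distance(f3))
rooted = root_and_transform(tree, "Ref8", grafen=True, exponent=0.5)
(OUT / "f3_nj_tree.nwk").write_text(to_newick(rooted) + "\n")
print(f"\nNJ tree (Grafen heights, exponent 0.5) -> {OUT / 'f3_nj_tree.nwk'}")
print(to_newick(rooted))
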