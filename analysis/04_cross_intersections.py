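#!/usr/bin/env python
"""Cross-level synthesis: UpSet-style intersections of significant genes,
the permutation null for the all-cross overlap, direction tallies and the
genes significant in at least four of the six crosses.

Reads the per-cross tables written by 03_gene_ase.py from results/ase/.
"""

import argparse
from pathlib import Path

from asecross.cross_compare import (CrossResultSet, consistency_table,
                                    direction_summary, intersect_ase,
                                    permute_intersection, shared_universe,
                                    upset_long_table)
from asecross.io_formats import read_results

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--ase-dir", type=Path, default=Path("results/ase"))
parser.add_argument("--n-perm", type=int, default=10_000)
parser.add_argument("--min-crosses", type=int, default=4)
parser.add_argument("--out", type=Path, default=Path("results/compare"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

sets = [CrossResultSet.from_results_table(read_results(p))
        for p in sorted(args.ase_dir.glob("ase_*.tsv"))]
print(f"loaded {len(sets)} crosses; significant per cross: "
      f"{ {rs.cross_id: len(rs.significant) for rs in sets} }")

universe = shared_universe(sets)
summary = permute_intersection(sets, universe, n_perm=args.n_perm, seed=args.seed)
upset_long_table(intersect_ase(sets)).to_csv(args.out / "intersections.tsv",
                                             sep="\t", index=False)
print(f"shared detectable universe: {len(universe)} genes")
print(f"all-cross overlap: {summary.observed_overlap} "
      f"(permutation null max {summary.null_max} over {args.n_perm} draws, "
      f"p = {summary.p_value:.2e})")

table = consistency_table(sets, args.min_crosses)
table.to_csv(args.out / "consistency.tsv", sep="\t", index=False)
print(f"genes significant in >= {args.min_crosses} crosses: {len(table)} "
      f"({int(table['any_het_significant'].sum())} with significant "
      "heterogeneity in some cross)")

directions = direction_summary(sets)
directions.to_csv(args.out / "directions.tsv", sep="\t", index=False)
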