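#!/usr/bin/env python
"""Generate the default synthetic cohort and write it as a file bundle.

Six reciprocal crosses between a susceptible-like and a resistant-like
colony (two crosses without a sequenced father), 400 genes with 20%
cis-regulated at a true major-allele fraction of 0.7, beta-binomial allelic
counts at overdispersion 0.038, planted copy-number confounders and gene
ages.  Downstream analysis steps read the bundle from results/cohort/.
"""

import argparse
from pathlib import Path

from asecross.synthetic_data import SimConfig, simulate_cohort, write_bundle

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-genes", type=int, default=400)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

config = SimConfig(seed=args.seed, n_genes=args.n_genes)
bundle = simulate_cohort(config)
write_bundle(bundle, args.out)

truth = bundle.truth.genes
print(f"wrote bundle to {args.out}")
print(f"  genes: {config.n_genes}  sites: {len(bundle.sites)}  "
      f"fixed colony differences: {len(bundle.truth.fixed_diff_sites)}")
print(f"  cis-regulated genes: {int(truth['is_ase'].sum())}  "
      f"with planted CNV: {int(truth['has_cnv'].sum())}")
for cross in bundle.crosses:
    n = len(bundle.counts[cross.cross_id])
    print(f"  {cross.cross_id}: {'phased' if cross.phased else 'unphased'}, "
          f"{n} SNP count rows, true father {cross.true_father_id}")
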