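"""Published summary inputs from the Kisumu x Nagongera cross experiment.

These are small printed tables from the study this pipeline reproduces; they
serve as inputs to the report-level arithmetic and exact tests (the raw
sequencing data are not required for those).
"""

#: Percentage of F1 RNA-seq reads mapping to the reference genome, one value
#: per cross (B1, B3, B5, K2, K4, K6).
MAPPING_RATES_PCT = (88.6, 87.1, 87.7, 85.5, 86.3, 86.9)

#: Annotated genes in the reference genome and the per-gene read count
#: recommended for 60% power to detect 1.5-fold ASE.
N_ANNOTATED_GENES = 13_796
READS_PER_GENE_FOR_POWER = 500

#: Colony-consensus SNP differences per chromosome arm (sites homozygous in
#: all sequenced individuals of each colony and differing between colonies).
COLONY_CONSENSUS_DIFFS = {"2L": 2519, "2R": 12_769, "3L": 1530, "3R": 1931,
                          "X": 10_510, "other": 0}

#: Bendiocarb bioassay mortality (%): alone, and with PBO synergist pre-exposure.
BENDIOCARB_MORTALITY_PCT = 65.9
BENDIOCARB_PBO_MORTALITY_PCT = 97.4

#: Copy-number confounder table: of 114 autosomal genes with consistent ASE,
#: 60 carried a possible CNV; of 1333 genes without ASE, 481 did.
CNV_ASE_TABLE = (60, 114 - 60, 481, 1333 - 481)

#: Selective-sweep table: 13 of 115 consistent-ASE genes lay in swept
#: regions, versus 103 of 1333 genes without ASE.
SWEEP_ASE_TABLE = (13, 115 - 13, 103, 1333 - 103)

#: Per-cross significant / detectable gene counts used for the intersection
#: permutation: six crosses, a 2934-gene shared detectable universe, and an
#: observed 13-gene all-cross intersection.
CROSS_SIGNIFICANT_COUNTS = {"B1": 327, "B3": 324, "B5": 823,
                            "K2": 255, "K4": 979, "K6": 757}
SHARED_UNIVERSE_SIZE = 2934
OBSERVED_ALL_CROSS_OVERLAP = 13
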