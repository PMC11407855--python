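"""End-to-end orchestration: from a cohort bundle directory to report tables.

All exchange between stages is via files and plain data structures; a single
global seed fans out to named substreams (ase / permute) so stages can be
rerun independently.  The run configuration and seeds are echoed into a
machine-readable manifest next to the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ase_core import NullModel, run_gene_ase
from .cross_compare import (CrossResultSet, consistency_table, intersect_ase,
                            permute_intersection, shared_universe, upset_long_table)
from .enrichment_stats import (SpeciesTree, age_assign, age_enrichment, arm_anova,
                               arm_proportions, cnv_flag, fisher_exact_2x2)
from .io_formats import (AUTOSOMES, read_copy_number, read_count_table,
                          read_gene_annotation, read_presence_absence, read_tree,
                          write_results)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    bundle_dir: str
    out_dir: str
    rho: float = 0.038
    n_sims: int = 1_000_000
    min_total: int = 10
    alpha: float = 0.05
    min_crosses: int = 4
    n_perm: int = 100_000
    seed: int = 0
    fast: bool = False  # n_sims and n_perm capped at 1e4 for desk-scale runs

    def effective_n_sims(self) -> int:
        return min(self.n_sims, 10_000) if self.fast else self.n_sims

    def effective_n_perm(self) -> int:
        return min(self.n_perm, 10_000) if self.fast else self.n_perm


def _load_bundle_tables(bundle_dir: Path):
    genes = read_gene_annotation(bundle_dir / "genes.bed")
    crosses = pd.read_csv(bundle_dir / "crosses.tsv", sep="\t")
    counts = {row.cross_id: read_count_table(bundle_dir / f"counts_{row.cross_id}.tsv")
              for row in crosses.itertuples()}
    cn = read_copy_number(bundle_dir / "copy_number.tsv")
    presence = read_presence_absence(bundle_dir / "presence_absence.tsv")
    tree = read_tree(bundle_dir / "tree.nwk")
    return genes, crosses, counts, cn, presence, tree


def validate_inputs(config: RunConfig) -> list[str]:
    """Cross-reference and coordinate checks; returns diagnostics (empty = valid)."""
    diags = []
    bundle_dir = Path(config.bundle_dir)
    try:
        genes, crosses, counts, cn, presence, tree = _load_bundle_tables(bundle_dir)
    except Exception as exc:
        return [f"bundle unreadable: {exc}"]
    gene_ids = {g.gene_id for g in genes}
    for cross_id, df in counts.items():
        unknown = set(df["gene_id"]) - gene_ids
        if unknown:
            diags.append(f"{cross_id}: count-table gene ids absent from annotation: "
                         f"{sorted(unknown)[:5]}...")
        phased = bool(crosses.set_index("cross_id").loc[cross_id, "phased"])
        if not phased and df["phase_known"].any():
            diags.append(f"{cross_id}: declared unphased but counts carry "
                         "parental-phase SNPs; will proceed unphased (warning)")
    unknown_cn = set(cn["gene_id"]) - gene_ids
    if unknown_cn:
        diags.append(f"copy-number gene ids absent from annotation: {sorted(unknown_cn)[:5]}")
    return diags


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write report tables + a run manifest.

    Stages: SNP filter -> per-cross gene ASE with FDR -> cross intersections
    and permutation test -> consistency list (>= min_crosses) -> CNV Fisher
    test -> gene-age enrichment -> chromosome-arm ANOVA.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle_dir = Path(config.bundle_dir)
    stage = "load"
    try:
        genes, crosses, counts, cn, presence, tree = _load_bundle_tables(bundle_dir)

        stage = "gene_ase"
        null = NullModel(rho=config.rho, n_sims=config.effective_n_sims(),
                         seed=config.seed)
        result_sets, tables = [], {}
        for row in crosses.itertuples():
            phased = bool(row.phased)
            res = run_gene_ase(counts[row.cross_id], null, phased,
                               min_total=config.min_total, alpha=config.alpha,
                               cross_id=row.cross_id)
            tables[row.cross_id] = res
            write_results(res, out_dir / f"ase_{row.cross_id}.tsv")
            result_sets.append(CrossResultSet.from_results_table(
                res, alpha=config.alpha, cross_id=row.cross_id, phased=phased))

        stage = "intersections"
        summary = None
        if len(result_sets) >= 2:
            universe = shared_universe(result_sets)
            summary = permute_intersection(result_sets, universe,
                                           n_perm=config.effective_n_perm(),
                                           seed=config.seed + 1)
            upset_long_table(intersect_ase(result_sets)).to_csv(
                out_dir / "intersections.tsv", sep="\t", index=False)

        stage = "consistency"
        consistent = consistency_table(result_sets, min(config.min_crosses,
                                                        len(result_sets)))
        consistent.to_csv(out_dir / "consistency.tsv", sep="\t", index=False)
        ase_genes = set(consistent["gene_id"])
        never_sig = set().union(*(rs.detectable for rs in result_sets)) - \
            set().union(*(rs.significant for rs in result_sets))

        stage = "cnv"
        arm_of = {g.gene_id: g.arm for g in genes}
        flags = cnv_flag(cn)
        auto_ase = [g for g in ase_genes if arm_of.get(g) in AUTOSOMES]
        auto_non = [g for g in never_sig if arm_of.get(g) in AUTOSOMES]
        a = sum(bool(flags.get(g, False)) for g in auto_ase)
        c = sum(bool(flags.get(g, False)) for g in auto_non)
        cnv_or, cnv_p = fisher_exact_2x2((a, len(auto_ase) - a, c, len(auto_non) - c))

        stage = "ages"
        stree = SpeciesTree(tree, focal="Agam")
        ages = age_assign(presence, stree)
        age_enr = age_enrichment(sorted(ase_genes), sorted(never_sig), ages)
        age_enr.to_csv(out_dir / "age_enrichment.tsv", sep="\t", index=False)

        stage = "arms"
        props = arm_proportions(result_sets, genes)
        props.to_csv(out_dir / "arm_proportions.tsv", sep="\t", index=False)
        anova = arm_anova(props.dropna(subset=["proportion"]))

    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {
        "n_crosses": len(result_sets),
        "significant_per_cross": {rs.cross_id: len(rs.significant)
                                  for rs in result_sets},
        "detectable_per_cross": {rs.cross_id: len(rs.detectable)
                                 for rs in result_sets},
        "consistent_ase_genes": len(ase_genes),
        "all_cross_overlap": summary.observed_overlap if summary else None,
        "permutation_p": summary.p_value if summary else None,
        "permutation_null_max": summary.null_max if summary else None,
        "cnv_odds_ratio": cnv_or,
        "cnv_fisher_p": cnv_p,
        "arm_anova_p_arm": anova.p_arm,
        "arm_anova_p_cross": anova.p_cross,
    }
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "effective_n_sims": config.effective_n_sims(),
        "effective_n_perm": config.effective_n_perm(),
        "report": report,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {"report": report, "tables": tables, "consistency": consistent,
            "intersection": summary, "ages": ages, "age_enrichment": age_enr,
            "arm_anova": anova, "cnv_table": (a, len(auto_ase) - a, c,
                                              len(auto_non) - c)}
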