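"""Confounder and enrichment analyses around the ASE gene lists.

Exact 2x2 tests for copy-number and selective-sweep enrichment, gene ages by
Wagner (minimum-change) parsimony on a presence/absence matrix over a rooted
species tree, a two-way main-effects ANOVA on per-arm ASE proportions, and
generic interval operations (overlap counts, flanking-gene assignment for
predicted cis-regulatory modules).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AUTOSOMES, GeneModel, IntervalRecord


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = (ASE, non-ASE) and columns = (feature present, absent)."""

    a: int  # ASE, feature present
    b: int  # ASE, feature absent
    c: int  # non-ASE, feature present
    d: int  # non-ASE, feature absent

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Sample odds ratio (a*d)/(b*c) and two-sided Fisher exact p-value.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    The odds ratio is reported as inf when b*c = 0 with a*d > 0.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(res.pvalue)


# ---------------------------------------------------------------------------
# Wagner-parsimony gene ages


@dataclass
class SpeciesTree:
    """A rooted species tree with the focal taxon's root-to-tip ancestor path.

    Age classes are the ordered ancestors of the focal lineage: class 0 is
    the root (oldest), the last class is the focal tip itself (youngest).
    """

    tree: "object"  # dendropy.Tree
    focal: str

    def __post_init__(self):
        self.focal_leaf = None
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is not None and leaf.taxon.label == self.focal:
                self.focal_leaf = leaf
        if self.focal_leaf is None:
            raise ValueError(f"focal taxon {self.focal!r} is not a tip of the tree")
        path = []
        node = self.focal_leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        self.focal_path = path[::-1]  # root first

    @property
    def n_age_classes(self) -> int:
        return len(self.focal_path)

    def tip_labels(self) -> list:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]


def _min_cost_tables(tree, tip_state: dict):
    """Sankoff up/down tables for a binary character; returns (up, out, min_cost).

    up[node][s] = min changes in node's subtree given node state s;
    out[node][s] = min changes outside the subtree given node state s.
    """
    INF = float("inf")
    up = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_state[node.taxon.label]
            up[node] = [0 if s == 0 else INF, 0 if s == 1 else INF]
        else:
            cost = [0.0, 0.0]
            for child in node.child_nodes():
                cu = up[child]
                for s in (0, 1):
                    cost[s] += min(cu[0] + (s != 0), cu[1] + (s != 1))
            up[node] = cost
    root = tree.seed_node
    out = {root: [0.0, 0.0]}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            oc = [INF, INF]
            for sc in (0, 1):
                best = INF
                for sv in (0, 1):
                    tot = out[node][sv] + (sv != sc)
                    for sib in children:
                        if sib is child:
                            continue
                        cu = up[sib]
                        tot += min(cu[0] + (sv != 0), cu[1] + (sv != 1))
                    best = min(best, tot)
                oc[sc] = best
            out[child] = oc
    min_cost = min(up[root][0], up[root][1])
    return up, out, min_cost


def age_assign(presence: pd.DataFrame, stree: SpeciesTree) -> pd.Series:
    """Wagner-parsimony age class per gene.

    For each gene the binary presence/absence character is reconstructed by
    minimum-change parsimony; the age is the deepest (most rootward) ancestor
    of the focal tip that carries the gene in at least one minimum-cost
    labelling (ties resolved toward the older state).  Genes absent from the
    focal taxon raise an error.  Returns class indices (0 = root/oldest).
    """
    tips = stree.tip_labels()
    missing = [t for t in tips if t not in presence.columns]
    if missing:
        raise ValueError(f"presence matrix lacks tree tips: {missing}")
    ages = {}
    for gene_id, row in presence.iterrows():
        tip_state = {t: int(row[t]) for t in tips}
        if tip_state[stree.focal] != 1:
            raise ValueError(f"gene {gene_id} absent from focal taxon {stree.focal}")
        up, out, min_cost = _min_cost_tables(stree.tree, tip_state)
        age = stree.n_age_classes - 1  # focal tip: always attainable
        for depth, node in enumerate(stree.focal_path):
            if up[node][1] + out[node][1] == min_cost:
                age = depth
                break
        ages[gene_id] = age
    return pd.Series(ages, name="age_class")


def age_enrichment(ase_genes: Sequence, non_ase_genes: Sequence, ages: pd.Series,
                   alpha: float = 0.05, strong: float = 0.001) -> pd.DataFrame:
    """Per-age-class 2x2 Fisher tests of ASE vs non-ASE gene age composition.

    Classes with zero genes in both groups are skipped.  Significance stars:
    '*' for strong < p <= alpha, '***' for p <= strong.
    """
    ase_genes = [g for g in ase_genes if g in ages.index]
    non_ase_genes = [g for g in non_ase_genes if g in ages.index]
    ase_ages = ages.loc[ase_genes]
    non_ages = ages.loc[non_ase_genes]
    rows = []
    for cls in sorted(ages.unique()):
        a = int((ase_ages == cls).sum())
        b = len(ase_ages) - a
        c = int((non_ages == cls).sum())
        d = len(non_ages) - c
        if a + c == 0:
            continue
        odds, p = fisher_exact_2x2((a, b, c, d))
        star = "***" if p <= strong else ("*" if p <= alpha else "")
        rows.append((cls, a, len(ase_ages), c, len(non_ages), odds, p, star))
    return pd.DataFrame(rows, columns=[
        "age_class", "n_ase_in_class", "n_ase", "n_non_ase_in_class",
        "n_non_ase", "odds_ratio", "p_value", "significance"])


# ---------------------------------------------------------------------------
# Chromosome-arm ANOVA


@dataclass
class ArmAnovaResult:
    f_arm: float
    p_arm: float
    f_cross: float
    p_cross: float
    ss_arm: float
    ss_cross: float
    ss_resid: float
    ss_total: float
    df_arm: int
    df_cross: int
    df_resid: int


def arm_anova(arm_table: pd.DataFrame) -> ArmAnovaResult:
    """Two-way main-effects ANOVA (no interaction) on per-(arm, cross) proportions.

    ``arm_table`` needs columns arm, cross, proportion forming a complete
    grid with one value per cell.  Sums of squares come from marginal means;
    the residual carries (A-1)(C-1) degrees of freedom.
    """
    grid = arm_table.pivot(index="arm", columns="cross", values="proportion")
    if grid.isna().any().any():
        raise ValueError("arm x cross grid has missing cells")
    y = grid.to_numpy(dtype=float)
    A, C = y.shape
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_arm = float(C * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_cross = float(A * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_resid = ss_total - ss_arm - ss_cross
    df_arm, df_cross, df_resid = A - 1, C - 1, (A - 1) * (C - 1)

    def f_and_p(ss_eff, df_eff):
        if ss_eff <= 1e-15:
            return 0.0, 1.0
        if ss_resid <= 1e-15:
            return float("inf"), 0.0
        f = (ss_eff / df_eff) / (ss_resid / df_resid)
        return float(f), float(stats.f.sf(f, df_eff, df_resid))

    f_arm, p_arm = f_and_p(ss_arm, df_arm)
    f_cross, p_cross = f_and_p(ss_cross, df_cross)
    return ArmAnovaResult(f_arm, p_arm, f_cross, p_cross, ss_arm, ss_cross,
                          ss_resid, ss_total, df_arm, df_cross, df_resid)


def arm_proportions(result_sets, genes: Sequence[GeneModel],
                    arms=AUTOSOMES) -> pd.DataFrame:
    """Per-(arm, cross) proportion of significant over detectable genes."""
    arm_of = {g.gene_id: g.arm for g in genes}
    rows = []
    for rs in result_sets:
        for arm in arms:
            det = [g for g in rs.detectable if arm_of.get(g) == arm]
            sig = [g for g in rs.significant if arm_of.get(g) == arm]
            prop = len(sig) / len(det) if det else float("nan")
            rows.append((arm, rs.cross_id, len(sig), len(det), prop))
    return pd.DataFrame(rows, columns=["arm", "cross", "n_ase", "n_detectable",
                                       "proportion"])


# ---------------------------------------------------------------------------
# Interval operations


def overlap_count(set_a: Sequence[IntervalRecord], set_b: Sequence[IntervalRecord]) -> int:
    """Number of a-intervals overlapping (>0 bp) any b-interval."""
    by_chrom: dict[str, list] = {}
    for iv in set_b:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    index = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        index[chrom] = (starts, ends)
    n = 0
    for iv in set_a:
        if iv.chrom not in index:
            continue
        starts, ends = index[iv.chrom]
        j = int(np.searchsorted(starts, iv.end, side="left"))  # b.start < a.end
        if j > 0 and ends[j - 1] > iv.start:
            n += 1
    return n


def flank_assign(intervals: Sequence[IntervalRecord],
                 genes: Sequence[GeneModel]) -> dict:
    """Map each interval to its overlapping genes plus nearest neighbours.

    Every interval gets all genes it overlaps on the same arm, plus the
    nearest non-overlapping gene on each side (gene end <= interval start on
    the left; gene start >= interval end on the right).  Returns
    {interval.label: [gene ids]} with gene order left-to-right.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.end))
    out = {}
    for iv in intervals:
        assigned: list[str] = []
        glist = by_chrom.get(iv.chrom, [])
        left_best, right_best = None, None
        for g in glist:
            if g.start < iv.end and g.end > iv.start:
                assigned.append(g.gene_id)
            elif g.end <= iv.start:
                if left_best is None or g.end > left_best.end:
                    left_best = g
            elif g.start >= iv.end:
                if right_best is None or g.start < right_best.start:
                    right_best = g
        ordered = []
        if left_best is not None:
            ordered.append(left_best.gene_id)
        ordered.extend(assigned)
        if right_best is not None:
            ordered.append(right_best.gene_id)
        out[iv.label] = ordered
    return out


def genes_in_intervals(genes: Sequence[GeneModel],
                       intervals: Sequence[IntervalRecord]) -> set:
    """Gene ids whose interval overlaps (>= 1 bp) any of the given intervals."""
    hits = set()
    for g in genes:
        gi = IntervalRecord(g.chrom, g.start, g.end, g.gene_id)
        if overlap_count([gi], list(intervals)):
            hits.add(g.gene_id)
    return hits


# ---------------------------------------------------------------------------
# Copy-number flags


def cnv_flag(copy_number_table: pd.DataFrame,
             individuals: Optional[Sequence[str]] = None) -> pd.Series:
    """Per-gene flag: any relevant individual has copy number != 2."""
    df = copy_number_table
    if individuals is not None:
        df = df[df["individual"].isin(individuals)]
    flags = df.groupby("gene_id")["copy_number"].apply(lambda s: bool((s != 2).any()))
    flags.name = "has_possible_cnv"
    return flags
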