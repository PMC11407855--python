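"""Combining gene-level ASE results across crosses.

Overlap of significant gene sets between crosses is summarised UpSet-style
(exclusive per-combination counts) and tested against a permutation null
that redraws each cross's significant genes uniformly from the shared
detectable universe, mirroring the observed draw sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CrossResultSet:
    """One cross's detectable and significant gene sets with per-gene direction."""

    cross_id: str
    detectable: frozenset
    significant: frozenset
    direction: dict = field(default_factory=dict)       # gene -> maternal|paternal|unknown
    het_significant: frozenset = frozenset()
    phased: bool = False

    def __post_init__(self):
        if not self.significant <= self.detectable:
            raise ValueError(f"{self.cross_id}: significant genes must be detectable")

    @classmethod
    def from_results_table(cls, results: pd.DataFrame, alpha: float = 0.05,
                           cross_id: Optional[str] = None, phased: Optional[bool] = None):
        if cross_id is None:
            cross_id = str(results["cross_id"].iloc[0])
        detectable = frozenset(results["gene_id"])
        sig = results[results["q_ase"] <= alpha]
        het = results[(results["q_het"].notna()) & (results["q_het"] <= alpha)]
        if phased is None:
            phased = results["maternal_fraction"].notna().any()
        return cls(cross_id, detectable, frozenset(sig["gene_id"]),
                   dict(zip(sig["gene_id"], sig["direction"])),
                   frozenset(het["gene_id"]), bool(phased))


@dataclass
class IntersectionSummary:
    observed_overlap: int
    combination_counts: dict       # frozenset of cross ids -> exclusive count
    null_overlaps: np.ndarray
    p_value: float
    null_max: int
    universe_size: int
    draw_sizes: dict
    mode: str = "universe-restricted"


def intersect_ase(result_sets: Sequence[CrossResultSet]) -> dict:
    """Exclusive per-combination overlap counts (UpSet-style) of significant sets.

    Returns {frozenset(cross ids): number of genes significant in exactly that
    combination} for every non-empty combination that contains genes, plus a
    zero entry for the all-cross combination so the full intersection is
    always reported.
    """
    if len(result_sets) < 2:
        raise ValueError("need at least two crosses to intersect")
    membership: dict[str, frozenset] = {}
    for rs in result_sets:
        for g in rs.significant:
            membership.setdefault(g, frozenset())
            membership[g] = membership[g] | {rs.cross_id}
    counts: dict[frozenset, int] = {}
    for combo in membership.values():
        counts[combo] = counts.get(combo, 0) + 1
    all_combo = frozenset(rs.cross_id for rs in result_sets)
    counts.setdefault(all_combo, 0)
    return counts


def all_cross_overlap(result_sets: Sequence[CrossResultSet]) -> int:
    """Size of the plain intersection of all significant sets."""
    return len(reduce(lambda a, b: a & b, (set(rs.significant) for rs in result_sets)))


def shared_universe(result_sets: Sequence[CrossResultSet]) -> frozenset:
    """Genes detectable in every cross."""
    return frozenset(reduce(lambda a, b: a & b,
                            (set(rs.detectable) for rs in result_sets)))


def permute_intersection(result_sets: Sequence[CrossResultSet],
                         universe: Optional[Sequence] = None,
                         n_perm: int = 100_000, seed: int = 0,
                         restrict_draws: bool = True,
                         draw_sizes: Optional[Sequence[int]] = None) -> IntersectionSummary:
    """Permutation null for the all-cross overlap of significant genes.

    Each permutation draws, per cross, a uniform subset (without replacement)
    of the universe with size equal to that cross's significant-gene count
    (restricted to the universe by default) and records the all-cross overlap.
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if universe is None:
        universe = shared_universe(result_sets)
    universe = list(universe)
    n_u = len(universe)
    uset = set(universe)
    if draw_sizes is not None:
        ks = list(draw_sizes)
        if len(ks) != len(result_sets):
            raise ValueError("draw_sizes length must match result_sets")
    elif restrict_draws:
        ks = [len(set(rs.significant) & uset) for rs in result_sets]
    else:
        ks = [len(rs.significant) for rs in result_sets]
    for k in ks:
        if k > n_u:
            raise ValueError(f"draw size {k} exceeds universe size {n_u}")

    observed = all_cross_overlap(result_sets)
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=np.int64)
    hits = np.zeros(n_u, dtype=np.int16)
    for i in range(n_perm):
        hits[:] = 0
        for k in ks:
            idx = rng.choice(n_u, size=k, replace=False, shuffle=False)
            hits[idx] += 1
        null[i] = int((hits == len(ks)).sum())
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return IntersectionSummary(
        observed_overlap=observed,
        combination_counts=intersect_ase(result_sets),
        null_overlaps=null, p_value=float(p), null_max=int(null.max()),
        universe_size=n_u,
        draw_sizes={rs.cross_id: k for rs, k in zip(result_sets, ks)},
        mode="universe-restricted" if restrict_draws else "full-set")


def consistency_table(result_sets: Sequence[CrossResultSet], k: int) -> pd.DataFrame:
    """Genes significant in >= k crosses, with direction and p_het flags.

    Columns: gene_id, n_significant, n_detectable, n_maternal, n_paternal,
    direction_agreement (all phased significant calls same direction),
    any_het_significant.
    """
    if k > len(result_sets):
        raise ValueError("k cannot exceed the number of crosses")
    genes = sorted(set().union(*(rs.significant for rs in result_sets)))
    rows = []
    for g in genes:
        n_sig = sum(g in rs.significant for rs in result_sets)
        if n_sig < k:
            continue
        n_det = sum(g in rs.detectable for rs in result_sets)
        dirs = [rs.direction.get(g) for rs in result_sets
                if rs.phased and g in rs.significant]
        dirs = [d for d in dirs if d in ("maternal", "paternal")]
        n_mat = sum(d == "maternal" for d in dirs)
        n_pat = sum(d == "paternal" for d in dirs)
        agree = len(set(dirs)) <= 1
        any_het = any(g in rs.het_significant for rs in result_sets)
        rows.append((g, n_sig, n_det, n_mat, n_pat, agree, any_het))
    return pd.DataFrame(rows, columns=[
        "gene_id", "n_significant", "n_detectable", "n_maternal", "n_paternal",
        "direction_agreement", "any_het_significant"])


def direction_summary(result_sets: Sequence[CrossResultSet]) -> pd.DataFrame:
    """Per-gene maternal/paternal tallies over phased crosses only."""
    phased = [rs for rs in result_sets if rs.phased]
    genes = sorted(set().union(*(rs.significant for rs in phased)) if phased else set())
    rows = []
    for g in genes:
        n_mat = sum(rs.direction.get(g) == "maternal" for rs in phased)
        n_pat = sum(rs.direction.get(g) == "paternal" for rs in phased)
        rows.append((g, n_mat, n_pat))
    return pd.DataFrame(rows, columns=["gene_id", "n_maternal", "n_paternal"])


def upset_long_table(counts: dict) -> pd.DataFrame:
    """Exclusive combination counts as a long-format table for plotting."""
    rows = [("+".join(sorted(combo)), len(combo), n)
            for combo, n in sorted(counts.items(), key=lambda kv: (-kv[1], len(kv[0])))]
    return pd.DataFrame(rows, columns=["combination", "degree", "n_genes"])
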