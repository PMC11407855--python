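"""Parentage assignment, sibling SNP inference and small QC summaries.

F1 crosses between two partially inbred colonies are checked by Mendelian
error analysis: the true father among candidates is the one minimising the
median per-progeny Mendelian error rate.  Sites where the parents are
homozygous for different alleles (so every F1 is heterozygous) are the
informative sites for allele-specific expression; when parents are
unavailable they are inferred from male sibling genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import ARMS, AUTOSOMES, VariantRecord

logger = logging.getLogger(__name__)

CONSISTENT = "consistent"
ERROR = "error"
UNINFORMATIVE = "uninformative"

MISSING = -1  # dosage code for a missing diploid call


@dataclass
class GenotypeMatrix:
    """Diploid calls for individuals x biallelic sites.

    ``dosages`` holds alt-allele dosages (0, 1, 2) with -1 for missing, shape
    (n_individuals, n_sites).  ``sites`` are (chrom, pos, ref, alt) tuples in
    site order.
    """

    individuals: list
    sites: list
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("dosage matrix shape inconsistent with individuals x sites")
        ok = np.isin(self.dosages, [MISSING, 0, 1, 2])
        if not ok.all():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def row(self, individual) -> np.ndarray:
        return self.dosages[self.individuals.index(individual)]

    def chroms(self) -> np.ndarray:
        return np.array([s[0] for s in self.sites])

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        sites = [s for s, m in zip(self.sites, mask) if m]
        return GenotypeMatrix(list(self.individuals), sites, self.dosages[:, mask])

    @classmethod
    def from_records(cls, records: Sequence[VariantRecord], individuals=None) -> "GenotypeMatrix":
        if individuals is None:
            individuals = list(records[0].genotypes) if records else []
        dos = np.full((len(individuals), len(records)), MISSING, dtype=np.int8)
        sites = []
        for j, r in enumerate(records):
            sites.append((r.chrom, r.pos, r.ref, r.alt))
            for i, ind in enumerate(individuals):
                gt = r.genotypes.get(ind)
                if gt is not None:
                    dos[i, j] = gt[0] + gt[1]
        return cls(list(individuals), sites, dos)

    def to_records(self) -> list[VariantRecord]:
        recs = []
        _pair = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        for j, (chrom, pos, ref, alt) in enumerate(self.sites):
            gts = {}
            for i, ind in enumerate(self.individuals):
                d = int(self.dosages[i, j])
                gts[ind] = None if d == MISSING else _pair[d]
            recs.append(VariantRecord(chrom, pos, ref, alt, gts))
        return recs


@dataclass
class MendelianErrorSummary:
    candidate_father: str
    per_progeny_rate: dict
    median_rate: float
    n_informative: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mendelian logic

_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}


def mendelian_error_rate(mother_call: int, father_call: int, child_call: int) -> str:
    """Classify one genotype trio (alt dosages; -1 = missing).

    A trio is an ``error`` iff no gamete pair (one allele from each parent)
    can produce the child genotype; any missing call is ``uninformative``.
    """
    if MISSING in (mother_call, father_call, child_call):
        return UNINFORMATIVE
    for a in _ALLELES[mother_call]:
        for b in _ALLELES[father_call]:
            if a + b == child_call:
                return CONSISTENT
    return ERROR


def _trio_error_mask(mother: np.ndarray, father: np.ndarray, child: np.ndarray):
    """Vectorised trio classification; returns (error_mask, informative_mask)."""
    informative = (mother != MISSING) & (father != MISSING) & (child != MISSING)
    # child dosage attainable iff min-gamete-sum <= child <= max-gamete-sum,
    # with het parents contributing either allele.
    lo = (mother == 2).astype(int) + (father == 2).astype(int)
    hi = 2 - (mother == 0).astype(int) - (father == 0).astype(int)
    error = informative & ((child < lo) | (child > hi))
    return error, informative


def trio_error_summary(mother: np.ndarray, father: np.ndarray, progeny: np.ndarray,
                       progeny_ids: Sequence[str]) -> tuple[dict, dict]:
    """Per-progeny Mendelian error rates for one candidate father."""
    rates, n_inf = {}, {}
    for pid, child in zip(progeny_ids, progeny):
        err, inf = _trio_error_mask(mother, father, child)
        n = int(inf.sum())
        n_inf[pid] = n
        rates[pid] = float(err.sum() / n) if n else float("nan")
    return rates, n_inf


def match_father(mother_gt: np.ndarray, candidates: dict, progeny_gt: "GenotypeMatrix",
                 max_error: float = 0.05) -> tuple[Optional[str], list[MendelianErrorSummary]]:
    """Assign the father minimising median per-progeny Mendelian error.

    Parameters
    ----------
    mother_gt : dosage vector of the mother.
    candidates : mapping candidate id -> dosage vector.
    progeny_gt : GenotypeMatrix of the progeny.
    max_error : no-match threshold on the minimal median error rate.

    Returns (assigned father id or None, summaries sorted by median error).
    """
    if not candidates:
        raise ValueError("at least one candidate father required")
    if not progeny_gt.individuals:
        raise ValueError("at least one progeny individual required")
    summaries = []
    for cid, father in candidates.items():
        rates, n_inf = trio_error_summary(mother_gt, father, progeny_gt.dosages,
                                          progeny_gt.individuals)
        finite = [r for r in rates.values() if np.isfinite(r)]
        if not finite:
            logger.warning("candidate %s has zero informative sites; excluded", cid)
            continue
        summaries.append(MendelianErrorSummary(cid, rates, float(np.median(finite)), n_inf))
    if not summaries:
        raise ValueError("no candidate father had informative sites")
    summaries.sort(key=lambda s: s.median_rate)
    best = summaries[0]
    if best.median_rate > max_error:
        return None, summaries
    return best.candidate_father, summaries


# ---------------------------------------------------------------------------
# Sibling-based informative-site inference


def infer_sibling_snps(sib_matrix: GenotypeMatrix, max_missing: float = 0.5,
                       min_calls: int = 2, autosomes=AUTOSOMES) -> np.ndarray:
    """Sites consistent with parents homozygous for different alleles.

    Returns a boolean mask over ``sib_matrix.sites`` selecting autosomal sites
    at which every non-missing sibling is heterozygous, with at least
    ``min_calls`` non-missing calls and a missing fraction <= ``max_missing``.
    These sites are phase-unknown: the maternal/paternal assignment of the two
    alleles is not recoverable from siblings alone.
    """
    if len(sib_matrix.individuals) < 2:
        raise ValueError("sibling inference requires >= 2 siblings")
    dos = sib_matrix.dosages
    n_sibs = dos.shape[0]
    observed = dos != MISSING
    n_obs = observed.sum(axis=0)
    all_het = ((dos == 1) | ~observed).all(axis=0)
    autosomal = np.isin(sib_matrix.chroms(), autosomes)
    mask = (autosomal & all_het & (n_obs >= min_calls)
            & ((n_sibs - n_obs) / n_sibs <= max_missing))
    return mask


# ---------------------------------------------------------------------------
# Colony consensus differences


def consensus_diff_counts(colony_a: GenotypeMatrix, colony_b: GenotypeMatrix,
                          arms=ARMS) -> dict:
    """Per-arm counts of sites fixed for different alleles between colonies.

    A site counts when every observed call within each colony is homozygous
    for one allele (colony consensus) and the two colony consensus alleles
    differ.  Missing calls are ignored; a site with no observed calls in a
    colony does not count.  Returns {arm: count, ..., 'total': n}.
    """
    if colony_a.sites != colony_b.sites:
        raise ValueError("colonies must share the same site universe")

    def fixed_allele(dos):
        observed = dos != MISSING
        any_obs = observed.any(axis=0)
        all_ref = ((dos == 0) | ~observed).all(axis=0) & any_obs
        all_alt = ((dos == 2) | ~observed).all(axis=0) & any_obs
        allele = np.full(dos.shape[1], MISSING, dtype=np.int8)
        allele[all_ref] = 0
        allele[all_alt] = 1
        return allele

    fa = fixed_allele(colony_a.dosages)
    fb = fixed_allele(colony_b.dosages)
    diff = (fa != MISSING) & (fb != MISSING) & (fa != fb)
    chroms = colony_a.chroms()
    counts = {arm: int((diff & (chroms == arm)).sum()) for arm in arms}
    counts["other"] = int(diff.sum() - sum(counts.values()))
    counts["total"] = int(diff.sum())
    return counts


# ---------------------------------------------------------------------------
# Swap diagnostic and report arithmetic


def mismatch_diagnostic(count_table, min_total: int = 10) -> tuple[float, float]:
    """Mean |per-SNP allele fraction - 0.5| and mean fraction.

    Inflated mean deviation from 0.5 indicates SNPs from non-matching parents
    (the F1 pool is then homozygous at many queried sites, pushing fractions
    to 0 or 1); matched parental SNP sets keep the mean imbalance near 0.5.
    """
    totals = count_table["count_a"] + count_table["count_b"]
    keep = totals >= min_total
    if not keep.any():
        raise ValueError("no SNPs pass the minimum-total filter")
    frac = count_table.loc[keep, "count_a"] / totals[keep]
    return float(np.abs(frac - 0.5).mean()), float(frac.mean())


def summarize_mapping(rates: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1) of mapping rates."""
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValueError("sample standard deviation requires >= 2 values")
    return float(rates.mean()), float(rates.std(ddof=1))


def reads_for_power(n_genes: int, reads_per_gene: int) -> int:
    """Total reads needed at a per-gene read recommendation (simple product)."""
    if n_genes < 0 or reads_per_gene < 0:
        raise ValueError("inputs must be non-negative")
    return int(n_genes) * int(reads_per_gene)


def percent_relative_increase(baseline: float, new: float) -> float:
    """100 x (new - baseline) / baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (new - baseline) / baseline
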