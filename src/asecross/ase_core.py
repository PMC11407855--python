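"""Gene-level allele-specific expression testing.

SNP-level allelic counts are aggregated per gene by pseudo-phasing: at each
SNP the allele with the higher read count joins the putative major haplotype,
and the gene's major allele frequency (MAF) is the summed major count over
the summed total.  Significance comes from a Monte-Carlo null: holding each
SNP's total fixed, one allele's count is drawn from a beta-binomial with mean
0.5 x total and intraclass-correlation overdispersion rho (default 0.038),
the same aggregation is applied to every simulated replicate, and the p-value
is the proportion of replicates whose simulated MAF is >= the observed MAF.

For genes with several SNPs a heterogeneity statistic

    Q = sum_i total_i * (f_i - fbar)^2

(with f_i the per-SNP major-haplotype fraction and fbar the count-weighted
mean) is compared against the same null replicates; a low p_het suggests
inconsistent per-SNP imbalance (possible isoform-specific ASE).

Benjamini-Hochberg correction at a nominal 5% FDR is applied across genes to
both p-values.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

DEFAULT_RHO = 0.038
DEFAULT_N_SIMS = 1_000_000
DEFAULT_MIN_TOTAL = 10

#: replicate batch size cap (replicates x SNPs elements per batch)
_BATCH_ELEMENTS = 4_000_000


@dataclass(frozen=True)
class SnpAllelicCount:
    """Allelic read counts at one exonic SNP of one gene.

    ``count_m`` is the maternal-allele count when ``phase_known``, otherwise
    an arbitrary consistent allele (reference-like).
    """

    gene_id: str
    chrom: str
    pos: int
    count_m: int
    count_p: int
    phase_known: bool = False

    @property
    def total(self) -> int:
        return self.count_m + self.count_p


@dataclass(frozen=True)
class NullModel:
    """Beta-binomial simulation null (mean 0.5 x total, overdispersion rho)."""

    rho: float = DEFAULT_RHO
    n_sims: int = DEFAULT_N_SIMS
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")
        if self.n_sims < 100:
            logger.warning("n_sims=%d gives very coarse p-values", self.n_sims)


@dataclass
class OverdispersionFit:
    rho_hat: float
    loglik_betabinom: float
    loglik_binom: float
    lrt_statistic: float
    lrt_p: float


@dataclass
class GeneASEResult:
    gene_id: str
    n_snps: int
    maf: float
    maternal_fraction: Optional[float]
    p_ase: float
    p_het: Optional[float]
    direction: str  # maternal | paternal | unknown
    q_ase: Optional[float] = None
    q_het: Optional[float] = None


# ---------------------------------------------------------------------------
# Primitives


def filter_snps(counts: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL) -> pd.DataFrame:
    """Retain SNPs with count_a + count_b >= min_total (removals logged)."""
    totals = counts["count_a"] + counts["count_b"]
    kept = counts[totals >= min_total].copy()
    removed = len(counts) - len(kept)
    if removed:
        logger.info("filter_snps: removed %d/%d SNPs below %d total counts",
                    removed, len(counts), min_total)
    return kept


def betabinom_shapes(mu: float, rho: float) -> tuple[float, float]:
    """Map (mean, intraclass correlation) to beta-binomial shape parameters."""
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must be in (0, 1), got {mu}")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if rho == 0.0:
        return np.inf, np.inf
    nu = 1.0 / rho - 1.0
    return mu * nu, (1.0 - mu) * nu


def betabinom_pmf(k, n, mu: float, rho: float):
    """Beta-binomial mass; reduces to binomial(n, mu) as rho -> 0."""
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("k must satisfy 0 <= k <= n")
    if rho == 0.0:
        return stats.binom.pmf(k, n, mu)
    a, b = betabinom_shapes(mu, rho)
    return stats.betabinom.pmf(k, n, a, b)


def pseudo_phase(count_a: np.ndarray, count_b: np.ndarray):
    """Assign the higher-count allele at each SNP to the major haplotype.

    Returns (major_counts, minor_counts, maf); ties (count_a == count_b)
    contribute 0.5 at that SNP.
    """
    count_a = np.asarray(count_a)
    count_b = np.asarray(count_b)
    if count_a.size == 0:
        raise ValueError("pseudo_phase requires at least one SNP")
    totals = count_a + count_b
    if (totals == 0).any():
        raise ValueError("zero-total SNPs must be filtered before pseudo-phasing")
    major = np.maximum(count_a, count_b)
    minor = np.minimum(count_a, count_b)
    maf = float(major.sum() / totals.sum())
    return major, minor, maf


# ---------------------------------------------------------------------------
# Overdispersion estimation


def estimate_overdispersion(count_a, count_b) -> OverdispersionFit:
    """Maximum-likelihood intraclass-correlation rho with mean fixed at 0.5.

    Fits a beta-binomial to per-SNP allelic counts by bounded 1-D likelihood
    maximisation and reports a likelihood-ratio test against the nested
    binomial, with the p-value from the 0.5*chi2_0 + 0.5*chi2_1 boundary
    mixture (rho = 0 lies on the parameter-space boundary).
    """
    k = np.asarray(count_a, dtype=int)
    n = k + np.asarray(count_b, dtype=int)
    if k.size < 2:
        raise ValueError("overdispersion estimation needs several SNPs")

    ll_binom = float(stats.binom.logpmf(k, n, 0.5).sum())

    def negll(rho):
        a, b = betabinom_shapes(0.5, rho)
        return -float(stats.betabinom.logpmf(k, n, a, b).sum())

    res = optimize.minimize_scalar(negll, bounds=(1e-8, 0.95), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"overdispersion optimiser failed: {res.message}")
    ll_bb = -float(res.fun)
    rho_hat = float(res.x)
    if ll_bb < ll_binom:  # boundary case: binomial is the MLE
        ll_bb, rho_hat = ll_binom, 0.0
    lrt = max(0.0, 2.0 * (ll_bb - ll_binom))
    p = 1.0 if lrt == 0.0 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    return OverdispersionFit(rho_hat, ll_bb, ll_binom, lrt, p)


# ---------------------------------------------------------------------------
# Simulation null


def _gene_rng(null_model: NullModel, gene_id: str) -> np.random.Generator:
    # deterministic per-gene substream so results are order-independent
    sub = zlib.crc32(str(gene_id).encode())
    return np.random.default_rng(np.random.SeedSequence([null_model.seed, sub]))


def _simulate_null(totals: np.ndarray, null_model: NullModel, phased: bool,
                   rng: np.random.Generator, n_sims: Optional[int] = None):
    """Null replicates of (major-allele numerator, heterogeneity Q).

    Holds each SNP's total fixed; draws one allele's count from
    beta-binomial(total, mu=0.5, rho).  Returns (maf_numerators, q) where the
    numerator is the integer summed major count (denominator sum(totals)),
    enabling exact tie handling in the p-value comparison.
    """
    n_sims = null_model.n_sims if n_sims is None else n_sims
    totals = np.asarray(totals, dtype=np.int64)
    S = totals.size
    grand = totals.sum()
    num = np.empty(n_sims, dtype=np.int64)
    q = np.empty(n_sims, dtype=float)
    batch = max(1, _BATCH_ELEMENTS // max(S, 1))
    a, b = (None, None)
    if null_model.rho > 0:
        a, b = betabinom_shapes(0.5, null_model.rho)
    done = 0
    while done < n_sims:
        m = min(batch, n_sims - done)
        if null_model.rho > 0:
            p = rng.beta(a, b, size=(m, S))
            k = rng.binomial(totals, p)
        else:
            k = rng.binomial(totals, 0.5, size=(m, S))
        if phased:
            mat = k.sum(axis=1)
            num[done:done + m] = np.maximum(mat, grand - mat)
            f = k / totals
            fbar = mat / grand
        else:
            major = np.maximum(k, totals - k)
            msum = major.sum(axis=1)
            num[done:done + m] = msum
            f = major / totals
            fbar = msum / grand
        q[done:done + m] = (totals * (f - fbar[:, None]) ** 2).sum(axis=1)
        done += m
    return num, q


def _observed_stats(count_m: np.ndarray, count_p: np.ndarray, phased: bool):
    totals = count_m + count_p
    grand = totals.sum()
    if phased:
        mat = count_m.sum()
        num = max(mat, grand - mat)
        f = count_m / totals
        fbar = mat / grand
    else:
        major = np.maximum(count_m, count_p)
        num = major.sum()
        f = major / totals
        fbar = num / grand
    q = float((totals * (f - fbar) ** 2).sum())
    return int(num), int(grand), q


def gene_ase_test(gene_counts: pd.DataFrame, null_model: NullModel,
                  phased: bool, add_one: bool = False,
                  gene_id: Optional[str] = None) -> GeneASEResult:
    """Monte-Carlo gene-level ASE test for one gene's filtered SNP counts.

    ``gene_counts`` needs columns count_a/count_b (count_a = maternal when
    phased).  p_ase is the proportion of null replicates whose simulated MAF
    is >= the observed MAF (the raw proportion by default; ``add_one``
    switches to the (k+1)/(n+1) estimator).  p_het (>= 2 SNPs) compares the
    heterogeneity Q against the same replicates.
    """
    if gene_id is None:
        gene_id = str(gene_counts["gene_id"].iloc[0]) if "gene_id" in gene_counts else "?"
    count_m = gene_counts["count_a"].to_numpy(dtype=np.int64)
    count_p = gene_counts["count_b"].to_numpy(dtype=np.int64)
    if count_m.size == 0:
        raise ValueError(f"gene {gene_id}: no SNPs to test")
    totals = count_m + count_p
    if (totals == 0).any():
        raise ValueError(f"gene {gene_id}: zero-total SNPs must be filtered out")

    num_obs, grand, q_obs = _observed_stats(count_m, count_p, phased)
    maf = num_obs / grand
    rng = _gene_rng(null_model, gene_id)
    num_sim, q_sim = _simulate_null(totals, null_model, phased, rng)

    n_ge = int((num_sim >= num_obs).sum())
    if add_one:
        p_ase = (n_ge + 1) / (null_model.n_sims + 1)
    else:
        p_ase = n_ge / null_model.n_sims

    p_het = None
    if count_m.size >= 2:
        n_ge_q = int((q_sim >= q_obs - 1e-12).sum())
        p_het = ((n_ge_q + 1) / (null_model.n_sims + 1)) if add_one \
            else n_ge_q / null_model.n_sims

    if phased:
        mat_frac = float(count_m.sum() / grand)
        if mat_frac > 0.5:
            direction = "maternal"
        elif mat_frac < 0.5:
            direction = "paternal"
        else:
            direction = "unknown"
    else:
        mat_frac = None
        direction = "unknown"
    return GeneASEResult(gene_id, int(count_m.size), float(maf), mat_frac,
                         float(p_ase), p_het, direction)


def heterogeneity_test(gene_counts: pd.DataFrame, null_model: NullModel,
                       phased: bool = False) -> float:
    """p_het for a multi-SNP gene (see ``gene_ase_test``)."""
    if len(gene_counts) < 2:
        raise ValueError("heterogeneity test requires >= 2 SNPs")
    return gene_ase_test(gene_counts, null_model, phased).p_het


# ---------------------------------------------------------------------------
# FDR and the per-cross table


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def run_gene_ase(counts: pd.DataFrame, null_model: NullModel, phased: bool,
                 min_total: int = DEFAULT_MIN_TOTAL, alpha: float = 0.05,
                 cross_id: str = "") -> pd.DataFrame:
    """Filter, test every gene of one cross, and apply FDR correction.

    Returns the gene-level results table (one row per gene) with q_ase/q_het
    from Benjamini-Hochberg at ``alpha`` across genes of this cross.
    """
    kept = filter_snps(counts, min_total)
    results: list[GeneASEResult] = []
    for gene_id, sub in kept.groupby("gene_id", sort=True):
        results.append(gene_ase_test(sub, null_model, phased, gene_id=str(gene_id)))
    if not results:
        return pd.DataFrame(columns=["cross_id", "gene_id", "n_snps", "maf",
                                     "maternal_fraction", "p_ase", "p_het",
                                     "q_ase", "q_het", "direction"])
    q_ase, _ = bh_fdr([r.p_ase for r in results], alpha)
    het = [r for r in results if r.p_het is not None]
    if het:
        q_het, _ = bh_fdr([r.p_het for r in het], alpha)
        for r, q in zip(het, q_het):
            r.q_het = float(q)
    for r, q in zip(results, q_ase):
        r.q_ase = float(q)
    return pd.DataFrame({
        "cross_id": cross_id,
        "gene_id": [r.gene_id for r in results],
        "n_snps": [r.n_snps for r in results],
        "maf": [r.maf for r in results],
        "maternal_fraction": [r.maternal_fraction for r in results],
        "p_ase": [r.p_ase for r in results],
        "p_het": [r.p_het for r in results],
        "q_ase": [r.q_ase for r in results],
        "q_het": [r.q_het for r in results],
        "direction": [r.direction for r in results],
    })
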