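"""Synthetic F1 crosses between two partially inbred mosquito colonies.

The generator emulates the statistical structure of a reciprocal-cross ASE
experiment: two colonies fixed for different alleles at a configurable
density of sites (plus residual within-colony heterozygosity, denser in the
resistant-like colony), Mendelian F1 inheritance, pooled-female RNA allelic
counts with beta-binomial noise, a planted fraction of cis-regulated genes
whose high allele is a colony allele, copy-number confounders realised as
copy-weighted allele fractions in the pool, and per-gene phylostratigraphic
age classes on a small species tree.  Every quantity downstream stages
estimate is recorded as ground truth, so parameter recovery is testable
without any sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (ARMS, GeneModel, write_copy_number,
                         write_count_table, write_gene_annotation,
                         write_presence_absence, write_vcf_subset)
from .parentage_qc import MISSING, GenotypeMatrix

#: Species tree for gene ages: a ladder with the focal taxon innermost.
#: Focal-lineage ancestors root->tip define age classes 0 (oldest) .. 5 (youngest).
TREE_TIPS = ["Dmel", "Aste", "Afun", "Aara", "Acol", "Agam"]
FOCAL_TAXON = "Agam"
TREE_NEWICK = "(Dmel,(Aste,(Afun,(Aara,(Acol,Agam)))));"
N_AGE_CLASSES = 6
#: Stationary age-class mix (oldest first): most genes are ancient, a tail is lineage-specific.
AGE_CLASS_PROBS = (0.45, 0.10, 0.10, 0.10, 0.10, 0.15)

COLONY_SUS = "sus"  # susceptible-like, more inbred
COLONY_RES = "res"  # resistant-like


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort (all rates are per-unit probabilities)."""

    seed: int = 0
    n_genes: int = 1000
    mean_snps_per_gene: float = 8.0   # Poisson candidate exonic SNP sites per gene
    mean_coverage: float = 100.0      # Poisson per-SNP total read count
    rho_true: float = 0.038           # beta-binomial intraclass correlation
    frac_ase: float = 0.2             # fraction of genes cis-regulated
    ase_maf: float = 0.7              # true major-allele fraction of ASE genes
    ase_maf_jitter: float = 0.0       # uniform half-width around ase_maf
    n_sibs: int = 6                   # genotyped male siblings per cross
    n_crosses: int = 6
    n_unphased: int = 2               # crosses without a sequenced father
    n_candidate_fathers: int = 6      # sequenced candidates per colony
    n_pool_females: int = 10          # F1 females pooled for RNA
    colony_div: float = 0.3           # P(site is a fixed colony difference)
    het_rate_sus: float = 0.25        # residual polymorphism, susceptible colony
    het_rate_res: float = 0.45        # residual polymorphism, resistant colony
    frac_cnv: float = 0.1             # fraction of genes with a planted duplication
    missing_rate: float = 0.01        # per-call genotype missingness
    ase_young_bias: float = 1.0       # ASE-probability multiplier for youngest-class genes

    def __post_init__(self):
        for name in ("frac_ase", "colony_div", "het_rate_sus", "het_rate_res",
                     "frac_cnv", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.rho_true < 1.0:
            raise ValueError("rho_true must be in [0, 1)")
        if not 0.5 < self.ase_maf <= 1.0:
            raise ValueError("ase_maf must be in (0.5, 1]")
        if self.n_genes < 1 or self.n_crosses < 1 or self.n_sibs < 1:
            raise ValueError("degenerate configuration: zero-sized cohort")
        if self.n_unphased > self.n_crosses:
            raise ValueError("n_unphased cannot exceed n_crosses")


@dataclass(frozen=True)
class CrossSpec:
    cross_id: str
    mother_id: str
    mother_colony: str
    father_colony: str
    true_father_id: str
    phased: bool  # father sequenced and among candidates


@dataclass
class SimTruth:
    """Planted ground truth for parameter-recovery tests."""

    genes: pd.DataFrame  # index gene_id: is_ase, true_maf, high_colony, has_cnv, cnv_colony, age_class, arm
    true_father: dict    # cross_id -> father id
    fixed_diff_sites: list  # (chrom, pos) of planted fixed colony differences

    def direction_in(self, gene_id: str, cross: CrossSpec) -> str:
        """Planted ASE direction (maternal/paternal) for a gene in a cross."""
        row = self.genes.loc[gene_id]
        if not row["is_ase"]:
            return "none"
        return "maternal" if row["high_colony"] == cross.mother_colony else "paternal"


@dataclass
class CohortBundle:
    config: SimConfig
    genes: list
    sites: list            # (chrom, pos, ref, alt)
    site_gene: np.ndarray  # gene index per site
    parents: GenotypeMatrix
    colony_of: dict
    candidate_fathers: dict  # colony -> [ids]
    crosses: list
    sib_matrices: dict       # cross_id -> GenotypeMatrix
    counts: dict             # cross_id -> count table DataFrame
    copy_number: pd.DataFrame
    presence: pd.DataFrame
    tree_newick: str = TREE_NEWICK
    truth: SimTruth = None
    pools: dict = field(default_factory=dict)  # cross_id -> (mat_hap, pat_hap) allele arrays


# ---------------------------------------------------------------------------
# Genome layout


def _gene_layout(config: SimConfig, rng: np.random.Generator):
    """Genes on arms (blocks), candidate SNP positions inside each gene."""
    genes: list[GeneModel] = []
    site_chrom, site_pos, site_gene = [], [], []
    cursor = {arm: 0 for arm in ARMS}
    gene_len, gap = 2000, 1000
    n_digits = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        arm = ARMS[(5 * i) // config.n_genes]
        start = cursor[arm]
        end = start + gene_len
        cursor[arm] = end + gap
        gid = f"g{i:0{n_digits}d}"
        genes.append(GeneModel(gid, arm, start, end, arm))
        k = rng.poisson(config.mean_snps_per_gene)
        if k > 0:
            pos = np.sort(rng.choice(np.arange(start + 1, end + 1), size=min(k, gene_len),
                                     replace=False))
            site_chrom.extend([arm] * len(pos))
            site_pos.extend(int(p) for p in pos)
            site_gene.extend([i] * len(pos))
    sites = [(c, p, "A", "T") for c, p in zip(site_chrom, site_pos)]
    return genes, sites, np.asarray(site_gene, dtype=int)


# ---------------------------------------------------------------------------
# Parents


def simulate_parents(config: SimConfig, rng: Optional[np.random.Generator] = None,
                     sites=None):
    """Two colonies of diploid parents over a shared site universe.

    A fraction ``colony_div`` of sites is fixed for different alleles between
    the colonies (susceptible colony ref, resistant colony alt); remaining
    sites may segregate within either colony (denser in the resistant one),
    in which case one individual is guaranteed heterozygous, so a segregating
    site can never masquerade as a fixed colony difference.

    Returns (GenotypeMatrix, colony_of, fixed_diff_mask, crosses, candidate_fathers).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if sites is None:
        _, sites, _ = _gene_layout(config, rng)
    S = len(sites)

    # cross roster: B-type (resistant mother) then K-type (susceptible mother)
    n_b = (config.n_crosses + 1) // 2
    crosses: list[CrossSpec] = []
    individuals, colony_of = [], {}
    candidate_fathers = {COLONY_SUS: [], COLONY_RES: []}
    for colony in (COLONY_SUS, COLONY_RES):
        for j in range(config.n_candidate_fathers):
            fid = f"{colony}_cand{j}"
            candidate_fathers[colony].append(fid)
            individuals.append(fid)
            colony_of[fid] = colony
    for i in range(config.n_crosses):
        btype = i < n_b
        cross_id = f"{'B' if btype else 'K'}{i + 1}"
        m_colony = COLONY_RES if btype else COLONY_SUS
        f_colony = COLONY_SUS if btype else COLONY_RES
        mother = f"mother_{cross_id}"
        individuals.append(mother)
        colony_of[mother] = m_colony
        phased = i >= config.n_unphased
        if phased:
            father = candidate_fathers[f_colony][
                int(rng.integers(len(candidate_fathers[f_colony])))]
        else:
            father = f"father_{cross_id}_unsampled"
            individuals.append(father)
            colony_of[father] = f_colony
        crosses.append(CrossSpec(cross_id, mother, m_colony, f_colony, father, phased))

    fixed_diff = rng.random(S) < config.colony_div
    het_rate = {COLONY_SUS: config.het_rate_sus, COLONY_RES: config.het_rate_res}
    seg = {c: ~fixed_diff & (rng.random(S) < het_rate[c]) for c in (COLONY_SUS, COLONY_RES)}
    seg_freq = {c: rng.uniform(0.1, 0.7, size=S) for c in (COLONY_SUS, COLONY_RES)}

    dosages = np.zeros((len(individuals), S), dtype=np.int8)
    for colony in (COLONY_SUS, COLONY_RES):
        rows = [i for i, ind in enumerate(individuals) if colony_of[ind] == colony]
        freq = np.zeros(S)
        if colony == COLONY_RES:
            freq[fixed_diff] = 1.0
        freq[seg[colony]] = seg_freq[colony][seg[colony]]
        block = rng.binomial(2, freq, size=(len(rows), S)).astype(np.int8)
        # guarantee one het carrier at every segregating site
        seg_idx = np.flatnonzero(seg[colony])
        if seg_idx.size:
            forced = rng.integers(len(rows), size=seg_idx.size)
            block[forced, seg_idx] = 1
        dosages[rows] = block

    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING
    matrix = GenotypeMatrix(individuals, list(sites), dosages)
    return matrix, colony_of, fixed_diff, crosses, candidate_fathers


# ---------------------------------------------------------------------------
# F1 genotypes


def _gametes(parent: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per site for n offspring (missing parent -> -1)."""
    parent = np.asarray(parent)
    g = np.where(parent == 2, 1, 0).astype(np.int8)
    het = parent == 1
    out = np.tile(g, (n, 1))
    if het.any():
        out[:, het] = rng.integers(0, 2, size=(n, int(het.sum())), dtype=np.int8)
    out[:, parent == MISSING] = MISSING
    return out


def simulate_f1(mother_gt: np.ndarray, father_gt: np.ndarray, n_sibs: int,
                seed=None, rng: Optional[np.random.Generator] = None,
                male_x_mask: Optional[np.ndarray] = None,
                ids: Optional[list] = None, sites=None) -> GenotypeMatrix:
    """Mendelian F1 genotypes: one allele per parent, independent across sites.

    ``male_x_mask`` marks hemizygous sites for male offspring: there the
    paternal gamete is replaced by a second copy of the maternal allele
    (recorded as a homozygous diploid call).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mat = _gametes(mother_gt, n_sibs, rng)
    pat = _gametes(father_gt, n_sibs, rng)
    if male_x_mask is not None:
        pat[:, male_x_mask] = mat[:, male_x_mask]
    dos = (mat + pat).astype(np.int8)
    dos[(mat == MISSING) | (pat == MISSING)] = MISSING
    if ids is None:
        ids = [f"sib{i}" for i in range(n_sibs)]
    if sites is None:
        sites = [("NA", j + 1, "A", "T") for j in range(mat.shape[1])]
    return GenotypeMatrix(ids, list(sites), dos)


# ---------------------------------------------------------------------------
# Allelic counts


def simulate_allelic_counts(totals: np.ndarray, mu: np.ndarray, rho: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw count_a ~ beta-binomial(total, mean mu, overdispersion rho) per SNP."""
    totals = np.asarray(totals, dtype=np.int64)
    mu = np.asarray(mu, dtype=float)
    interior = (mu > 0) & (mu < 1)
    if rho > 0:
        nu = 1.0 / rho - 1.0
        p = rng.beta(np.clip(mu, 1e-12, None) * nu,
                     np.clip(1.0 - mu, 1e-12, None) * nu)
    else:
        p = mu.copy()
    p = np.where(interior, p, mu)  # mu in {0,1}: deterministic
    k = rng.binomial(totals, p)
    return k


def _pool_haplotypes(cross: CrossSpec, parents: GenotypeMatrix, n_pool: int,
                     x_mask: np.ndarray, rng: np.random.Generator):
    """Realised maternal/paternal haplotype alleles of the pooled F1 females."""
    mother = parents.row(cross.mother_id)
    father = parents.row(cross.true_father_id)
    # pooled females are drawn from complete parental haplotypes: treat the few
    # missing parental calls as the colony-typical allele (dosage via consensus 0)
    mother = np.where(mother == MISSING, 0, mother)
    father = np.where(father == MISSING, 0, father)
    mat = _gametes(mother, n_pool, rng)
    pat = _gametes(father, n_pool, rng)
    # females carry a paternal X normally; nothing special needed
    _ = x_mask
    return mat, pat


def pool_expected_fraction(bundle: "CohortBundle", cross: CrossSpec,
                           site_idx: np.ndarray, allele_a: np.ndarray) -> np.ndarray:
    """Expected fraction of reads carrying allele_a at each queried site.

    Copy-weighted over the realised pool: each female contributes her maternal
    haplotype with weight (maternal copies x maternal expression weight) and
    likewise paternally; cis-regulated genes weight the colony haplotype
    carrying the high allele by the true major fraction.
    """
    cfg = bundle.config
    mat, pat = bundle.pools[cross.cross_id]
    truth = bundle.truth.genes
    gene_idx = bundle.site_gene[site_idx]
    gene_ids = [bundle.genes[g].gene_id for g in gene_idx]
    wm = np.full(len(site_idx), 0.5)
    wp = np.full(len(site_idx), 0.5)
    is_ase = truth.loc[gene_ids, "is_ase"].to_numpy()
    high = truth.loc[gene_ids, "high_colony"].to_numpy()
    tmaf = truth.loc[gene_ids, "true_maf"].to_numpy()
    mat_high = is_ase & (high == cross.mother_colony)
    pat_high = is_ase & (high == cross.father_colony)
    wm[mat_high], wp[mat_high] = tmaf[mat_high], 1 - tmaf[mat_high]
    wm[pat_high], wp[pat_high] = 1 - tmaf[pat_high], tmaf[pat_high]

    # copy numbers per female per queried gene (duplication on one colony haplotype)
    n = cfg.n_pool_females
    has_cnv = truth.loc[gene_ids, "has_cnv"].to_numpy()
    cnv_col = truth.loc[gene_ids, "cnv_colony"].to_numpy()
    cm = np.ones((n, len(site_idx)))
    cp = np.ones((n, len(site_idx)))
    if has_cnv.any():
        carrier = bundle._pool_cnv_carriers[cross.cross_id]  # (n, n_genes) bool
        dup_mat = has_cnv & (cnv_col == cross.mother_colony)
        dup_pat = has_cnv & (cnv_col == cross.father_colony)
        car = carrier[:, gene_idx]
        cm[:, dup_mat] += car[:, dup_mat]
        cp[:, dup_pat] += car[:, dup_pat]

    mat_a = (mat[:, site_idx] == allele_a)
    pat_a = (pat[:, site_idx] == allele_a)
    num = (cm * wm * mat_a + cp * wp * pat_a).sum(axis=0)
    den = (cm * wm + cp * wp).sum(axis=0)
    return num / den


def counts_at_sites(bundle: "CohortBundle", cross_id: str, site_idx: np.ndarray,
                    allele_a: np.ndarray, rng: np.random.Generator,
                    phase_known: bool) -> pd.DataFrame:
    """Simulate a pooled-RNA allelic count table at an arbitrary site set.

    ``allele_a`` gives, per queried site, the allele (0/1) counted as
    ``count_a``.  Used both for matched informative sites and for the
    wrong-parent swap diagnostic (scoring a cross at another cross's SNPs).
    """
    cfg = bundle.config
    cross = next(c for c in bundle.crosses if c.cross_id == cross_id)
    mu = pool_expected_fraction(bundle, cross, site_idx, allele_a)
    totals = rng.poisson(cfg.mean_coverage, size=len(site_idx))
    k = simulate_allelic_counts(totals, mu, cfg.rho_true, rng)
    gene_idx = bundle.site_gene[site_idx]
    return pd.DataFrame({
        "sample": cross_id,
        "chrom": [bundle.sites[s][0] for s in site_idx],
        "pos": [bundle.sites[s][1] for s in site_idx],
        "gene_id": [bundle.genes[g].gene_id for g in gene_idx],
        "count_a": k.astype(int),
        "count_b": (totals - k).astype(int),
        "phase_known": phase_known,
    })


def informative_sites(parents: GenotypeMatrix, cross: CrossSpec) -> np.ndarray:
    """Indices of sites where the cross's parents are homozygous-different."""
    m = parents.row(cross.mother_id)
    f = parents.row(cross.true_father_id)
    mask = ((m == 0) & (f == 2)) | ((m == 2) & (f == 0))
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Gene truth, ages, CNV


def _gene_truth(config: SimConfig, genes, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    age = rng.choice(N_AGE_CLASSES, size=n, p=AGE_CLASS_PROBS)
    p_ase = np.full(n, config.frac_ase)
    if config.ase_young_bias != 1.0:
        p_ase[age == N_AGE_CLASSES - 1] = np.clip(
            config.frac_ase * config.ase_young_bias, 0, 1)
    is_ase = rng.random(n) < p_ase
    if config.ase_maf_jitter > 0:
        maf = rng.uniform(config.ase_maf - config.ase_maf_jitter,
                          config.ase_maf + config.ase_maf_jitter, size=n)
        maf = np.clip(maf, 0.5 + 1e-6, 1.0)
    else:
        maf = np.full(n, config.ase_maf)
    true_maf = np.where(is_ase, maf, 0.5)
    high = rng.choice([COLONY_SUS, COLONY_RES], size=n)
    has_cnv = rng.random(n) < config.frac_cnv
    cnv_col = rng.choice([COLONY_SUS, COLONY_RES], size=n)
    cnv_col = np.where(has_cnv, cnv_col, "")
    return pd.DataFrame({
        "is_ase": is_ase, "true_maf": true_maf, "high_colony": high,
        "has_cnv": has_cnv, "cnv_colony": cnv_col, "age_class": age,
        "arm": [g.arm for g in genes],
    }, index=pd.Index([g.gene_id for g in genes], name="gene_id"))


def _presence_matrix(truth: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Presence/absence per tip: a gene born in age class c occupies the clade
    of the focal lineage's ancestor c (single gain, no loss)."""
    _ = rng
    n = len(truth)
    mat = np.zeros((n, len(TREE_TIPS)), dtype=int)
    for j, _tip in enumerate(TREE_TIPS):
        # tip j (ladder order) belongs to the clades of ancestors 0..j
        mat[:, j] = (truth["age_class"].to_numpy() <= j).astype(int)
    return pd.DataFrame(mat, index=truth.index, columns=TREE_TIPS)


def _copy_number_table(bundle: "CohortBundle", rng: np.random.Generator) -> pd.DataFrame:
    """Long-format copy numbers for individuals at planted-CNV genes.

    Parents of the duplication-carrying colony have three copies; siblings
    inherit the extra copy with probability one half.
    """
    truth = bundle.truth.genes
    rows = []
    cnv_genes = truth.index[truth["has_cnv"]]
    for gid in cnv_genes:
        colony = truth.loc[gid, "cnv_colony"]
        for cross in bundle.crosses:
            parent = cross.mother_id if cross.mother_colony == colony else cross.true_father_id
            other = cross.true_father_id if cross.mother_colony == colony else cross.mother_id
            rows.append((gid, parent, 3))
            rows.append((gid, other, 2))
            for sib in bundle.sib_matrices[cross.cross_id].individuals:
                rows.append((gid, sib, 2 + int(rng.integers(0, 2))))
    return pd.DataFrame(rows, columns=["gene_id", "individual", "copy_number"])


# ---------------------------------------------------------------------------
# Cohort assembly


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate a complete, internally consistent synthetic cohort."""
    root = np.random.SeedSequence(config.seed)
    rng_layout, rng_parents, rng_truth, rng_f1, rng_pool, rng_counts, rng_cnv = (
        np.random.default_rng(s) for s in root.spawn(7))

    genes, sites, site_gene = _gene_layout(config, rng_layout)
    parents, colony_of, fixed_diff, crosses, candidates = simulate_parents(
        config, rng_parents, sites=sites)
    truth_df = _gene_truth(config, genes, rng_truth)
    chroms = np.array([s[0] for s in sites])
    x_mask = chroms == "X"

    sib_matrices = {}
    for cross in crosses:
        mother = parents.row(cross.mother_id)
        father = parents.row(cross.true_father_id)
        mother = np.where(mother == MISSING, 0, mother)
        father = np.where(father == MISSING, 0, father)
        sibs = simulate_f1(mother, father, config.n_sibs, rng=rng_f1,
                           male_x_mask=x_mask,
                           ids=[f"{cross.cross_id}_sib{i}" for i in range(config.n_sibs)],
                           sites=sites)
        if config.missing_rate > 0:
            miss = rng_f1.random(sibs.dosages.shape) < config.missing_rate
            sibs.dosages[miss] = MISSING
        sib_matrices[cross.cross_id] = sibs

    fixed_sites = [(sites[i][0], sites[i][1]) for i in np.flatnonzero(fixed_diff)]
    truth = SimTruth(truth_df, {c.cross_id: c.true_father_id for c in crosses}, fixed_sites)

    bundle = CohortBundle(config=config, genes=genes, sites=sites, site_gene=site_gene,
                          parents=parents, colony_of=colony_of,
                          candidate_fathers=candidates, crosses=crosses,
                          sib_matrices=sib_matrices, counts={},
                          copy_number=pd.DataFrame(), presence=_presence_matrix(truth_df, rng_truth),
                          truth=truth)

    # realised pool haplotypes and CNV carriers per cross
    bundle._pool_cnv_carriers = {}
    for cross in crosses:
        bundle.pools[cross.cross_id] = _pool_haplotypes(
            cross, parents, config.n_pool_females, x_mask, rng_pool)
        bundle._pool_cnv_carriers[cross.cross_id] = (
            rng_cnv.random((config.n_pool_females, config.n_genes)) < 0.5)

    bundle.copy_number = _copy_number_table(bundle, rng_cnv)

    from .parentage_qc import infer_sibling_snps

    for cross in crosses:
        if cross.phased:
            idx = informative_sites(parents, cross)
            mother = parents.row(cross.mother_id)
            # count_a = maternal allele (0 where mother hom-ref, 1 where hom-alt)
            allele_a = (mother[idx] == 2).astype(np.int8)
            bundle.counts[cross.cross_id] = counts_at_sites(
                bundle, cross.cross_id, idx, allele_a, rng_counts, phase_known=True)
        else:
            mask = infer_sibling_snps(sib_matrices[cross.cross_id])
            idx = np.flatnonzero(mask)
            allele_a = np.zeros(len(idx), dtype=np.int8)  # reference-based counting
            bundle.counts[cross.cross_id] = counts_at_sites(
                bundle, cross.cross_id, idx, allele_a, rng_counts, phase_known=False)
    return bundle


# ---------------------------------------------------------------------------
# Bundle I/O


def write_bundle(bundle: CohortBundle, out_dir) -> Path:
    """Write the cohort as the file dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_annotation(bundle.genes, out / "genes.bed")
    write_vcf_subset(bundle.parents.to_records(), bundle.parents.individuals,
                     out / "parents.vcf")
    for cross in bundle.crosses:
        sibs = bundle.sib_matrices[cross.cross_id]
        write_vcf_subset(sibs.to_records(), sibs.individuals,
                         out / f"sibs_{cross.cross_id}.vcf")
        write_count_table(bundle.counts[cross.cross_id],
                          out / f"counts_{cross.cross_id}.tsv")
    write_copy_number(bundle.copy_number, out / "copy_number.tsv")
    write_presence_absence(bundle.presence, out / "presence_absence.tsv")
    (out / "tree.nwk").write_text(bundle.tree_newick + "\n")
    truth = bundle.truth.genes.copy()
    truth.to_csv(out / "truth_genes.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame({
        "cross_id": [c.cross_id for c in bundle.crosses],
        "mother_id": [c.mother_id for c in bundle.crosses],
        "true_father_id": [c.true_father_id for c in bundle.crosses],
        "mother_colony": [c.mother_colony for c in bundle.crosses],
        "phased": [int(c.phased) for c in bundle.crosses],
    }).to_csv(out / "crosses.tsv", sep="\t", index=False)
    import json
    from dataclasses import asdict
    (out / "config.json").write_text(json.dumps(asdict(bundle.config), indent=2) + "\n")
    return out
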