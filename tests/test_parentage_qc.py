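import itertools

import numpy as np
import pytest

from asecross import parentage_qc as pq
from asecross.synthetic_data import (SimConfig, counts_at_sites, informative_sites,
                                     simulate_cohort, simulate_f1)

AUTOSOMES = ("2L", "2R", "3L", "3R")


def _autosomal(matrix):
    return matrix.subset_sites(np.isin(matrix.chroms(), AUTOSOMES))


class TestMendelianError:
    def test_forced_examples(self):
        # mother AA, father AA, child AB is impossible; AA x BB forces AB
        assert pq.mendelian_error_rate(0, 0, 1) == pq.ERROR
        assert pq.mendelian_error_rate(0, 2, 1) == pq.CONSISTENT
        assert pq.mendelian_error_rate(0, 2, 0) == pq.ERROR
        assert pq.mendelian_error_rate(pq.MISSING, 0, 0) == pq.UNINFORMATIVE

    def test_exhaustive_grid_matches_gamete_enumeration(self):
        """All 27 genotype triples agree with brute-force gamete enumeration."""
        alleles = {0: (0,), 1: (0, 1), 2: (1,)}
        for m, f, c in itertools.product((0, 1, 2), repeat=3):
            possible = {a + b for a in alleles[m] for b in alleles[f]}
            expected = pq.CONSISTENT if c in possible else pq.ERROR
            assert pq.mendelian_error_rate(m, f, c) == expected
            # vectorised path agrees with the scalar classification
            err, inf = pq._trio_error_mask(np.array([m]), np.array([f]), np.array([c]))
            assert bool(inf[0]) and bool(err[0]) == (expected == pq.ERROR)


class TestMatchFather:
    def test_true_father_recovered_with_zero_median_error(self, small_bundle):
        parents = _autosomal(small_bundle.parents)
        for cross in small_bundle.crosses:
            if not cross.phased:
                continue
            cands = {f: parents.row(f)
                     for f in small_bundle.candidate_fathers[cross.father_colony]}
            sibs = _autosomal(small_bundle.sib_matrices[cross.cross_id])
            assigned, summaries = pq.match_father(parents.row(cross.mother_id),
                                                  cands, sibs)
            assert assigned == cross.true_father_id
            assert summaries[0].median_rate == 0.0

    def test_unrelated_candidates_yield_no_match(self, small_bundle):
        # candidates from the mother's own colony share no paternal haplotype:
        # their Mendelian error rates are far above a 2% threshold
        parents = _autosomal(small_bundle.parents)
        cross = small_bundle.crosses[0]
        wrong = {f: parents.row(f)
                 for f in small_bundle.candidate_fathers[cross.mother_colony]}
        sibs = _autosomal(small_bundle.sib_matrices[cross.cross_id])
        assigned, summaries = pq.match_father(parents.row(cross.mother_id), wrong,
                                              sibs, max_error=0.02)
        assert assigned is None
        assert summaries[0].median_rate > 0.02

    def test_single_true_candidate_returned(self, small_bundle):
        parents = _autosomal(small_bundle.parents)
        cross = next(c for c in small_bundle.crosses if c.phased)
        sibs = _autosomal(small_bundle.sib_matrices[cross.cross_id])
        assigned, _ = pq.match_father(
            parents.row(cross.mother_id),
            {cross.true_father_id: parents.row(cross.true_father_id)}, sibs)
        assert assigned == cross.true_father_id

    def test_all_missing_candidate_excluded(self, small_bundle):
        parents = _autosomal(small_bundle.parents)
        cross = next(c for c in small_bundle.crosses if c.phased)
        sibs = _autosomal(small_bundle.sib_matrices[cross.cross_id])
        cands = {"ghost": np.full(parents.n_sites, pq.MISSING, dtype=np.int8),
                 cross.true_father_id: parents.row(cross.true_father_id)}
        assigned, summaries = pq.match_father(parents.row(cross.mother_id), cands, sibs)
        assert assigned == cross.true_father_id
        assert all(s.candidate_father != "ghost" for s in summaries)

    def test_planted_father_recovered_across_seeds(self):
        """With >= 500 informative autosomal sites the planted father is the
        unique zero-error candidate in every one of 20 simulated cohorts."""
        from asecross.synthetic_data import SimConfig, simulate_parents, simulate_f1

        recovered = trials = 0
        for seed in range(500, 520):
            cfg = SimConfig(seed=seed, n_genes=100)
            rng = np.random.default_rng(np.random.SeedSequence(seed))
            matrix, colony_of, _, crosses, candidates = simulate_parents(cfg, rng)
            chroms = matrix.chroms()
            auto = np.isin(chroms, AUTOSOMES)
            ma = matrix.subset_sites(auto)
            cross = next(c for c in crosses if c.phased)
            mother = np.where(ma.row(cross.mother_id) == pq.MISSING, 0,
                              ma.row(cross.mother_id))
            father = np.where(ma.row(cross.true_father_id) == pq.MISSING, 0,
                              ma.row(cross.true_father_id))
            sibs = simulate_f1(mother, father, cfg.n_sibs, rng=rng, sites=ma.sites)
            assert ma.n_sites >= 500
            cands = {f: ma.row(f) for f in candidates[cross.father_colony]}
            assigned, _ = pq.match_father(ma.row(cross.mother_id), cands, sibs)
            trials += 1
            recovered += assigned == cross.true_father_id
        assert recovered == trials == 20

    def test_requires_candidates_and_progeny(self, small_bundle):
        parents = _autosomal(small_bundle.parents)
        cross = small_bundle.crosses[0]
        with pytest.raises(ValueError):
            pq.match_father(parents.row(cross.mother_id), {},
                            _autosomal(small_bundle.sib_matrices[cross.cross_id]))


class TestSiblingSnps:
    def _matrix(self, dosages, chrom="2L"):
        dosages = np.asarray(dosages, dtype=np.int8)
        sites = [(chrom, j + 1, "A", "T") for j in range(dosages.shape[1])]
        ids = [f"s{i}" for i in range(dosages.shape[0])]
        return pq.GenotypeMatrix(ids, sites, dosages)

    def test_all_het_informative_one_hom_excluded(self):
        m = self._matrix([[1, 1], [1, 0], [1, 1]])
        mask = pq.infer_sibling_snps(m)
        assert mask.tolist() == [True, False]

    def test_x_sites_excluded(self):
        m = self._matrix([[1], [1]], chrom="X")
        assert pq.infer_sibling_snps(m).tolist() == [False]

    def test_recovers_parental_hom_diff_sites(self, small_bundle):
        """Sibling-inferred sites include every fully observed autosomal site
        where the parents are homozygous-different; extras are rare het x het
        leakage sites at which every sibling happens to be heterozygous."""
        parents = small_bundle.parents
        cross = small_bundle.crosses[0]
        sibs = small_bundle.sib_matrices[cross.cross_id]
        mask = pq.infer_sibling_snps(sibs)
        got = set(np.flatnonzero(mask))
        chroms = parents.chroms()
        fully_observed = (sibs.dosages != pq.MISSING).all(axis=0)
        expected = {i for i in informative_sites(parents, cross)
                    if chroms[i] in AUTOSOMES and fully_observed[i]}
        assert expected <= got
        # leakage stays a small minority of the returned set
        assert len(got - expected) <= 0.1 * len(got)
        for i in got:
            d = sibs.dosages[:, i]
            assert ((d == 1) | (d == pq.MISSING)).all()

    def test_het_by_het_leakage_matches_binomial_rate(self):
        """With parents het x het, P(all n sibs het) = 0.5^n per site."""
        n_sites, n_sibs = 4000, 6
        rng = np.random.default_rng(7)
        sites = [("2L", j + 1, "A", "T") for j in range(n_sites)]
        sibs = simulate_f1(np.ones(n_sites, dtype=np.int8),
                           np.ones(n_sites, dtype=np.int8), n_sibs,
                           rng=rng, sites=sites)
        frac = pq.infer_sibling_snps(sibs).mean()
        p = 0.5 ** n_sibs
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n_sites)


class TestConsensusDiff:
    def _colony(self, dosages, sites=None):
        dosages = np.asarray(dosages, dtype=np.int8)
        if sites is None:
            sites = [("2L", j + 1, "A", "T") for j in range(dosages.shape[1])]
        return pq.GenotypeMatrix([f"i{k}" for k in range(dosages.shape[0])],
                                 sites, dosages)

    def test_identical_colonies_zero(self):
        a = self._colony([[0, 2, 1], [0, 2, 1]])
        counts = pq.consensus_diff_counts(a, a)
        assert counts["total"] == 0

    def test_single_planted_difference(self):
        a = self._colony([[0, 0], [0, 0]])
        b = self._colony([[0, 2], [0, 2]])
        counts = pq.consensus_diff_counts(a, b)
        assert counts == {"2L": 1, "2R": 0, "3L": 0, "3R": 0, "X": 0,
                          "other": 0, "total": 1}

    def test_planted_cohort_differences_recovered_exactly(self, small_bundle):
        parents = small_bundle.parents
        by_colony = {}
        for colony in ("sus", "res"):
            rows = [parents.individuals.index(i) for i in parents.individuals
                    if small_bundle.colony_of[i] == colony]
            by_colony[colony] = pq.GenotypeMatrix(
                [parents.individuals[r] for r in rows], parents.sites,
                parents.dosages[rows])
        counts = pq.consensus_diff_counts(by_colony["sus"], by_colony["res"])
        assert counts["total"] == len(small_bundle.truth.fixed_diff_sites)
        assert counts["total"] == sum(counts[a] for a in ("2L", "2R", "3L", "3R", "X", "other"))

    def test_site_universe_mismatch_rejected(self):
        a = self._colony([[0]])
        b = self._colony([[0, 0]])
        with pytest.raises(ValueError):
            pq.consensus_diff_counts(a, b)


class TestMismatchDiagnostic:
    def test_balanced_counts(self):
        import pandas as pd
        df = pd.DataFrame({"count_a": [5, 5, 5], "count_b": [5, 5, 5]})
        dev, mean = pq.mismatch_diagnostic(df)
        assert dev == 0.0 and mean == 0.5

    def test_single_snp(self):
        import pandas as pd
        df = pd.DataFrame({"count_a": [9], "count_b": [1]})
        dev, mean = pq.mismatch_diagnostic(df)
        assert mean == pytest.approx(0.9) and dev == pytest.approx(0.4)

    def test_empty_after_filter_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            pq.mismatch_diagnostic(pd.DataFrame({"count_a": [1], "count_b": [2]}))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_wrong_parent_snps_inflate_imbalance(self, seed):
        """Scoring a cross's RNA at another cross's parental SNPs shifts
        per-SNP fractions away from 0.5 (the F1 pool is homozygous at many
        of the foreign sites)."""
        cfg = SimConfig(seed=seed, n_genes=150, n_crosses=4, n_unphased=0)
        bundle = simulate_cohort(cfg)
        c1 = bundle.crosses[2]
        c2 = next(c for c in bundle.crosses
                  if c.true_father_id != c1.true_father_id and c is not c1)
        rng = np.random.default_rng(100 + seed)
        dev_matched, _ = pq.mismatch_diagnostic(bundle.counts[c1.cross_id])
        idx = informative_sites(bundle.parents, c2)
        allele_a = (bundle.parents.row(c2.mother_id)[idx] == 2).astype(np.int8)
        foreign = counts_at_sites(bundle, c1.cross_id, idx, allele_a, rng,
                                  phase_known=True)
        dev_mismatched, _ = pq.mismatch_diagnostic(foreign)
        assert dev_mismatched > dev_matched


class TestReportArithmetic:
    def test_mapping_summary_published_values(self):
        from asecross.study_tables import MAPPING_RATES_PCT
        mean, sd = pq.summarize_mapping(MAPPING_RATES_PCT)
        assert round(mean, 1) == 87.0
        assert round(sd, 1) == 1.1

    def test_mapping_summary_edge_cases(self):
        assert pq.summarize_mapping([3.0, 3.0, 3.0]) == (3.0, 0.0)
        mean, _ = pq.summarize_mapping([2.0, 4.0])
        assert mean == 3.0
        with pytest.raises(ValueError):
            pq.summarize_mapping([1.0])

    def test_reads_for_power(self):
        assert pq.reads_for_power(13_796, 500) == 6_898_000
        assert pq.reads_for_power(0, 500) == 0
        assert pq.reads_for_power(1, 500) == 500

    def test_percent_relative_increase(self):
        assert round(pq.percent_relative_increase(65.9, 97.4)) == 48
        assert pq.percent_relative_increase(5.0, 5.0) == 0.0
        assert pq.percent_relative_increase(50, 75) == 50.0
        with pytest.raises(ValueError):
            pq.percent_relative_increase(0, 1)
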