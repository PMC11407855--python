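import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asecross import enrichment_stats as es
from asecross.io_formats import GeneModel, IntervalRecord
from asecross.synthetic_data import FOCAL_TAXON, TREE_NEWICK, TREE_TIPS


# ---------------------------------------------------------------------------
# Independent oracles

def fisher_p_by_enumeration(a, b, c, d):
    """Two-sided Fisher p: sum hypergeometric probabilities of all tables with
    the observed margins whose probability <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    rv = stats.hypergeom(n, r1, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


def wagner_age_by_enumeration(tree, tip_state, focal):
    """Brute force over all internal labelings: minimum change count, then the
    deepest focal ancestor present in any minimum-cost labeling."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.leaf_node_iter()]
    focal_leaf = next(l for l in leaves if l.taxon.label == focal)
    path = []
    node = focal_leaf
    while node is not None:
        path.append(node)
        node = node.parent_node
    path = path[::-1]

    best_cost = None
    best_age = None
    for states in itertools.product((0, 1), repeat=len(internals)):
        lab = dict(zip((id(n) for n in internals), states))
        for l in leaves:
            lab[id(l)] = tip_state[l.taxon.label]
        cost = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                cost += lab[id(nd)] != lab[id(nd.parent_node)]
        age = len(path) - 1
        for depth, nd in enumerate(path):
            if lab[id(nd)] == 1:
                age = depth
                break
        if best_cost is None or cost < best_cost or \
                (cost == best_cost and age < best_age):
            best_cost, best_age = cost, age
    return best_cost, best_age


# ---------------------------------------------------------------------------


class TestFisher:
    def test_published_cnv_table(self):
        odds, p = es.fisher_exact_2x2((60, 54, 481, 852))
        assert round(odds, 1) == 2.0
        assert p == pytest.approx(0.0006, abs=1e-4)

    def test_published_sweep_table(self):
        odds, p = es.fisher_exact_2x2((13, 102, 103, 1230))
        assert round(odds, 1) == 1.5
        assert p == pytest.approx(0.2, abs=0.05)

    def test_small_symmetric_table(self):
        odds, p = es.fisher_exact_2x2((2, 1, 1, 2))
        assert odds == 4.0 and p == pytest.approx(1.0)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            t = rng.integers(0, 12, size=4)
            _, p = es.fisher_exact_2x2(tuple(t))
            assert p == pytest.approx(fisher_p_by_enumeration(*t), rel=1e-6)
            assert 0 < p <= 1

    def test_transposition_inverts_odds(self):
        o1, p1 = es.fisher_exact_2x2((8, 3, 4, 9))
        o2, p2 = es.fisher_exact_2x2((3, 8, 9, 4))
        assert o1 == pytest.approx(1 / o2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_and_invalid(self):
        odds, _ = es.fisher_exact_2x2((3, 0, 0, 3))
        assert odds == float("inf")
        with pytest.raises(ValueError):
            es.fisher_exact_2x2((-1, 1, 1, 1))


@pytest.fixture(scope="module")
def stree():
    t = dendropy.Tree.get(data=TREE_NEWICK, schema="newick")
    return es.SpeciesTree(t, FOCAL_TAXON)


class TestWagnerAges:
    def test_focal_only_is_youngest(self, stree):
        pres = pd.DataFrame([[0, 0, 0, 0, 0, 1]], columns=TREE_TIPS, index=["g"])
        assert es.age_assign(pres, stree).loc["g"] == stree.n_age_classes - 1

    def test_all_present_is_root_class(self, stree):
        pres = pd.DataFrame([[1] * 6], columns=TREE_TIPS, index=["g"])
        assert es.age_assign(pres, stree).loc["g"] == 0

    def test_absent_from_focal_rejected(self, stree):
        pres = pd.DataFrame([[1, 1, 1, 1, 1, 0]], columns=TREE_TIPS, index=["g"])
        with pytest.raises(ValueError, match="absent from focal"):
            es.age_assign(pres, stree)

    def test_matches_exhaustive_enumeration_on_ladder(self, stree, rng):
        for _ in range(40):
            state = dict(zip(TREE_TIPS, rng.integers(0, 2, size=6)))
            state[FOCAL_TAXON] = 1
            _, age_bf = wagner_age_by_enumeration(stree.tree, state, FOCAL_TAXON)
            pres = pd.DataFrame([state], index=["g"])
            assert es.age_assign(pres, stree).loc["g"] == age_bf

    @pytest.mark.parametrize("newick,focal", [
        ("((A,B),((C,D),(E,F)));", "A"),
        ("(((A,B),C),((D,E),(F,(G,H))));", "G"),
        ("((((A,B),(C,D)),E),(F,G));", "C"),
    ])
    def test_matches_enumeration_on_assorted_trees(self, newick, focal, rng):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        stree = es.SpeciesTree(tree, focal)
        tips = stree.tip_labels()
        for _ in range(25):
            state = dict(zip(tips, rng.integers(0, 2, size=len(tips))))
            state[focal] = 1
            _, age_bf = wagner_age_by_enumeration(stree.tree, state, focal)
            pres = pd.DataFrame([state], index=["g"])
            assert es.age_assign(pres, stree).loc["g"] == age_bf


class TestAgeEnrichment:
    def test_identical_distributions_not_significant(self):
        ages = pd.Series({f"g{i}": i % 3 for i in range(60)})
        ase = [f"g{i}" for i in range(0, 30)]
        non = [f"g{i}" for i in range(30, 60)]
        t = es.age_enrichment(ase, non, ages)
        assert (t["p_value"] > 0.5).all()

    def test_planted_young_excess_detected(self, rng):
        ages = pd.Series({f"g{i}": (2 if i < 200 else 0) for i in range(400)})
        ase = [f"g{i}" for i in range(0, 150)]          # mostly young
        non = [f"g{i}" for i in range(150, 400)]        # mostly old
        t = es.age_enrichment(ase, non, ages).set_index("age_class")
        assert t.loc[2, "p_value"] < 0.05
        assert t.loc[2, "odds_ratio"] > 1

    def test_empty_class_skipped(self):
        ages = pd.Series({"g1": 0, "g2": 0, "g3": 5})
        t = es.age_enrichment(["g1"], ["g2"], ages)
        assert 5 not in set(t["age_class"])


class TestArmAnova:
    def _grid(self, values):
        rows = []
        arms = ["2L", "2R", "3L", "3R"]
        crosses = [f"c{i}" for i in range(len(values[0]))]
        for i, arm in enumerate(arms):
            for j, cross in enumerate(crosses):
                rows.append((arm, cross, values[i][j]))
        return pd.DataFrame(rows, columns=["arm", "cross", "proportion"])

    def test_constant_grid(self):
        r = es.arm_anova(self._grid([[0.1] * 3] * 4))
        assert r.f_arm == 0.0 and r.p_arm == 1.0
        assert r.f_cross == 0.0 and r.p_cross == 1.0

    def test_planted_arm_effect(self, rng):
        base = rng.uniform(0.08, 0.12, size=(4, 6))
        base[1] += 0.2
        r = es.arm_anova(self._grid(base))
        assert r.p_arm < 0.01

    def test_sum_of_squares_identity(self, rng):
        vals = rng.random((4, 5))
        r = es.arm_anova(self._grid(vals))
        assert r.ss_total == pytest.approx(r.ss_arm + r.ss_cross + r.ss_resid,
                                           abs=1e-9)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = self._grid(rng.random((4, 4)))
        r = es.arm_anova(df)
        fit = smf.ols("proportion ~ C(arm) + C(cross)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert r.f_arm == pytest.approx(tab.loc["C(arm)", "F"])
        assert r.p_arm == pytest.approx(tab.loc["C(arm)", "PR(>F)"])

    def test_missing_cell_rejected(self):
        df = self._grid([[0.1] * 2] * 4).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            es.arm_anova(df)


class TestIntervalOps:
    @staticmethod
    def _random_intervals(rng, n, label):
        out = []
        for i in range(n):
            chrom = rng.choice(["2L", "2R"])
            start = int(rng.integers(0, 5000))
            out.append(IntervalRecord(chrom, start, start + int(rng.integers(1, 300)),
                                      f"{label}{i}"))
        return out

    def test_overlap_trivials(self):
        a = [IntervalRecord("2L", 0, 10, "a")]
        assert es.overlap_count(a, [IntervalRecord("2L", 10, 20, "b")]) == 0
        assert es.overlap_count(a, a) == 1

    def test_overlap_matches_quadratic_oracle(self, rng):
        for _ in range(30):
            a = self._random_intervals(rng, 30, "a")
            b = self._random_intervals(rng, 30, "b")
            brute = sum(any(x.chrom == y.chrom and x.start < y.end and y.start < x.end
                            for y in b) for x in a)
            assert es.overlap_count(a, b) == brute

    @staticmethod
    def _random_genes(rng, n):
        genes = []
        pos = 0
        for i in range(n):
            arm = "2L" if i < n // 2 else "2R"
            start = int(rng.integers(pos, pos + 400))
            genes.append(GeneModel(f"g{i}", arm, start, start + int(rng.integers(50, 400)),
                                   arm))
            pos = start + 500
        return genes

    def _flank_oracle(self, iv, genes):
        same = [g for g in genes if g.chrom == iv.chrom]
        overlapping = [g for g in same if g.start < iv.end and g.end > iv.start]
        left = [g for g in same if g.end <= iv.start]
        right = [g for g in same if g.start >= iv.end]
        out = []
        if left:
            out.append(max(left, key=lambda g: g.end).gene_id)
        out.extend(g.gene_id for g in overlapping)
        if right:
            out.append(min(right, key=lambda g: g.start).gene_id)
        return out

    def test_flank_containment_and_between(self):
        genes = [GeneModel("g1", "2L", 100, 200, "2L"),
                 GeneModel("g2", "2L", 300, 400, "2L")]
        inside = es.flank_assign([IntervalRecord("2L", 150, 160, "iv")], genes)
        assert "g1" in inside["iv"]
        between = es.flank_assign([IntervalRecord("2L", 220, 240, "iv")], genes)
        assert between["iv"] == ["g1", "g2"]

    def test_flank_matches_quadratic_oracle(self, rng):
        for _ in range(20):
            genes = self._random_genes(rng, 25)
            ivs = self._random_intervals(rng, 15, "iv")
            got = es.flank_assign(ivs, genes)
            for iv in ivs:
                assert sorted(got[iv.label]) == sorted(self._flank_oracle(iv, genes))


def test_cnv_confounder_inflates_odds_ratio_across_seeds():
    """Copy-number duplications shift pooled allele fractions, so genes with
    planted CNV are over-represented among significant calls: the CNV-vs-ASE
    odds ratio exceeds 1 in at least 19 of 20 simulated cohorts."""
    from asecross.ase_core import NullModel, run_gene_ase
    from asecross.synthetic_data import SimConfig, simulate_cohort

    above_one = 0
    for seed in range(200, 220):
        cfg = SimConfig(seed=seed, n_genes=400, n_crosses=1, n_unphased=0)
        bundle = simulate_cohort(cfg)
        res = run_gene_ase(bundle.counts[bundle.crosses[0].cross_id],
                           NullModel(0.038, 3000, seed), phased=True)
        flags = es.cnv_flag(bundle.copy_number)
        arm_of = dict(zip(bundle.truth.genes.index, bundle.truth.genes["arm"]))
        auto = {"2L", "2R", "3L", "3R"}
        sig = [g for g in res.loc[res["q_ase"] <= 0.05, "gene_id"]
               if arm_of[g] in auto]
        non = [g for g in set(res["gene_id"]) - set(sig) if arm_of[g] in auto]
        a = sum(bool(flags.get(g, False)) for g in sig)
        c = sum(bool(flags.get(g, False)) for g in non)
        odds, _ = es.fisher_exact_2x2((a, len(sig) - a, c, len(non) - c))
        above_one += odds > 1
    assert above_one >= 19


class TestCnvFlag:
    def test_trivials(self):
        df = pd.DataFrame({"gene_id": ["g1", "g1", "g2"],
                           "individual": ["a", "b", "a"],
                           "copy_number": [2, 2, 3]})
        flags = es.cnv_flag(df)
        assert not flags["g1"] and flags["g2"]

    def test_individual_restriction(self):
        df = pd.DataFrame({"gene_id": ["g1", "g1"], "individual": ["a", "b"],
                           "copy_number": [2, 3]})
        assert not es.cnv_flag(df, individuals=["a"])["g1"]

    def test_bundle_flags_match_planted_truth(self, small_bundle):
        flags = es.cnv_flag(small_bundle.copy_number)
        truth = small_bundle.truth.genes
        cnv_genes = set(truth.index[truth["has_cnv"]])
        assert set(flags.index[flags]) == cnv_genes
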