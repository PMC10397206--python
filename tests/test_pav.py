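"""Deletion calling, PAV genotyping and the PAV statistics."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from conftest import small_config
from sweeptepop.pav import (
    call_deletions,
    fisher_differentiation,
    filter_pav,
    genotype_pav,
    pav_clustering,
    pav_counts,
    pav_group_tests,
    pav_maf,
    singletons,
    superfamily_enrichment,
    wilcoxon_rank_sum,
)
from sweeptepop.simulate import (
    FragmentTable,
    simulate_read_pairs,
    simulate_snp_genotypes,
    simulate_te_deletions,
)
from sweeptepop.types import (
    Deletion,
    DeletionCallSet,
    PAVMatrix,
    TEAnnotation,
)


def _dels(acc_intervals) -> DeletionCallSet:
    d = DeletionCallSet()
    for acc, ivals in acc_intervals.items():
        for s, e in ivals:
            d.add(acc, Deletion("c1", s, e))
    return d


class TestGenotypePav:
    te = [TEAnnotation("t1", "c1", 5_000, 6_000, "LTR/Gypsy")]

    def test_boundary_inclusive_at_085(self):
        dels = _dels({"a": [(5_000, 5_850)]})
        pav = genotype_pav(self.te, dels, ["a", "b"], threshold=0.85)
        assert pav.codes[0, 0] == 0  # exactly 85% covered
        assert pav.codes[1, 0] == 1

    def test_union_of_fragmented_deletions(self):
        dels = _dels({"a": [(5_000, 5_400), (5_500, 6_000)]})
        for thr, want in [(0.85, 0), (0.90, 0), (0.95, 1)]:
            pav = genotype_pav(self.te, dels, ["a"], threshold=thr)
            assert pav.codes[0, 0] == want, thr

    def test_no_deletions_row_of_ones(self):
        pav = genotype_pav(self.te, _dels({}), ["a", "b", "c"], 0.85)
        assert (pav.codes == 1).all()

    def test_threshold_monotonicity_property(self):
        """Lower thresholds call a superset of absences."""
        rng = np.random.default_rng(0)
        tes = [TEAnnotation(f"t{j}", "c1", 10_000 * j, 10_000 * j + 1_000,
                            "LTR/Copia") for j in range(30)]
        dels = DeletionCallSet()
        for acc in ["a", "b", "c", "d"]:
            for j in rng.choice(30, 15, replace=False):
                frac = rng.uniform(0.6, 1.0)
                start = 10_000 * j
                dels.add(acc, Deletion("c1", start,
                                       start + int(1_000 * frac)))
        prev_zero = None
        for thr in (1.0, 0.95, 0.90, 0.85):
            pav = genotype_pav(tes, dels, ["a", "b", "c", "d"], thr)
            zeros = {(i, j) for i, j in zip(*np.where(pav.codes == 0))}
            if prev_zero is not None:
                assert prev_zero <= zeros
            prev_zero = zeros


def test_end_to_end_identity_with_truth_deletions():
    """genotype_pav on the simulator's truth deletions reproduces the
    truth PAV matrix exactly at the generating threshold."""
    cfg = small_config(seed=41)
    m = simulate_snp_genotypes(cfg)
    tes, truth, dels, _ = simulate_te_deletions(cfg, m)
    pav = genotype_pav(tes, dels, m.accessions, truth.overlap_threshold)
    np.testing.assert_array_equal(pav.codes, truth.codes)


class TestFilterPav:
    def test_length_boundary(self):
        tes = [TEAnnotation("short", "c1", 0, 499, "LTR/Gypsy"),
               TEAnnotation("long", "c1", 1_000, 1_500, "LTR/Gypsy")]
        pav = PAVMatrix(["a", "b"], ["short", "long"],
                        np.array([[0, 0], [1, 1]], dtype=np.int8))
        out = filter_pav(pav, tes, min_te_length=500, require_variable=False)
        assert out.te_ids == ["long"]

    def test_invariant_columns_dropped(self):
        tes = [TEAnnotation("t1", "c1", 0, 600, "LTR/Gypsy"),
               TEAnnotation("t2", "c1", 1_000, 1_600, "LTR/Gypsy")]
        pav = PAVMatrix(["a", "b"], ["t1", "t2"],
                        np.array([[1, 0], [1, 1]], dtype=np.int8))
        out = filter_pav(pav, tes, 500, require_variable=True)
        assert out.te_ids == ["t2"]

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        tes = [TEAnnotation(f"t{j}", "c1", 1_000 * j,
                            1_000 * j + int(rng.integers(100, 900)),
                            "LTR/Gypsy") for j in range(40)]
        codes = rng.choice([0, 1], size=(6, 40), p=[0.2, 0.8]).astype(np.int8)
        pav = PAVMatrix([f"a{i}" for i in range(6)],
                        [t.id for t in tes], codes)
        out = filter_pav(pav, tes, 500, True)
        want = [t.id for j, t in enumerate(tes)
                if t.length >= 500 and (codes[:, j] == 0).any()]
        assert out.te_ids == want


class TestPavStats:
    pav = PAVMatrix(["a", "b", "c", "d"], ["t1", "t2", "t3"],
                    np.array([[1, 0, 1],
                              [1, 0, 1],
                              [1, 1, 0],
                              [0, 1, -1]], dtype=np.int8))

    def test_maf_and_singletons(self):
        maf = pav_maf(self.pav)
        assert maf["t1"] == pytest.approx(0.25)
        assert maf["t2"] == pytest.approx(0.5)
        assert maf["t3"] == pytest.approx(1 / 3)
        assert singletons(self.pav) == ["t1", "t3"]

    def test_counts_sum_to_total_zeros(self):
        counts = pav_counts(self.pav)
        assert counts.tolist() == [1, 1, 1, 1]
        assert counts.sum() == (self.pav.codes == 0).sum()

    def test_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(2)
        codes = rng.choice([-1, 0, 1], size=(10, 50),
                           p=[0.05, 0.3, 0.65]).astype(np.int8)
        pav = PAVMatrix([f"a{i}" for i in range(10)],
                        [f"t{j}" for j in range(50)], codes)
        maf = pav_maf(pav)
        for j in range(50):
            col = codes[:, j][codes[:, j] >= 0]
            f = (col == 0).mean()
            assert maf.iloc[j] == pytest.approx(min(f, 1 - f))
        assert pav_counts(pav).tolist() == \
            [(codes[i] == 0).sum() for i in range(10)]
        assert singletons(pav) == \
            [f"t{j}" for j in range(50) if (codes[:, j] == 0).sum() == 1]


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration
    (minimum-likelihood convention)."""
    n1, n2 = a + b, c + d
    k = a + c
    lo, hi = max(0, k - n2), min(k, n1)
    probs = {x: hypergeom.pmf(x, n1 + n2, k, n1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


class TestFisher:
    def _pav_from_cols(self, col_a, col_b):
        codes = np.array([col_a + col_b], dtype=np.int8).T.reshape(-1, 1)
        accs = [f"x{i}" for i in range(len(col_a))] + \
               [f"y{i}" for i in range(len(col_b))]
        pops = {a: ("WILD_AI" if a.startswith("x") else "WILD_MI")
                for a in accs}
        return PAVMatrix(accs, ["te"], codes), pops

    def test_diagonal_table_example(self):
        """Table [[5,0],[0,5]] -> p = 2/C(10,5) = 2/252."""
        pav, pops = self._pav_from_cols([0] * 5, [1] * 5)
        res = fisher_differentiation(pav, pops, "WILD_AI", "WILD_MI",
                                     alpha=0.05)
        assert res[0].table == ((5, 0), (0, 5))
        assert res[0].fisher_p == pytest.approx(2 / 252, abs=1e-12)
        assert res[0].significant

    def test_balanced_table_p_one(self):
        pav, pops = self._pav_from_cols([0, 0, 0, 1, 1, 1],
                                        [0, 0, 0, 1, 1, 1])
        res = fisher_differentiation(pav, pops, "WILD_AI", "WILD_MI")
        assert res[0].fisher_p == pytest.approx(1.0)

    def test_matches_enumeration_for_small_margins(self):
        """scipy's two-sided p equals the hypergeometric enumeration for a
        grid of tables with margins <= 15."""
        from scipy.stats import fisher_exact
        for a in range(0, 16, 3):
            for b in range(0, 16 - a, 4):
                for c in range(0, 16, 3):
                    for d in range(0, 16 - c, 4):
                        if (a + b) == 0 or (c + d) == 0:
                            continue
                        _, p = fisher_exact([[a, b], [c, d]])
                        assert p == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-9), (a, b, c, d)

    def test_invariant_to_row_and_column_swaps(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 12, 4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            p = fisher_exact([[a, b], [c, d]])[1]
            assert fisher_exact([[c, d], [a, b]])[1] == pytest.approx(p)
            assert fisher_exact([[b, a], [d, c]])[1] == pytest.approx(p)


class TestGroupTests:
    def test_wilcoxon_exact_enumeration_value(self):
        """{1,2,3} vs {4,5,6}: most extreme of C(6,3)=20 assignments,
        two-sided p = 2/20."""
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_wilcoxon_identical_groups(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_pav_group_tests_shape(self):
        import pandas as pd
        counts = pd.Series([5, 6, 30, 31, 4, 5, 29, 30],
                           index=[f"a{i}" for i in range(8)])
        pops = {f"a{i}": p for i, p in enumerate(
            ["DOM_AI", "DOM_AI", "WILD_AI", "WILD_AI",
             "DOM_MI", "DOM_MI", "WILD_MI", "WILD_MI"])}
        df = pav_group_tests(counts, pops)
        assert len(df) == 6  # all population pairs
        row = df[(df.pop_a == "DOM_AI") & (df.pop_b == "WILD_AI")]
        assert row.wilcoxon_p.iloc[0] < 0.5

    def test_chi_square_arithmetic_example(self):
        """Observed [90,10] against equal background: chi2 = 64, df = 1."""
        res = superfamily_enrichment({"A": 90, "B": 10},
                                     {"A": 500, "B": 500})
        assert res.chi2 == pytest.approx(64.0)
        assert res.df == 1

    def test_empty_group_is_hard_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])


class TestCallDeletions:
    def _frag(self, lefts, rights, preds):
        return FragmentTable("c1", np.array(lefts, dtype=np.int64),
                             np.array(rights, dtype=np.int64),
                             np.array(preds, dtype=np.int64))

    def test_min_support_threshold(self):
        ft = self._frag([100, 120], [900, 950], [1500, 1520])
        dels = call_deletions({"a": ft}, 600, 60, min_support=3)
        assert dels.n_calls() == 0

    def test_cluster_emits_intersection_and_length(self):
        ft = self._frag([100, 120, 140], [900, 950, 930],
                        [1600, 1650, 1620])
        dels = call_deletions({"a": ft}, 600, 60, min_support=3)
        assert dels.n_calls() == 1
        d = dels.get("a")[0]
        assert (d.start, d.end) == (140, 900)
        assert d.support == 3
        assert d.est_length == pytest.approx(1620 - 600)

    def test_clean_sample_produces_no_calls(self):
        from sweeptepop.types import DeletionCallSet as DCS
        cfg = small_config(chrom_length=1_000_000, coverage=10.0, seed=44)
        rp = simulate_read_pairs(cfg, DCS(), accessions=["WILD_AI_00"])
        dels = call_deletions(rp, cfg.insert_mean, cfg.insert_sd)
        assert dels.n_calls() == 0

    def test_recovers_simulated_deletion(self):
        cfg = small_config(coverage=10.0, seed=45)
        truth = DeletionCallSet()
        truth.add("DOM_AI_00", Deletion(cfg.chrom, 200_000, 201_000))
        rp = simulate_read_pairs(cfg, truth, accessions=["DOM_AI_00"])
        dels = call_deletions(rp, cfg.insert_mean, cfg.insert_sd)
        assert dels.n_calls() == 1
        d = dels.get("DOM_AI_00")[0]
        assert d.start <= 200_000 and d.end >= 201_000
        mid = (d.start + d.end) / 2
        assert abs(mid - 200_500) <= cfg.insert_sd
        assert abs(d.est_length - 1_000) <= 3 * cfg.insert_sd / np.sqrt(d.support)

    def test_insert_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            call_deletions({}, 600, 0.0)


class TestClustering:
    def test_identical_accessions_merge_first_at_zero(self):
        codes = np.array([[1, 0, 1, 0],
                          [1, 0, 1, 0],
                          [0, 1, 0, 1]], dtype=np.int8)
        pav = PAVMatrix(["a", "b", "c"], [f"t{j}" for j in range(4)], codes)
        linkage, tree = pav_clustering(pav)
        assert linkage[0, 2] == 0.0  # first merge at height 0
        assert sorted(linkage[0, :2]) == [0, 1]  # a with b

    def test_pools_form_separate_top_clusters(self, small_cohort):
        from sweeptepop.popgen import is_clade
        truth = small_cohort.deletion_truth
        _, tree = pav_clustering(truth)
        pools = small_cohort.population_map
        ai = [a for a in truth.accessions if pools[a].endswith("AI")]
        assert is_clade(tree, ai)

    def test_three_accessions_closest_pair_merges_first(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform
        d = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        Z = average(squareform(d, checks=False))
        assert sorted(Z[0, :2]) == [0, 1]
        assert Z[0, 2] == pytest.approx(0.1)
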