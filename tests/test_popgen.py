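"""Diversity/FST oracles, sliding windows, distances and neighbor-joining."""

import numpy as np
import pytest

from conftest import random_matrix, small_config
from sweeptepop.popgen import (
    DistanceMatrix,
    fst,
    gene_scan,
    is_clade,
    neighbor_joining,
    nucleotide_diversity,
    sliding_windows,
    snp_distance_matrix,
    tree_splits,
    window_scan,
)
from sweeptepop.simulate import simulate_snp_genotypes
from sweeptepop.types import POOLS
from test_filtering import matrix_from_codes


# --- independent pair-counting oracles -------------------------------------

def oracle_pi(codes, length):
    """Mean pairwise haplotype differences per bp, by allele-pair counting:
    per site k alt alleles among n -> k(n-k)/C(n,2)."""
    total = 0.0
    for j in range(codes.shape[1]):
        col = codes[:, j]
        geno = col[col >= 0]
        n = 2 * len(geno)
        if n < 2:
            continue
        k = int(geno.sum())
        total += k * (n - k) / (n * (n - 1) / 2)
    return total / length


def oracle_hudson_fst(codes_a, codes_b):
    """Hudson ratio-of-sums by explicit between/within pair counting."""
    num = den = 0.0
    for j in range(codes_a.shape[1]):
        ga = codes_a[:, j][codes_a[:, j] >= 0]
        gb = codes_b[:, j][codes_b[:, j] >= 0]
        na, nb = 2 * len(ga), 2 * len(gb)
        if na < 2 or nb < 2:
            continue
        ka, kb = int(ga.sum()), int(gb.sum())
        hw_a = ka * (na - ka) / (na * (na - 1) / 2)
        hw_b = kb * (nb - kb) / (nb * (nb - 1) / 2)
        hb = (ka * (nb - kb) + kb * (na - ka)) / (na * nb)
        num += 0.5 * (hw_a + hw_b)
        den += hb
    return 1.0 - num / den


def test_pi_single_site_two_hets():
    """One site, 2 diploids both het, in 100 bp: 4 haplotypes with allele
    freq 0.5 -> pi = (4/3)*0.5/100."""
    m = matrix_from_codes(np.array([[1], [1]]))
    pi = nucleotide_diversity(m, ["a0", "a1"], ("chr1", 0, 100))
    assert pi == pytest.approx((4 / 3) * 0.5 / 100, abs=1e-12)
    # brute force: 4 of 6 haplotype pairs differ
    assert pi == pytest.approx(4 / 6 / 100, abs=1e-12)


def test_pi_monomorphic_interval_is_zero():
    m = matrix_from_codes(np.zeros((6, 10), dtype=np.int8))
    assert nucleotide_diversity(m, m.accessions, ("chr1", 0, 50)) == 0.0


def test_pi_empty_subset_is_hard_error():
    m = matrix_from_codes(np.zeros((4, 5), dtype=np.int8))
    with pytest.raises(ValueError):
        nucleotide_diversity(m, [], ("chr1", 0, 10))


def test_pi_matches_bruteforce_oracle_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(50):
        m = random_matrix(rng, n_acc=int(rng.integers(4, 11)),
                          n_sites=int(rng.integers(5, 51)))
        iv = ("chr1", 0, 1000)
        pi = nucleotide_diversity(m, m.accessions, iv)
        assert pi == pytest.approx(oracle_pi(m.genotypes, 1000), abs=1e-12)


def test_pi_invariant_to_allele_relabeling_and_order():
    rng = np.random.default_rng(3)
    m = random_matrix(rng, n_acc=8, n_sites=30, missing_rate=0.1)
    iv = ("chr1", 0, 500)
    pi = nucleotide_diversity(m, m.accessions, iv)
    flipped = m.genotypes.copy()
    flipped[flipped >= 0] = 2 - flipped[flipped >= 0]
    m_flip = matrix_from_codes(flipped)
    assert nucleotide_diversity(m_flip, m_flip.accessions, iv) == \
        pytest.approx(pi, abs=1e-15)
    perm = rng.permutation(m.n_accessions)
    m_perm = matrix_from_codes(m.genotypes[perm])
    assert nucleotide_diversity(m_perm, m_perm.accessions, iv) == \
        pytest.approx(pi, abs=1e-15)


def test_pi_additive_over_partition():
    rng = np.random.default_rng(4)
    m = random_matrix(rng, n_acc=6, n_sites=40)
    lo, mid, hi = 0, 200, 401
    full = nucleotide_diversity(m, m.accessions, ("chr1", lo, hi))
    left = nucleotide_diversity(m, m.accessions, ("chr1", lo, mid))
    right = nucleotide_diversity(m, m.accessions, ("chr1", mid, hi))
    assert full * (hi - lo) == pytest.approx(
        left * (mid - lo) + right * (hi - mid), abs=1e-12)


class TestFst:
    def test_fixed_difference_gives_one(self):
        codes = np.array([[0, 0, 0, 2, 2, 2]]).T.reshape(6, 1)
        m = matrix_from_codes(codes)
        assert fst(m, ["a0", "a1", "a2"], ["a3", "a4", "a5"]) == \
            pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, n_acc=10, n_sites=50, missing_rate=0.1)
        a = [f"acc{i}" for i in range(5)]
        b = [f"acc{i}" for i in range(5, 10)]
        assert fst(m, a, b) == pytest.approx(fst(m, b, a), abs=1e-15)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            m = random_matrix(rng, n_acc=int(rng.integers(6, 11)),
                              n_sites=int(rng.integers(10, 51)))
            half = m.n_accessions // 2
            a = m.accessions[:half]
            b = m.accessions[half:]
            got = fst(m, a, b)
            want = oracle_hudson_fst(m.genotypes[:half], m.genotypes[half:])
            assert got == pytest.approx(want, abs=1e-12)

    def test_random_split_of_one_population_near_zero(self):
        cfg = small_config(n_per_pop=15, n_snps=4000, pool_divergence_F=0.0,
                           bottleneck_F=0.0, n_sweeps=0, seed=31)
        m = simulate_snp_genotypes(cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.accessions)
        assert abs(fst(m, list(perm[:30]), list(perm[30:]))) < 0.05


class TestSlidingWindows:
    def test_closed_form_count(self):
        wins = list(sliding_windows({"c": 100_000}, 50_000, 5_000))
        assert len(wins) == 11
        assert wins[0] == ("c", 0, 50_000)
        assert wins[-1] == ("c", 50_000, 100_000)

    def test_chromosome_shorter_than_window(self):
        assert list(sliding_windows({"c": 49_999}, 50_000, 5_000)) == []

    def test_window_equals_step_tiles(self):
        wins = list(sliding_windows({"c": 104_000}, 10_000, 10_000))
        assert len(wins) == 10
        assert all(w[2] - w[1] == 10_000 for w in wins)

    def test_trailing_partial_flag(self):
        wins = list(sliding_windows({"c": 104_000}, 10_000, 10_000,
                                    include_trailing=True))
        assert wins[-1] == ("c", 100_000, 104_000)

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            list(sliding_windows({"c": 100}, 10, 20))


def test_window_scan_ratio_and_gene_units():
    cfg = small_config(seed=32)
    m = simulate_snp_genotypes(cfg)
    wins = list(sliding_windows({cfg.chrom: cfg.chrom_length}, 50_000, 5_000))
    stats = window_scan(m, "AI", wins)
    assert len(stats) == len(wins)
    ok = np.isfinite(stats.pi_reduction)
    np.testing.assert_allclose(
        stats.pi_reduction[ok],
        (stats.pi_wild[ok] - stats.pi_dom[ok]) / stats.pi_wild[ok])
    genes = cfg.gene_models()
    gstats = gene_scan(m, "AI", genes)
    np.testing.assert_allclose(gstats.diff_per_kbp_dom,
                               1000 * gstats.pi_dom)


def test_sweep_windows_have_higher_pi_reduction():
    """Planted sweeps elevate the diversity-reduction ratio relative to
    neutral windows (one-sided rank test)."""
    from scipy.stats import mannwhitneyu
    cfg = small_config(n_per_pop=10, n_snps=3000, seed=33,
                       sweep_pool_assignment="both")
    m = simulate_snp_genotypes(cfg)
    wins = list(sliding_windows({cfg.chrom: cfg.chrom_length}, 50_000, 5_000))
    stats = window_scan(m, "MI", wins)
    regions = cfg.sweep_regions()
    in_sweep = stats.apply(
        lambda r: any(r.start < s.end and s.start < r.end for s in regions),
        axis=1)
    sub = stats[np.isfinite(stats.pi_reduction)]
    p = mannwhitneyu(sub.pi_reduction[in_sweep[sub.index]],
                     sub.pi_reduction[~in_sweep[sub.index]],
                     alternative="greater").pvalue
    assert p < 0.01


# --- distances and NJ -------------------------------------------------------

def _canon_splits(splits, all_leaves, ref):
    out = set()
    for s in splits:
        side = s if ref not in s else frozenset(all_leaves) - s
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        """Additive distances on ((A:1,B:2):1,(C:3,D:4)) are recovered with
        exact branch lengths."""
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert is_clade(tree, ["A", "B"])
        assert tree.newick() == "(C:3,D:4,(A:1,B:2):1);"

    def test_identical_accessions_zero_cherry(self):
        labels = ["x", "y", "z"]
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lens = {child.label: bl for child, bl in tree.children}
        assert lens["x"] == 0 and lens["y"] == 0
        assert lens["z"] == 1

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_recovers_all_five_taxon_topologies(self):
        """NJ on exactly additive distances reconstructs the generating
        topology and branch lengths, for all 15 labeled 5-taxon trees."""
        import itertools
        labels = list("ABCDE")
        rng = np.random.default_rng(8)
        # every unrooted binary 5-taxon topology = an unordered choice of
        # two disjoint cherries; the fifth leaf hangs off the central node
        seen = set()
        for cherry1 in itertools.combinations(range(5), 2):
            rest = [i for i in range(5) if i not in cherry1]
            for cherry2 in itertools.combinations(rest, 2):
                key = frozenset([cherry1, cherry2])
                if key in seen:
                    continue
                seen.add(key)
                mid = next(i for i in rest if i not in cherry2)
                # internal path u --e1-- c --e2-- v; cherry1 at u,
                # mid at c, cherry2 at v
                stem = rng.uniform(0.5, 3.0, size=5)
                e1, e2 = rng.uniform(0.5, 3.0, size=2)
                attach = {cherry1[0]: 0.0, cherry1[1]: 0.0, mid: e1,
                          cherry2[0]: e1 + e2, cherry2[1]: e1 + e2}
                d = np.zeros((5, 5))
                for i in range(5):
                    for j in range(i + 1, 5):
                        d[i, j] = d[j, i] = (abs(attach[i] - attach[j])
                                             + stem[i] + stem[j])
                tree = neighbor_joining(DistanceMatrix(labels, d))
                assert is_clade(tree, [labels[c] for c in cherry1]), key
                assert is_clade(tree, [labels[c] for c in cherry2]), key
        assert len(seen) == 15

    def test_matches_scikit_bio_on_random_distances(self):
        """Topology agrees with scikit-bio's NJ on generic (tie-free)
        random distance matrices."""
        import skbio
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(5):
            x = rng.uniform(0.5, 2.0, size=(8, 8))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0)
            mine = neighbor_joining(DistanceMatrix(labels, d))
            ref = skbio_nj(skbio.DistanceMatrix(d, ids=labels))
            ref_splits = {frozenset(t.name for t in n.tips())
                          for n in ref.non_tips(include_self=False)}
            all_leaves = frozenset(labels)
            assert _canon_splits(tree_splits(mine), all_leaves, "t0") == \
                _canon_splits(ref_splits, all_leaves, "t0")


def test_snp_distance_and_pool_clades(small_cohort):
    """Distances are IBS-based and the NJ tree separates the gene pools."""
    m = small_cohort.genotypes
    dm = snp_distance_matrix(m)
    assert np.allclose(dm.values, dm.values.T)
    i, j = 0, 1
    both = (m.genotypes[i] >= 0) & (m.genotypes[j] >= 0)
    want = np.mean(np.abs(m.genotypes[i, both].astype(int)
                          - m.genotypes[j, both].astype(int)) / 2.0)
    assert dm.values[i, j] == pytest.approx(want, abs=1e-12)
    tree = neighbor_joining(dm)
    ai = [a for a in m.accessions if m.population_map[a] in POOLS["AI"]]
    assert is_clade(tree, ai)
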