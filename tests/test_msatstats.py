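"""Microsatellite statistics: heterozygosity, HWE, rarefaction,
Weir-Cockerham theta, Jost's D, shared-allele NJ tree."""

import numpy as np
import pandas as pd
import pytest

from seapan import (
    GenotypeDataset,
    allelic_richness,
    het_stats,
    hwe_permutation_test,
    jost_d,
    msat_summary_table,
    pairwise_fst_jostd,
    read_genotypes,
    shared_allele_distance,
    shared_allele_nj,
    unique_alleles,
    weir_cockerham_theta,
    write_genotypes,
)
from seapan.msatstats import GenotypeDataError


def make_gds(genos_by_pop, n_loci=None):
    """genos_by_pop: {pop: [[(a1,b1),(a2,b2),...], ...]} per individual."""
    ids, pops, rows = [], [], []
    for pop, indivs in genos_by_pop.items():
        for k, loci in enumerate(indivs):
            ids.append(f"{pop}_{k}")
            pops.append(pop)
            rows.append(loci)
    arr = np.array(rows)
    return GenotypeDataset(
        ids=ids, pops=pops, alleles=arr,
        locus_names=[f"L{i+1}" for i in range(arr.shape[1])])


def wc_theta_oracle(ds, pops):
    """Independent Weir & Cockerham (1984) theta, written directly from
    the defining per-allele sums with explicit loops."""
    num = den = 0.0
    r = len(pops)
    for l in range(ds.n_loci):
        blocks = []
        for pop in pops:
            block = ds.alleles[ds.pop_mask(pop), l, :]
            blocks.append(block[block[:, 0] > 0])
        ns = [b.shape[0] for b in blocks]
        if any(n == 0 for n in ns):
            continue
        nbar = sum(ns) / r
        nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
        alleles = sorted({int(a) for b in blocks for a in b.ravel()})
        for al in alleles:
            p = [np.mean(b.ravel() == al) for b in blocks]
            h = [np.mean((b[:, 0] != b[:, 1])
                         & ((b[:, 0] == al) | (b[:, 1] == al)))
                 for b in blocks]
            pbar = sum(n * pi for n, pi in zip(ns, p)) / sum(ns)
            s2 = sum(n * (pi - pbar) ** 2 for n, pi in zip(ns, p)) \
                / ((r - 1) * nbar)
            hbar = sum(n * hi for n, hi in zip(ns, h)) / sum(ns)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                     - (r - 1) / r * s2 - hbar / 4)
                               / (nbar - 1))
            b_ = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                        - (r - 1) / r * s2
                                        - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b_ + c
    return num / den if den else 0.0


class TestIO:
    def test_round_trip_and_missingness_flags(self, tmp_path):
        ds = make_gds({"A": [[(100, 102)], [(0, 0)], [(100, 100)],
                             [(102, 102)], [(100, 102)]]})
        path = tmp_path / "g.csv"
        write_genotypes(ds, path)
        back, flagged = read_genotypes(path, missing_threshold=0.05)
        assert np.array_equal(back.alleles, ds.alleles)
        assert flagged == ["L1"]  # 20% missing > 5% threshold
        _, not_flagged = read_genotypes(path, missing_threshold=0.25)
        assert not_flagged == []

    def test_odd_allele_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("pop_id,indiv_id,L1_1,L1_2,L2_1\nA,i1,1,2,3\n")
        with pytest.raises(GenotypeDataError, match="odd"):
            read_genotypes(path)

    def test_non_integer_allele_names_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("pop_id,indiv_id,L1_1,L1_2\nA,i1,ABC,2\n")
        with pytest.raises(GenotypeDataError, match="L1_1"):
            read_genotypes(path)

    def test_half_missing_genotype_rejected(self):
        with pytest.raises(GenotypeDataError, match="missing-pair"):
            make_gds({"A": [[(100, 0)]]})


class TestHetStats:
    def test_unbiased_he_hand_example(self):
        # (A/A), (A/B): Ho = 0.5; He = (4/3)(1 - 10/16) = 0.5; Fis = 0
        ds = make_gds({"P": [[(1, 1)], [(1, 2)]]})
        he, ho, fis = het_stats(ds, "P")
        assert he == pytest.approx(0.5)
        assert ho == pytest.approx(0.5)
        assert fis == pytest.approx(0.0)

    def test_monomorphic_convention(self):
        ds = make_gds({"P": [[(5, 5)], [(5, 5)]]})
        assert het_stats(ds, "P") == (0.0, 0.0, 0.0)

    def test_heterozygote_excess_gives_negative_fis(self):
        ds = make_gds({"P": [[(1, 2)]] * 10})
        he, ho, fis = het_stats(ds, "P")
        assert ho == 1.0
        assert fis < 0


class TestHWE:
    def test_monomorphic_p_is_one(self):
        ds = make_gds({"P": [[(7, 7)]] * 6})
        assert hwe_permutation_test(ds, "P", n_perm=99, seed=0) == 1.0

    def test_clonal_heterozygotes_are_extreme(self):
        ds = make_gds({"P": [[(1, 2)]] * 12})
        p = hwe_permutation_test(ds, "P", n_perm=499, seed=0)
        assert p < 0.05

    def test_calibration_under_random_mating(self):
        """Alleles paired at random should be rejected at roughly the
        nominal 5% rate."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_trials = 40
        for t in range(n_trials):
            alleles = rng.integers(1, 6, size=(30, 2, 2))
            ds = GenotypeDataset(
                ids=[f"i{k}" for k in range(30)], pops=["P"] * 30,
                alleles=alleles, locus_names=["L1", "L2"])
            p = hwe_permutation_test(ds, "P", n_perm=199, seed=t)
            rejections += p < 0.05
        assert rejections / n_trials <= 0.15


class TestAllelicRichness:
    def test_hypergeometric_hand_example(self):
        # copy counts (3, 1), N = 4, g = 2 -> 1 + 0.5 = 1.5
        ds = make_gds({"P": [[(1, 1)], [(1, 2)]]})
        assert allelic_richness(ds, "P", 2) == pytest.approx(1.5)

    def test_full_depth_recovers_observed_count(self):
        ds = make_gds({"P": [[(1, 2)], [(3, 1)], [(1, 1)]]})
        assert allelic_richness(ds, "P", 6) == pytest.approx(3.0)

    def test_monomorphic_locus_is_one(self):
        ds = make_gds({"P": [[(9, 9)], [(9, 9)]]})
        assert allelic_richness(ds, "P", 2) == pytest.approx(1.0)

    def test_g_below_two_rejected(self):
        ds = make_gds({"P": [[(1, 2)]]})
        with pytest.raises(GenotypeDataError):
            allelic_richness(ds, "P", 1)


class TestDifferentiation:
    def test_fixed_alleles_give_theta_and_d_of_one(self):
        ds = make_gds({"X": [[(1, 1)]] * 4, "Y": [[(2, 2)]] * 4})
        assert weir_cockerham_theta(ds) == pytest.approx(1.0)
        assert jost_d(ds) == pytest.approx(1.0)

    def test_identical_frequencies_give_near_zero(self):
        genos = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]] * 12
        ds = make_gds({"X": genos, "Y": genos})
        assert abs(weir_cockerham_theta(ds)) < 0.02
        assert abs(jost_d(ds)) < 0.05

    def test_theta_matches_independent_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(8):
            genos = {}
            for pop in ("X", "Y"):
                genos[pop] = [
                    [tuple(rng.integers(1, 5, 2)) for _ in range(2)]
                    for _ in range(rng.integers(5, 12))
                ]
            ds = make_gds(genos)
            assert weir_cockerham_theta(ds) == pytest.approx(
                wc_theta_oracle(ds, ["X", "Y"]), abs=1e-12)

    def test_pairwise_matrices_with_bootstrap_cis(self, panmictic_data):
        _, gen = panmictic_data
        theta, d = pairwise_fst_jostd(gen, n_boot=100, seed=0)
        iu = np.triu_indices(len(gen.pop_names), 1)
        assert np.isfinite(theta.est.values[iu]).all()
        assert (theta.lo.values[iu] <= theta.hi.values[iu]).all()
        # panmictic: CIs span 0 (the non-significance criterion)
        assert (theta.lo.values[iu] < 0.02).all()
        # reproducible under the same seed
        theta2, _ = pairwise_fst_jostd(gen, n_boot=100, seed=0)
        assert theta.lo.equals(theta2.lo)

    def test_locus_and_individual_order_invariance(self, panmictic_data):
        _, gen = panmictic_data
        t1 = weir_cockerham_theta(gen)
        perm = np.random.default_rng(0).permutation(gen.n)
        shuffled = GenotypeDataset(
            ids=[gen.ids[i] for i in perm],
            pops=[gen.pops[i] for i in perm],
            alleles=gen.alleles[perm][:, ::-1, :],
            locus_names=gen.locus_names[::-1])
        assert weir_cockerham_theta(shuffled) == pytest.approx(t1)
        assert jost_d(shuffled) == pytest.approx(jost_d(gen))


class TestSharedAlleleTree:
    def test_distance_zero_iff_identical_frequencies(self):
        genos = [[(1, 2), (3, 3)], [(1, 1), (3, 4)]]
        ds = make_gds({"A": genos, "B": genos, "C": [[(5, 5), (6, 6)]] * 2})
        dm = shared_allele_distance(ds)
        assert dm.loc["A", "B"] == pytest.approx(0.0)
        assert dm.loc["A", "C"] == pytest.approx(1.0)

    def test_nj_groups_similar_populations(self):
        ds = make_gds({
            "A": [[(1, 1), (3, 3)]] * 4,
            "B": [[(1, 1), (3, 3)], [(1, 1), (3, 3)], [(1, 1), (3, 3)],
                  [(1, 2), (3, 4)]],
            "C": [[(7, 7), (9, 9)]] * 4,
            "D": [[(7, 7), (9, 9)], [(7, 7), (9, 9)], [(7, 7), (9, 9)],
                  [(7, 8), (9, 8)]],
        })
        newick = shared_allele_nj(ds)
        from skbio import TreeNode
        from io import StringIO
        tree = TreeNode.read(StringIO(newick))
        # A-B and C-D each form a cherry: tip-to-tip distance within a pair
        # is far smaller than across pairs
        d_ab = tree.find("A").distance(tree.find("B"))
        d_ac = tree.find("A").distance(tree.find("C"))
        assert d_ab < d_ac

    def test_identical_populations_star_tree(self):
        genos = [[(1, 2)], [(1, 1)]]
        ds = make_gds({"A": genos, "B": genos, "C": genos})
        newick = shared_allele_nj(ds)
        from skbio import TreeNode
        from io import StringIO
        tree = TreeNode.read(StringIO(newick))
        assert tree.find("A").distance(tree.find("B")) == pytest.approx(
            0.0, abs=1e-12)

    def test_fewer_than_three_populations_rejected(self):
        ds = make_gds({"A": [[(1, 1)]], "B": [[(2, 2)]]})
        with pytest.raises(GenotypeDataError):
            shared_allele_nj(ds)


class TestRarefactionProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.integers(1, 8), min_size=1, max_size=5))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_rarefied_richness_monotone_in_depth(self, counts):
        """A(g) is nondecreasing in g and bounded by the allele count."""
        from seapan.msatstats import _rarefied_locus
        counts = np.array(counts)
        N = int(counts.sum())
        if N < 3:
            return
        values = [_rarefied_locus(counts, g) for g in range(2, N + 1)]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(len(counts))
        assert values[0] >= 1.0


def test_unique_alleles_counting():
    ds = make_gds({"A": [[(1, 2)], [(2, 3)]], "B": [[(2, 2)], [(4, 4)]]})
    ua = unique_alleles(ds)
    assert ua["A"] == 2  # alleles 1 and 3
    assert ua["B"] == 1  # allele 4


def test_summary_table_columns(panmictic_data):
    _, gen = panmictic_data
    tab = msat_summary_table(gen, rarefy_to=(4,), n_perm=50, seed=0)
    assert {"pop_id", "N", "He", "Ho", "Fis", "hwe_p", "UA",
            "A_rarefied_4"} <= set(tab.columns)
    assert tab.He.between(0, 1).all()
    assert tab.Ho.between(0, 1).all()
    assert (tab.A_rarefied_4 <= tab.A_mean + 1e-9).all()
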