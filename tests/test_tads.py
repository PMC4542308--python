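"""Directionality index, TAD calling, insulation comparison, conservation."""

import numpy as np
import pytest

from chromoci import (
    ContactMap,
    GenomeAssembly,
    IntervalSet,
    bin_genome,
    boundary_conservation,
    call_tads,
    compare_tads,
    tad_feature_enrichment,
)
from chromoci.tads import (
    directionality_index,
    intra_cross_counts,
    tad_boundaries,
)
from chromoci._stats import fisher_exact_2x2
from conftest import random_map
from _oracles import fisher_p_oracle


def small_bins(n=20, bin_size=200_000):
    return bin_genome(GenomeAssembly((("chr1", n * bin_size),)), bin_size)


class TestDirectionalityIndex:
    def test_symmetric_bin_is_zero(self):
        bins = small_bins()
        m = ContactMap(bins, [3, 5], [5, 7], [50, 50])  # A = B = 50 at bin 5
        di = directionality_index(m, span_bp=600_000)
        assert di.upstream[5] == 50 and di.downstream[5] == 50
        assert di.di[5] == 0.0

    def test_hand_arithmetic(self):
        # A=10 upstream, B=30 downstream: E=20, DI = +(100/20 + 100/20) = +10
        bins = small_bins()
        m = ContactMap(bins, [3, 5], [5, 8], [10, 30])
        di = directionality_index(m, span_bp=600_000)
        assert di.di[5] == pytest.approx(10.0)
        # sign flips when the bias flips
        m2 = ContactMap(bins, [2, 5], [5, 7], [30, 10])
        assert directionality_index(m2, span_bp=600_000).di[5] == pytest.approx(-10.0)

    def test_antisymmetric_under_reversal(self, rng):
        bins = small_bins(12)
        m = random_map(bins, rng)
        di = directionality_index(m, span_bp=800_000)
        n = bins.n_bins
        rev = ContactMap(bins, n - 1 - m.bin2, n - 1 - m.bin1, m.count)
        di_rev = directionality_index(rev, span_bp=800_000)
        np.testing.assert_allclose(di_rev.di, -di.di[::-1], atol=1e-9)

    def test_span_too_small(self):
        with pytest.raises(ValueError):
            directionality_index(ContactMap(small_bins(), [0], [1], [1]), span_bp=200_000)


class TestCallTads:
    def test_uniform_map_has_no_boundaries(self):
        bins = small_bins(30)
        iu, ju = np.triu_indices(bins.n_bins)
        m = ContactMap(bins, iu, ju, np.full(iu.size, 5))
        tads = call_tads(directionality_index(m))
        assert list(tads.frame["label"]) == ["unsegmented"]

    def test_planted_boundary_recovery(self, effect_sim):
        cfg, genome, maps, truth = effect_sim
        called = call_tads(directionality_index(maps["growing"]))
        planted = tad_boundaries(genome.tads)
        got = tad_boundaries(called)
        tol = genome.bins.bin_size
        hits = total = 0
        for chrom, edges in planted.items():
            other = got.get(chrom, np.empty(0))
            for e in edges:
                total += 1
                if other.size and np.abs(other - e).min() <= tol:
                    hits += 1
        assert hits / total >= 0.8

    def test_deterministic(self, effect_sim):
        cfg, genome, maps, truth = effect_sim
        di = directionality_index(maps["growing"])
        a = call_tads(di)
        b = call_tads(di)
        assert a.frame.equals(b.frame)


class TestIntraCross:
    def test_brute_force(self, rng):
        bins = small_bins(10)
        for _ in range(5):
            m = random_map(bins, rng)
            start, end, flank = 400_000, 1_200_000, 400_000
            intra, cross = intra_cross_counts(m, "chr1", start, end, flank)
            mid = bins.midpoint
            exp_intra = exp_cross = 0
            for i, j, c in zip(m.bin1, m.bin2, m.count):
                pi = start <= mid[i] < end
                pj = start <= mid[j] < end
                fi = (start - flank <= mid[i] < start) or (end <= mid[i] < end + flank)
                fj = (start - flank <= mid[j] < start) or (end <= mid[j] < end + flank)
                if pi and pj:
                    exp_intra += c
                elif (pi and fj) or (pj and fi):
                    exp_cross += c
            assert (intra, cross) == (exp_intra, exp_cross)

    def test_no_crossing_contacts(self):
        bins = small_bins(10)
        m = ContactMap(bins, [2, 3], [3, 4], [5, 5])
        intra, cross = intra_cross_counts(m, "chr1", 400_000, 1_000_000, 400_000)
        assert intra == 10 and cross == 0

    def test_linearity_in_depth(self, rng):
        bins = small_bins(10)
        m = random_map(bins, rng)
        double = ContactMap(bins, m.bin1, m.bin2, m.count * 2)
        a = intra_cross_counts(m, "chr1", 400_000, 1_200_000, 400_000)
        b = intra_cross_counts(double, "chr1", 400_000, 1_200_000, 400_000)
        assert b == (2 * a[0], 2 * a[1])


class TestFisher:
    def test_matches_exhaustive_oracle_small_margins(self):
        for n1 in range(0, 13):
            for n2 in range(0, 13):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        table = [[a, n1 - a], [c, n2 - c]]
                        _, p = fisher_exact_2x2(table)
                        assert p == pytest.approx(
                            fisher_p_oracle(a, n1 - a, c, n2 - c), abs=1e-9
                        ), table

    def test_matches_scipy_reference(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        for _ in range(300):
            a, b, c, d = rng.integers(0, 200, 4)
            table = [[a, b], [c, d]]
            odds, p = fisher_exact_2x2(table)
            ref_odds, ref_p = scipy_fisher(table)
            assert p == pytest.approx(ref_p, abs=1e-9), table
            if np.isfinite(ref_odds) and b * c > 0:
                assert odds == pytest.approx(ref_odds)

    def test_symmetry_invariance(self):
        base = [[9, 1], [3, 7]]
        _, p = fisher_exact_2x2(base)
        for t in ([[1, 9], [7, 3]], [[3, 7], [9, 1]], [[9, 3], [1, 7]]):
            assert fisher_exact_2x2(t)[1] == pytest.approx(p, abs=1e-12)


class TestCompareTads:
    def _two_maps(self, intra_a, cross_a, intra_b, cross_b):
        """Build two single-TAD maps with specified intra/cross counts."""
        bins = small_bins(10)
        tad = IntervalSet.from_records([("chr1", 400_000, 1_200_000, "")])

        def build(intra, cross):
            # intra at (3,4); cross at (1,3): bin 1 is flank, bin 3 inside
            return ContactMap(bins, [3, 1], [4, 3], [intra, cross])

        return tad, build(intra_a, cross_a), build(intra_b, cross_b)

    def test_known_opening_table(self):
        tad, ma, mb = self._two_maps(900, 100, 700, 300)
        out = compare_tads(tad, ma, mb, flank_bp=400_000)
        row = out.iloc[0]
        odds, p = fisher_exact_2x2([[300, 700], [100, 900]])
        assert row["odds_ratio"] == pytest.approx(odds)
        assert row["p"] == pytest.approx(p, abs=1e-12)
        assert p == pytest.approx(fisher_p_oracle(300, 700, 100, 900), abs=1e-9)
        assert row["label"] == "opening"
        assert row["ratio_a"] == pytest.approx(0.1)
        assert row["ratio_b"] == pytest.approx(0.3)

    def test_identical_maps_stable(self):
        tad, ma, _ = self._two_maps(900, 100, 900, 100)
        out = compare_tads(tad, ma, ma)
        assert (out["label"] == "stable").all()

    def test_degenerate_table_flagged(self):
        bins = small_bins(10)
        tad = IntervalSet.from_records([("chr1", 400_000, 1_200_000, "")])
        ma = ContactMap(bins, [3], [4], [10])   # no cross contacts in either map
        out = compare_tads(tad, ma, ma)
        assert out.iloc[0]["flagged"]
        assert out.iloc[0]["p"] == 1.0
        assert out.iloc[0]["label"] == "stable"

    def test_order_invariance(self, effect_sim):
        cfg, genome, maps, truth = effect_sim
        tads = genome.tads
        shuffled = IntervalSet(
            "TADs", tads.frame.sample(frac=1, random_state=0)
        )
        a = compare_tads(tads, maps["growing"], maps["senescent"])
        b = compare_tads(shuffled, maps["growing"], maps["senescent"])
        merged = a.merge(b, on=["chrom", "start", "end"], suffixes=("_a", "_b"))
        assert len(merged) == len(a)
        assert (merged["label_a"] == merged["label_b"]).all()

    def test_planted_opening_sensitivity(self, effect_sim):
        cfg, genome, maps, truth = effect_sim
        out = compare_tads(genome.tads, maps["growing"], maps["senescent"])
        planted = truth.per_tad["opening"].to_numpy()
        called = (out["label"] == "opening").to_numpy()
        sensitivity = (called & planted).sum() / planted.sum()
        assert sensitivity >= 0.9


class TestBoundaryConservation:
    def test_identical_sets(self):
        tads = IntervalSet.from_records(
            [("chr1", 0, 1_000_000, ""), ("chr1", 1_000_000, 2_000_000, "")]
        )
        out = boundary_conservation(tads, tads, bin_size=200_000)
        assert out == {"a_in_b": 1.0, "b_in_a": 1.0}

    def test_disjoint_beyond_tolerance(self):
        a = IntervalSet.from_records([("chr1", 0, 1_000_000, "")])
        b = IntervalSet.from_records([("chr1", 2_000_000, 3_000_000, "")])
        out = boundary_conservation(a, b, bin_size=200_000, tol_bins=1)
        assert out["a_in_b"] == 0.0

    def test_same_layout_two_conditions(self, null_sim):
        # replicate conditions sampled from one TAD layout agree on boundaries
        cfg, genome, maps, truth = null_sim
        a = call_tads(directionality_index(maps["growing"]))
        b = call_tads(directionality_index(maps["senescent"]))
        out = boundary_conservation(a, b, genome.bins.bin_size)
        assert out["a_in_b"] >= 0.8
        assert out["b_in_a"] >= 0.8


class TestTadFeatureEnrichment:
    def test_all_tads_vs_covering_feature(self, effect_sim):
        cfg, genome, maps, truth = effect_sim
        whole = IntervalSet.from_records(
            [(c, 0, l, "") for c, l in genome.assembly.chromosomes]
        )
        out = tad_feature_enrichment(genome.tads, {"genome": whole}, genome.assembly)
        assert abs(out.iloc[0]["log2_obs_exp"]) < 1e-4

    def test_opening_tads_enriched_in_target_feature(self, effect_sim):
        cfg, genome, maps, truth = effect_sim
        table = compare_tads(genome.tads, maps["growing"], maps["senescent"])
        sel = genome.tads.frame[ (table["label"] == "opening").to_numpy() ]
        selection = IntervalSet("opening", sel)
        out = tad_feature_enrichment(
            selection, {"LADs": genome.lads}, genome.assembly
        )
        assert out.iloc[0]["log2_obs_exp"] > 0

    def test_empty_selection_flagged(self, effect_sim):
        cfg, genome, maps, truth = effect_sim
        out = tad_feature_enrichment(
            IntervalSet.from_records([]), {"LADs": genome.lads}, genome.assembly
        )
        assert out.iloc[0]["flagged"]
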