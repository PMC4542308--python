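"""OCI counting, normalization chain, deltas, stratification, meta-profiles."""

import numpy as np
import pandas as pd
import pytest

from chromoci import (
    ContactMap,
    GenomeAssembly,
    IntervalSet,
    OCIParams,
    ScalarTrack,
    bin_genome,
    compute_oci,
    delta_oci,
    meta_profile,
    stratify_oci,
)
from chromoci.genome import FeatureClassing
from chromoci.oci import count_control, count_local, window_table
from conftest import random_map
from _oracles import oci_oracle

LOOSE = OCIParams(min_informative=0, pseudocount=1.0)


class TestCounting:
    def test_local_boundary_record_excluded(self, tiny_bins):
        # window = 2 bins; record (1,5) leaves the window
        windows, win_of = window_table(tiny_bins, 400_000)
        m = ContactMap(tiny_bins, [0, 0, 1], [0, 1, 5], [2, 3, 7])
        local = count_local(m, win_of, windows.n_bins)
        assert local[0] == 5
        assert local.sum() == 5

    def test_trans_control_double_anchors(self, tiny_bins):
        windows, win_of = window_table(tiny_bins, 200_000)
        m = ContactMap(tiny_bins, [0], [7], [5])  # chr1 bin 0 x chr2 bin 1
        ctrl = count_control(m, win_of, windows.n_bins, OCIParams())
        assert ctrl[0] == 5 and ctrl[7] == 5
        assert ctrl.sum() == 10

    def test_cis_distal_threshold(self):
        asm = GenomeAssembly((("chr1", 40_000_000),))
        bins = bin_genome(asm, 200_000)
        windows, win_of = window_table(bins, 200_000)
        params = OCIParams(control_mode="cis-distal")
        below = ContactMap(bins, [0], [95], [3])   # 19 Mb separation
        above = ContactMap(bins, [0], [105], [3])  # 21 Mb separation
        assert count_control(below, win_of, windows.n_bins, params).sum() == 0
        assert count_control(above, win_of, windows.n_bins, params).sum() == 6

    @pytest.mark.parametrize("mode", ["trans", "cis-distal"])
    def test_counts_match_brute_force(self, tiny_bins, rng, mode):
        params = OCIParams(
            control_mode=mode, cis_threshold_bp=300_000, min_informative=0
        )
        for _ in range(5):
            m = random_map(tiny_bins, rng)
            windows, win_of = window_table(tiny_bins, 200_000)
            got_l = count_local(m, win_of, windows.n_bins)
            got_c = count_control(m, win_of, windows.n_bins, params)
            exp = oci_oracle(m.dense(), tiny_bins, params)
            assert np.array_equal(got_l, exp["local"])
            assert np.array_equal(got_c, exp["control"])


class TestComputeOci:
    def test_hand_computed_six_window_chain(self):
        """Six windows on one chromosome vs a spreadsheet-style oracle."""
        asm = GenomeAssembly((("chr1", 1_200_000), ("chr2", 400_000)))
        bins = bin_genome(asm, 200_000)
        local = [8, 2, 4, 16, 1, 9]
        control = [4, 8, 4, 4, 15, 3]
        records = []
        for w, c in enumerate(local):
            records.append((w, w, c))
        # put each window's control count on a trans record to chr2 bin 6
        for w, c in enumerate(control):
            records.append((w, 6, c))
        i, j, c = zip(*records)
        m = ContactMap(bins, i, j, c)
        params = OCIParams(min_informative=0, smoothing_span_bp=600_000)
        track = compute_oci(m, params)
        raw = np.log2((np.array(control) + 1) / (np.array(local) + 1))
        centered = raw - np.median(raw)
        smoothed = [
            np.mean(centered[max(0, k - 1): k + 2]) for k in range(6)
        ]  # 3-window centered mean with partial ends
        assert np.allclose(track.raw[:6], raw)
        assert np.allclose(track.centered[:6], centered)
        assert np.allclose(track.smoothed[:6], smoothed)

    def test_symmetric_uniform_chromosome_is_zero(self):
        asm = GenomeAssembly((("chr1", 1_200_000), ("chr2", 1_200_000)))
        bins = bin_genome(asm, 200_000)
        # every window: local == trans control
        records = [(w, w, 6) for w in range(12)]
        for w in range(6):
            records.append((w, 6 + ((w + 1) % 6), 3))
            records.append((w, 6 + ((w + 2) % 6), 3))
        i, j, c = zip(*records)
        track = compute_oci(ContactMap(bins, i, j, c), OCIParams(min_informative=0))
        assert np.allclose(track.smoothed, 0.0)

    def test_oracle_equivalence_random_maps(self, rng):
        asm = GenomeAssembly((("chr1", 2_000_000), ("chr2", 1_600_000)))
        bins = bin_genome(asm, 200_000)
        params = OCIParams(
            min_informative=5, smoothing_span_bp=1_000_000,
        )
        for _ in range(10):
            m = random_map(bins, rng, density=0.7)
            track = compute_oci(m, params)
            exp = oci_oracle(m.dense(), bins, params)
            assert np.array_equal(track.mask, exp["mask"])
            for field in ("raw", "centered", "smoothed"):
                np.testing.assert_allclose(
                    getattr(track, field), exp[field], atol=1e-9, equal_nan=True
                )

    def test_empty_map_and_all_masked_errors(self, tiny_bins):
        with pytest.raises(ValueError):
            compute_oci(ContactMap(tiny_bins, [], [], []))
        sparse = ContactMap(tiny_bins, [0, 6], [1, 7], [1, 50])
        with pytest.raises(ValueError):  # chr1 windows all below min_informative
            compute_oci(sparse, OCIParams(min_informative=10))

    def test_local_loss_raises_oci(self, effect_sim):
        """Halving local contacts in target regions raises OCI there."""
        cfg, genome, maps, truth = effect_sim
        tg = compute_oci(maps["growing"])
        ts = compute_oci(maps["senescent"])
        d = delta_oci(tg, ts)
        target = truth.per_bin["delta_oci_dir"].to_numpy() == "+"
        ok = ~np.isnan(d.values)
        assert np.nanmean(d.values[target & ok]) > np.nanmean(d.values[~target & ok])
        assert (d.values[target & ok] > 0).mean() >= 0.9

    def test_depth_invariance_of_centered(self, rng):
        # invariance holds in the regime where counts dominate the pseudocount,
        # so every window gets substantial local and trans-control coverage
        asm = GenomeAssembly((("chr1", 2_000_000), ("chr2", 2_000_000)))
        bins = bin_genome(asm, 200_000)
        n = bins.n_bins
        i = list(range(n)) + [k % 10 for k in range(10)]
        j = list(range(n)) + [10 + (k * 3) % 10 for k in range(10)]
        c = list(rng.integers(50, 300, n)) + list(rng.integers(50, 300, 10))
        m = ContactMap(bins, i, j, c)
        deep = ContactMap(bins, m.bin1, m.bin2, m.count * 10)
        t1 = compute_oci(m, LOOSE)
        t2 = compute_oci(deep, LOOSE)
        np.testing.assert_allclose(t2.centered, t1.centered, atol=0.05)


class TestDelta:
    def test_antisymmetric_and_identity(self, tiny_bins, rng):
        m1 = random_map(tiny_bins, rng)
        m2 = random_map(tiny_bins, rng)
        t1 = compute_oci(m1, LOOSE)
        t2 = compute_oci(m2, LOOSE)
        d12 = delta_oci(t1, t2)
        d21 = delta_oci(t2, t1)
        np.testing.assert_allclose(d12.values, -d21.values, equal_nan=True)
        assert np.allclose(delta_oci(t1, t1).values, 0.0, atol=1e-12)

    def test_mismatched_windows_error(self, tiny_bins, rng):
        other = bin_genome(GenomeAssembly((("chr1", 1_200_000),)), 200_000)
        t1 = compute_oci(random_map(tiny_bins, rng), LOOSE)
        t2 = compute_oci(random_map(other, rng), LOOSE)
        with pytest.raises(ValueError):
            delta_oci(t1, t2)


class TestStratify:
    def test_single_class_equals_global(self, tiny_bins, rng):
        t = compute_oci(random_map(tiny_bins, rng), LOOSE)
        track = t.as_scalar_track("centered")
        classing = FeatureClassing(tiny_bins, np.full(tiny_bins.n_bins, "all", object))
        out = stratify_oci(track, classing)
        assert out.loc[0, "mean"] == pytest.approx(np.nanmean(track.values))

    def test_empty_class_reported(self, tiny_bins, rng):
        t = compute_oci(random_map(tiny_bins, rng), LOOSE)
        labels = np.full(tiny_bins.n_bins, "a", object)
        classing = FeatureClassing(tiny_bins, labels)
        track = ScalarTrack(tiny_bins, np.full(tiny_bins.n_bins, np.nan))
        out = stratify_oci(track, classing)
        assert out.loc[0, "n"] == 0

    def test_target_class_dominates_delta(self, effect_sim):
        cfg, genome, maps, truth = effect_sim
        d = delta_oci(compute_oci(maps["growing"]), compute_oci(maps["senescent"]))
        out = stratify_oci(d, genome.bin_class).set_index("class")
        target_mean = out.loc[cfg.target_class, "mean"]
        others = out.drop(cfg.target_class)["mean"]
        assert (target_mean > others).all()


class TestMetaProfile:
    def _track(self, values):
        asm = GenomeAssembly((("chr1", len(values) * 200_000),))
        bins = bin_genome(asm, 200_000)
        return ScalarTrack(bins, np.asarray(values, float))

    def test_constant_track_flat(self):
        track = self._track([2.5] * 40)
        ivs = IntervalSet.from_records([("chr1", 2_000_000, 4_000_000, "")])
        prof = meta_profile(track, ivs)
        assert np.allclose(prof["mean"], 2.5)

    def test_step_track_high_in_body(self):
        vals = np.zeros(40)
        vals[10:20] = 1.0
        track = self._track(vals)
        ivs = IntervalSet.from_records([("chr1", 2_000_000, 4_000_000, "")])
        prof = meta_profile(track, ivs, flank_fraction=0.5)
        body = prof[(prof["x"] > 0.1) & (prof["x"] < 0.9)]["mean"]
        flank = prof[prof["x"] < -0.2]["mean"]
        assert body.mean() > 0.9
        assert flank.mean() < 0.2

    def test_two_interval_interpolation_oracle(self):
        vals = np.arange(40, dtype=float)
        track = self._track(vals)
        ivs = IntervalSet.from_records(
            [("chr1", 1_000_000, 2_000_000, ""), ("chr1", 5_000_000, 7_000_000, "")]
        )
        prof = meta_profile(track, ivs, flank_fraction=0.5,
                            body_points=4, flank_points=2)
        mids = track.bins.midpoint
        grid = np.concatenate([
            -0.5 + (np.arange(2) + 0.5) * 0.25,
            (np.arange(4) + 0.5) / 4,
            1.0 + (np.arange(2) + 0.5) * 0.25,
        ])
        expected = np.mean(
            [
                np.interp(1_000_000 + grid * 1_000_000, mids, vals),
                np.interp(5_000_000 + grid * 2_000_000, mids, vals),
            ],
            axis=0,
        )
        np.testing.assert_allclose(prof["mean"], expected)

    def test_short_intervals_skipped(self):
        track = self._track([1.0] * 10)
        ivs = IntervalSet.from_records([("chr1", 0, 100_000, "")])
        prof = meta_profile(track, ivs)
        assert prof.attrs["skipped"] == 1
        assert prof["n"].iloc[0] == 0
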