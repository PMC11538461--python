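"""Feature matrices, correlograms, signal ops, fusion regions, shuffles and
ancestral-centromere projection."""

import numpy as np
import pytest
import scipy.stats as ss

from holocentro.coloc import (
    PermutationResult,
    SyntenyBlock,
    correlogram,
    fusion_regions_from_synteny,
    permutation_colocalization,
    project_ancestral_centromeres,
    rpkm_log2_ratio,
    scaled_metaprofile,
    shuffle_regions,
    window_feature_matrix,
)
from holocentro.intervals import GenomeIndex, Interval, IntervalSet, tile_windows
from holocentro.io import SignalTrack

from .conftest import ivset_to_tuples, mask_of, random_interval_set


def make_track(chrom_len, bin_size, values, chrom="c"):
    starts = np.arange(0, chrom_len, bin_size, dtype=np.int64)
    ends = np.minimum(starts + bin_size, chrom_len)
    return SignalTrack(
        bins={chrom: (starts, ends, np.asarray(values, dtype=float))}
    )


class TestFeatureMatrix:
    def test_full_and_absent_coverage(self):
        g = GenomeIndex({"c": 2_000})
        wins = tile_windows(g, 1_000)
        feat = IntervalSet([Interval("c", 0, 1_000)])
        m = window_feature_matrix(wins, {"f": feat})
        assert list(m["f"]) == [1.0, 0.0]

    def test_matches_per_base_mask_average(self, rng):
        chroms = {"chrA": 20_000}
        g = GenomeIndex(chroms)
        wins = tile_windows(g, 1_000)
        feat = random_interval_set(rng, chroms, 20, 1_500)
        m = window_feature_matrix(wins, {"f": feat})
        mask = mask_of(feat, chroms)["chrA"]
        expected = mask.reshape(20, 1_000).mean(axis=1)
        assert m["f"].to_numpy() == pytest.approx(expected, abs=1e-12)

    def test_signal_mean_with_missing_as_zero(self):
        g = GenomeIndex({"c": 2_000})
        wins = tile_windows(g, 1_000)
        # track covers only first half of each window
        track = SignalTrack(
            bins={"c": (np.array([0, 1_000]), np.array([500, 1_500]),
                        np.array([2.0, 4.0]))}
        )
        m = window_feature_matrix(wins, {"s": track})
        assert list(m["s"]) == [1.0, 2.0]


class TestCorrelogram:
    def test_planted_cooccurrence_unmasked(self, rng):
        n = 200
        base = rng.random(n)
        m = {
            "a": base + 0.05 * rng.random(n),
            "b": base + 0.05 * rng.random(n),
            "c": rng.random(n),
        }
        import pandas as pd

        rho, padj, mask = correlogram(pd.DataFrame(m))
        assert rho.loc["a", "b"] > 0.8
        assert not mask.loc["a", "b"]
        assert mask.loc["a", "a"]  # diagonal masked

    def test_constant_column_masked_with_warning(self, rng):
        import pandas as pd

        df = pd.DataFrame({"a": rng.random(50), "b": np.ones(50)})
        with pytest.warns(UserWarning):
            rho, padj, mask = correlogram(df)
        assert mask.loc["a", "b"]

    def test_null_false_discovery_controlled(self, rng):
        """Independent features: unmasked-pair rate stays near alpha."""
        import pandas as pd

        false_pos = 0
        pairs = 0
        for _ in range(60):
            df = pd.DataFrame(rng.random((50, 4)), columns=list("abcd"))
            _, _, mask = correlogram(df, alpha=0.05)
            off = ~mask.values & ~np.eye(4, dtype=bool)
            false_pos += off.sum() // 2
            pairs += 6
        assert false_pos / pairs <= 0.06


class TestRpkmLog2:
    def test_identical_tracks_zero(self, rng):
        counts = rng.poisson(10, size=20).astype(float) + 1
        chip = make_track(2_000, 100, counts)
        inp = make_track(2_000, 100, counts)
        out = rpkm_log2_ratio(chip, inp)
        assert out.values("c") == pytest.approx(np.zeros(20))

    def test_doubled_counts_equal_libraries(self):
        chip = make_track(2_000, 100, np.full(20, 20.0))
        inp = make_track(2_000, 100, np.full(20, 10.0))
        out = rpkm_log2_ratio(
            chip, inp, pseudocount=1e-12, chip_library=1e6, input_library=1e6
        )
        assert out.values("c") == pytest.approx(np.ones(20))

    def test_matches_direct_formula(self, rng):
        chip_counts = rng.poisson(20, size=30).astype(float)
        input_counts = rng.poisson(10, size=30).astype(float) + 1
        chip = make_track(3_000, 100, chip_counts)
        inp = make_track(3_000, 100, input_counts)
        eps = 0.5
        out = rpkm_log2_ratio(chip, inp, pseudocount=eps)
        lib_c, lib_i = chip_counts.sum(), input_counts.sum()
        rpkm_c = chip_counts / (0.1 * lib_c / 1e6)
        rpkm_i = input_counts / (0.1 * lib_i / 1e6)
        expected = np.log2((rpkm_c + eps) / (rpkm_i + eps))
        assert out.values("c") == pytest.approx(expected, abs=1e-12)

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rpkm_log2_ratio(
                make_track(2_000, 100, np.ones(20)),
                make_track(2_000, 200, np.ones(10)),
            )


class TestMetaprofile:
    def test_constant_track_flat_profile(self):
        track = make_track(50_000, 100, np.full(500, 3.5))
        feats = IntervalSet([Interval("c", 10_000, 20_000), Interval("c", 30_000, 40_000)])
        prof = scaled_metaprofile(track, feats, body_bins=20, flank=2_000, flank_bins=10)
        assert prof.values == pytest.approx(np.full(40, 3.5))

    def test_signal_inside_features_elevates_body(self):
        vals = np.zeros(500)
        vals[100:200] = 10.0  # feature [10k, 20k)
        track = make_track(50_000, 100, vals)
        feats = IntervalSet([Interval("c", 10_000, 20_000)])
        prof = scaled_metaprofile(track, feats, body_bins=20, flank=2_000, flank_bins=10)
        assert prof.body.mean() > prof.values[:10].mean()

    def test_border_gradient_shows_at_body_edges(self):
        """Signal rising toward feature borders: edge body-bins > center."""
        vals = np.zeros(1_000)
        s, e = 200, 600  # feature [20k, 60k)
        for b in range(s, e):
            mid = (s + e) / 2
            vals[b] = abs(b - mid) / (e - s) * 2  # 0 at center, 1 at borders
        track = make_track(100_000, 100, vals)
        feats = IntervalSet([Interval("c", 20_000, 60_000)])
        prof = scaled_metaprofile(track, feats, body_bins=40, flank=0, flank_bins=0)
        body = prof.body
        edges = np.concatenate([body[:5], body[-5:]]).mean()
        center = body[15:25].mean()
        assert edges > center

    def test_minus_strand_flipped(self):
        vals = np.zeros(500)
        vals[100:110] = 5.0  # at the 5' end of the feature on + strand
        track = make_track(50_000, 100, vals)
        plus = IntervalSet([Interval("c", 10_000, 20_000, attrs=("x", ".", "+"))])
        minus = IntervalSet([Interval("c", 10_000, 20_000, attrs=("x", ".", "-"))])
        p1 = scaled_metaprofile(track, plus, body_bins=10, flank=0, flank_bins=0)
        p2 = scaled_metaprofile(track, minus, body_bins=10, flank=0, flank_bins=0)
        assert p1.values == pytest.approx(p2.values[::-1])

    def test_short_features_skipped_and_counted(self):
        track = make_track(10_000, 100, np.ones(100))
        feats = IntervalSet([Interval("c", 0, 10), Interval("c", 1_000, 3_000)])
        prof = scaled_metaprofile(track, feats, body_bins=50, flank=0, flank_bins=0)
        assert prof.n_features == 1 and prof.n_skipped == 1


class TestFusionRegions:
    def test_large_gap_emits_flanks_and_region(self):
        blocks = [
            SyntenyBlock(Interval("c", 0, 1_000_000), Interval("r1", 0, 1_000_000)),
            SyntenyBlock(Interval("c", 1_150_000, 2_000_000), Interval("r2", 0, 850_000)),
        ]
        flanks, fusions = fusion_regions_from_synteny(blocks)
        assert ivset_to_tuples(flanks) == {
            ("c", 950_000, 1_000_000), ("c", 1_150_000, 1_200_000)
        }
        assert ivset_to_tuples(fusions) == {("c", 1_000_000, 1_150_000)}

    def test_small_gap_flanks_only(self):
        blocks = [
            SyntenyBlock(Interval("c", 0, 500_000), Interval("r1", 0, 500_000)),
            SyntenyBlock(Interval("c", 550_000, 900_000), Interval("r2", 0, 350_000)),
        ]
        flanks, fusions = fusion_regions_from_synteny(blocks)
        assert len(flanks) == 2 and len(fusions) == 0

    def test_adjacent_blocks_nothing(self):
        blocks = [
            SyntenyBlock(Interval("c", 0, 500_000), Interval("r1", 0, 500_000)),
            SyntenyBlock(Interval("c", 500_000, 900_000), Interval("r2", 0, 400_000)),
        ]
        flanks, fusions = fusion_regions_from_synteny(blocks)
        assert len(flanks) == 0 and len(fusions) == 0

    def test_overlapping_blocks_rejected(self):
        blocks = [
            SyntenyBlock(Interval("c", 0, 500_000), Interval("r1", 0, 500_000)),
            SyntenyBlock(Interval("c", 400_000, 900_000), Interval("r2", 0, 500_000)),
        ]
        with pytest.raises(ValueError):
            fusion_regions_from_synteny(blocks)


class TestShuffle:
    def test_lengths_preserved_and_exclusion_respected(self, rng):
        g = GenomeIndex({"c1": 100_000, "c2": 50_000})
        regions = random_interval_set(rng, g.chrom_sizes, 10, 3_000)
        exclusion = IntervalSet([Interval("c1", 0, 60_000)])
        out = shuffle_regions(regions, g, exclusion=exclusion, rng=1)
        assert sorted(len(iv) for iv in out) == sorted(len(iv) for iv in regions)
        from holocentro.intervals import intersect_intervals

        assert intersect_intervals(out, exclusion)[1] == 0
        # mutually non-overlapping
        for chrom in out.chroms:
            arr = out.coords(chrom)
            assert (arr[1:, 0] >= arr[:-1, 1]).all()

    def test_deterministic_per_seed(self, rng):
        g = GenomeIndex({"c": 100_000})
        regions = random_interval_set(rng, g.chrom_sizes, 5, 2_000)
        a = shuffle_regions(regions, g, rng=42)
        b = shuffle_regions(regions, g, rng=42)
        c = shuffle_regions(regions, g, rng=43)
        assert a == b and a != c

    def test_forced_placement_in_only_slot(self):
        g = GenomeIndex({"c": 10_000})
        regions = IntervalSet([Interval("c", 0, 1_000)])
        exclusion = IntervalSet([Interval("c", 0, 4_000), Interval("c", 5_000, 10_000)])
        out = shuffle_regions(regions, g, exclusion=exclusion, rng=0)
        iv = next(iter(out))
        assert iv.start >= 4_000 and iv.end <= 5_000

    def test_impossible_placement_errors(self):
        g = GenomeIndex({"c": 5_000})
        regions = IntervalSet([Interval("c", 0, 1_000)])
        exclusion = IntervalSet([Interval("c", 0, 5_000)])
        with pytest.raises(RuntimeError, match="c"):
            shuffle_regions(regions, g, exclusion=exclusion, rng=0, max_retries=50)

    def test_uniform_start_distribution(self):
        g = GenomeIndex({"c": 10_000})
        regions = IntervalSet([Interval("c", 0, 500)])
        rng = np.random.default_rng(0)
        starts = [
            next(iter(shuffle_regions(regions, g, rng=rng))).start
            for _ in range(2_000)
        ]
        ks = ss.kstest(np.array(starts) / 9_500, "uniform")
        assert ks.pvalue > 0.01


class TestPermutation:
    def test_feature_equal_regions_maximal(self, rng):
        g = GenomeIndex({"c": 1_000_000})
        regions = IntervalSet([Interval("c", 100_000, 102_000)], name="r")
        res = permutation_colocalization(regions, regions, g, n_rounds=100, seed=0)
        assert res.real_overlap_proportion == 1.0
        assert res.percentile > 95

    def test_invalid_rounds(self):
        g = GenomeIndex({"c": 1_000})
        s = IntervalSet([Interval("c", 0, 10)])
        with pytest.raises(ValueError):
            permutation_colocalization(s, s, g, n_rounds=0)

    def test_percentile_consistency_enforced(self):
        with pytest.raises(ValueError):
            PermutationResult("f", 0.5, np.array([0.1, 0.9]), 99.0, 2, 0)


class TestProjection:
    def test_gap_between_adjacent_blocks(self):
        blocks = [
            SyntenyBlock(Interval("t", 0, 1_000), Interval("s", 0, 1_000)),
            SyntenyBlock(Interval("t", 1_500, 2_500), Interval("s", 2_000, 3_000)),
        ]
        cens = IntervalSet([Interval("s", 1_200, 1_800)])
        res = project_ancestral_centromeres(blocks, cens)
        assert res[0].target == Interval("t", 1_000, 1_500)

    def test_containment_interpolation(self):
        blocks = [SyntenyBlock(Interval("t", 10_000, 20_000), Interval("s", 0, 10_000))]
        cens = IntervalSet([Interval("s", 4_000, 6_000)])
        res = project_ancestral_centromeres(blocks, cens)
        assert res[0].target == Interval("t", 14_000, 16_000)

    def test_minus_orientation_flips(self):
        blocks = [
            SyntenyBlock(Interval("t", 0, 10_000), Interval("s", 0, 10_000), "-")
        ]
        cens = IntervalSet([Interval("s", 0, 2_000)])
        res = project_ancestral_centromeres(blocks, cens)
        assert res[0].target == Interval("t", 8_000, 10_000)

    def test_unprojectable_reported(self):
        blocks = [SyntenyBlock(Interval("t", 0, 1_000), Interval("s", 0, 1_000))]
        cens = IntervalSet([Interval("s", 5_000, 6_000)])
        res = project_ancestral_centromeres(blocks, cens)
        assert res[0].target is None and "flanking" in res[0].note

    def test_collinear_genomes_contain_truth(self, rng):
        """On rearrangement-free genomes the projection brackets the true
        centromere location."""
        hits = 0
        n_sim = 40
        for i in range(n_sim):
            r = np.random.default_rng(i)
            # source genome: blocks with gaps; target = same layout + offset
            pos_s = 0
            pos_t = int(r.integers(0, 5_000))
            blocks = []
            gaps = []
            for b in range(4):
                blen = int(r.integers(5_000, 20_000))
                blocks.append(
                    SyntenyBlock(
                        Interval("t", pos_t, pos_t + blen),
                        Interval("s", pos_s, pos_s + blen),
                    )
                )
                gap = int(r.integers(2_000, 8_000))
                if b < 3:
                    gaps.append((pos_s + blen, pos_s + blen + gap,
                                 pos_t + blen, pos_t + blen + gap))
                pos_s += blen + gap
                pos_t += blen + gap
            gs, ge, ts, te = gaps[int(r.integers(0, 3))]
            cen_len = int(r.integers(500, min(2_000, ge - gs)))
            cs = int(r.integers(gs, ge - cen_len))
            true_target = (cs - gs + ts, cs - gs + ts + cen_len)
            res = project_ancestral_centromeres(
                blocks, IntervalSet([Interval("s", cs, cs + cen_len)])
            )
            t = res[0].target
            if t is not None and t.start <= true_target[0] and t.end >= true_target[1]:
                hits += 1
        assert hits / n_sim >= 0.95
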