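"""Functional/nonfunctional classification and its bookkeeping identities."""

import numpy as np
import pytest

from holocentro.classify import (
    classification_summary,
    classify_arrays,
    compare_array_sizes,
    domain_composition,
    label_units,
    satellite_free_units,
)
from holocentro.domains import CentromericUnit
from holocentro.intervals import Interval, IntervalSet
from holocentro.satellites import SatelliteArray

from .conftest import ivset_to_tuples, mask_of, random_interval_set


def arr(chrom, s, e, fam="Lusy1"):
    return SatelliteArray(Interval(chrom, s, e), fam, (e - s) / 124, 1.0)


def unit(chrom, s, e):
    return CentromericUnit(Interval(chrom, s, e), 1)


class TestClassify:
    def test_overlap_makes_functional_with_fragment(self):
        res = classify_arrays([arr("c", 0, 50_000)], [unit("c", 40_000, 60_000)])
        c = res[0]
        assert c.status == "functional"
        assert ivset_to_tuples(c.fragments) == {("c", 40_000, 50_000)}
        assert c.overlap_bases == 10_000

    def test_disjoint_is_nonfunctional(self):
        res = classify_arrays([arr("c", 0, 1_000)], [unit("c", 5_000, 6_000)])
        assert res[0].status == "nonfunctional"
        assert len(res[0].fragments) == 0 and res[0].overlap_bases == 0

    def test_counts_partition_and_fraction(self):
        arrays = [arr("c", i * 10_000, i * 10_000 + 2_000) for i in range(10)]
        units = [unit("c", i * 10_000, i * 10_000 + 500) for i in range(4)]
        res = classify_arrays(arrays, units)
        summ = classification_summary(res)
        row = summ.iloc[0]
        assert row["functional_count"] + row["nonfunctional_count"] == 10
        assert row["functional_fraction"] == pytest.approx(0.4)

    def test_fragment_bases_bounded(self, rng):
        chroms = {"chrA": 100_000}
        arrays = [
            SatelliteArray(iv, "f", 1.0, 1.0)
            for iv in random_interval_set(rng, chroms, 20, 5_000)
        ]
        units = [
            CentromericUnit(iv, 1)
            for iv in random_interval_set(rng, chroms, 10, 8_000)
        ]
        res = classify_arrays(arrays, units)
        frag = sum(c.overlap_bases for c in res)
        from holocentro.intervals import merge_intervals

        unit_bases = merge_intervals(
            IntervalSet([u.interval for u in units])
        ).total_bases
        assert frag <= unit_bases


class TestSatelliteFree:
    def test_one_bp_overlap_excludes(self):
        units = [unit("c", 0, 1_000), unit("c", 5_000, 6_000)]
        arrays = [arr("c", 999, 2_000)]
        free = satellite_free_units(units, arrays)
        assert ivset_to_tuples(free) == {("c", 5_000, 6_000)}

    def test_matches_mask_oracle(self, rng):
        chroms = {"chrA": 50_000}
        units = [
            CentromericUnit(iv, 1)
            for iv in random_interval_set(rng, chroms, 15, 3_000)
        ]
        arrays = [
            SatelliteArray(iv, "f", 1.0, 1.0)
            for iv in random_interval_set(rng, chroms, 15, 3_000)
        ]
        free = satellite_free_units(units, arrays)
        amask = mask_of(IntervalSet([a.interval for a in arrays]), chroms)["chrA"]
        expected = {
            (u.interval.chrom, u.interval.start, u.interval.end)
            for u in units
            if not amask[u.interval.start : u.interval.end].any()
        }
        assert ivset_to_tuples(free) == expected


class TestLabels:
    def test_single_and_double_labels(self):
        units = [unit("c", 0, 10_000), unit("c", 20_000, 30_000)]
        fams = {
            "Lusy1": [arr("c", 0, 1_000, "Lusy1"), arr("c", 21_000, 22_000, "Lusy1")],
            "Lusy2": [arr("c", 25_000, 26_000, "Lusy2")],
        }
        labels = label_units(units, fams)
        assert labels[0][1] == frozenset({"Lusy1"})
        assert labels[1][1] == frozenset({"Lusy1", "Lusy2"})

    def test_label_partition_covers_all_units(self, rng):
        chroms = {"chrA": 50_000}
        units = [
            CentromericUnit(iv, 1)
            for iv in random_interval_set(rng, chroms, 12, 2_000)
        ]
        fams = {
            "Lusy1": [
                SatelliteArray(iv, "Lusy1", 1.0, 1.0)
                for iv in random_interval_set(rng, chroms, 10, 2_000)
            ],
            "Lusy2": [
                SatelliteArray(iv, "Lusy2", 1.0, 1.0)
                for iv in random_interval_set(rng, chroms, 10, 2_000)
            ],
        }
        labels = label_units(units, fams)
        all_arrays = fams["Lusy1"] + fams["Lusy2"]
        free = satellite_free_units(units, all_arrays)
        labeled = sum(1 for _, ls in labels if ls)
        assert labeled + len(free) == len(units)
        per_family = sum(sum(1 for _, ls in labels if f in ls) for f in fams)
        assert per_family + len(free) >= len(units)


class TestComposition:
    def test_full_and_half_coverage(self):
        domains = IntervalSet([Interval("c", 0, 1_000)])
        annot = {
            "full": IntervalSet([Interval("c", 0, 1_000)]),
            "half": IntervalSet([Interval("c", 0, 500)]),
        }
        frac = domain_composition(domains, annot)
        assert frac["full"] == pytest.approx(1.0)
        assert frac["half"] == pytest.approx(0.5)

    def test_empty_domains_rejected(self):
        with pytest.raises(ValueError):
            domain_composition(IntervalSet(), {"x": IntervalSet()})

    def test_matches_mask_oracle(self, rng):
        chroms = {"chrA": 30_000}
        domains = random_interval_set(rng, chroms, 10, 3_000)
        annot = {
            "a": random_interval_set(rng, chroms, 10, 3_000),
            "b": random_interval_set(rng, chroms, 5, 5_000),
        }
        frac = domain_composition(domains, annot)
        dm = mask_of(domains, chroms)["chrA"]
        for name, track in annot.items():
            am = mask_of(track, chroms)["chrA"]
            assert frac[name] == pytest.approx((dm & am).sum() / dm.sum(), abs=1e-12)


class TestSizeComparison:
    def test_identical_distributions_high_p(self):
        arrays = [arr("c", i * 3_000, i * 3_000 + 1_000) for i in range(10)]
        units = [unit("c", i * 3_000, i * 3_000 + 100) for i in range(0, 10, 2)]
        res = classify_arrays(arrays, units)
        tests = compare_array_sizes(res)
        assert tests["Lusy1"][0].p_value > 0.5

    def test_planted_size_difference_detected(self, rng):
        detected = 0
        for i in range(10):
            r = np.random.default_rng(i)
            pos = 0
            classified = []
            units = []
            arrays = []
            for j in range(30):
                functional = j < 15
                length = int(r.lognormal(np.log(10_000 if functional else 1_000), 0.3))
                arrays.append(arr("c", pos, pos + length))
                if functional:
                    units.append(unit("c", pos, pos + 100))
                pos += length + 1_000
            res = classify_arrays(arrays, units)
            p = compare_array_sizes(res)["Lusy1"][0].p_value
            detected += p < 0.01
        assert detected >= 9

    def test_empty_group_raises(self):
        arrays = [arr("c", 0, 1_000)]
        res = classify_arrays(arrays, [])
        with pytest.raises(ValueError, match="non-empty"):
            compare_array_sizes(res)
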