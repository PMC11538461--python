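"""Inverted-repeat finder: examples, oracle equivalence, strand symmetry."""

import itertools

import numpy as np
import pytest

from holocentro.classify import ClassifiedArray
from holocentro.dyads import (
    compare_dyad_abundance,
    dyad_abundance,
    find_inverted_repeats,
)
from holocentro.intervals import GenomeIndex, Interval
from holocentro.satellites import SatelliteArray
from holocentro.sequence import revcomp

from ._oracles import brute_force_dyads, naive_dyads


def hit_tuples(hits):
    return {(h.left_start, h.stem_len, h.loop_len) for h in hits}


class TestFinder:
    def test_simple_palindrome(self):
        hits = find_inverted_repeats("AAAATTTT", min_stem=4, max_loop=0)
        assert hit_tuples(hits) == {(0, 4, 0)}
        h = hits[0]
        assert h.left_arm == (0, 4) and h.right_arm == (4, 8)

    def test_homopolymer_has_no_hits(self):
        assert find_inverted_repeats("A" * 50, min_stem=2) == []

    def test_n_never_pairs(self):
        assert find_inverted_repeats("AANNTT", min_stem=3, max_loop=0) == []

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            find_inverted_repeats("ACGT", min_stem=10, max_stem=5)
        with pytest.raises(ValueError):
            find_inverted_repeats("ACGT", mismatches=1)

    def test_loop_respected(self):
        seq = "GGGGCC" + "ATATA" + "GGCCCC"  # stem GGGGCC revcomp GGCCCC, loop 5
        hits = find_inverted_repeats(seq, min_stem=6, max_loop=5)
        assert (0, 6, 5) in hit_tuples(hits)
        assert find_inverted_repeats(seq, min_stem=6, max_loop=4) == [] or (
            (0, 6, 5) not in hit_tuples(find_inverted_repeats(seq, min_stem=6, max_loop=4))
        )

    @pytest.mark.parametrize("min_stem,max_loop", [(3, 0), (4, 10), (6, 25)])
    def test_matches_naive_triple_loop_oracle(self, min_stem, max_loop, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            got = hit_tuples(find_inverted_repeats(seq, min_stem, 40, max_loop))
            assert got == naive_dyads(seq, min_stem, 40, max_loop)

    def test_two_oracles_agree(self, rng):
        """The fast extension oracle matches the naive definition check."""
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            assert brute_force_dyads(seq, 4, 40, 10) == naive_dyads(seq, 4, 40, 10)

    def test_reverse_complement_count_invariance(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            a = find_inverted_repeats(seq, min_stem=4, max_loop=20)
            b = find_inverted_repeats(revcomp(seq), min_stem=4, max_loop=20)
            assert len(a) == len(b)

    def test_density_decreases_with_min_stem(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        counts = [
            len(find_inverted_repeats(seq, min_stem=ms, max_loop=50))
            for ms in (4, 6, 8, 10)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]


class TestAbundance:
    def test_duplicate_sequences_same_density(self, rng):
        body = "".join(rng.choice(list("ACGT"), size=2_000))
        spacer = "".join(rng.choice(list("ACGT"), size=500))
        genome = GenomeIndex({"c": 4_500}, {"c": body + spacer + body})
        arrs = [
            ClassifiedArray(
                SatelliteArray(Interval("c", 0, 2_000), "fam", 1.0, 1.0),
                "functional",
            ),
            ClassifiedArray(
                SatelliteArray(Interval("c", 2_500, 4_500), "fam", 1.0, 1.0),
                "nonfunctional",
            ),
        ]
        df = dyad_abundance(arrs, genome, min_stem=4, max_loop=20)
        assert df["density_per_kb"].iloc[0] == df["density_per_kb"].iloc[1]

    def test_out_of_bounds_array_rejected(self):
        genome = GenomeIndex({"c": 100}, {"c": "A" * 100})
        arr = ClassifiedArray(
            SatelliteArray(Interval("c", 50, 200), "fam", 1.0, 1.0), "functional"
        )
        with pytest.raises(ValueError):
            dyad_abundance([arr], genome)

    def test_label_swap_flips_one_tailed_p(self, rng):
        ivs = []
        parts = []
        pos = 0
        statuses = []
        for i in range(16):
            body = "".join(rng.choice(list("ACGT"), size=1_500))
            parts.append(body)
            ivs.append(Interval("c", pos, pos + 1_500))
            statuses.append("functional" if i % 2 == 0 else "nonfunctional")
            pos += 1_500
        genome = GenomeIndex({"c": pos}, {"c": "".join(parts)})
        classified = [
            ClassifiedArray(SatelliteArray(iv, "fam", 1.0, 1.0), st)
            for iv, st in zip(ivs, statuses)
        ]
        swapped = [
            ClassifiedArray(
                SatelliteArray(iv, "fam", 1.0, 1.0),
                "nonfunctional" if st == "functional" else "functional",
            )
            for iv, st in zip(ivs, statuses)
        ]
        p1 = compare_dyad_abundance(
            dyad_abundance(classified, genome, min_stem=4, max_loop=20)
        )["fam"].p_value
        p2 = compare_dyad_abundance(
            dyad_abundance(swapped, genome, min_stem=4, max_loop=20)
        )["fam"].p_value
        assert p1 + p2 == pytest.approx(1.0, abs=0.05)

    def test_empty_group_informative_error(self, rng):
        genome = GenomeIndex({"c": 1_000}, {"c": "".join(rng.choice(list("ACGT"), 1_000))})
        arr = ClassifiedArray(
            SatelliteArray(Interval("c", 0, 500), "fam", 1.0, 1.0), "functional"
        )
        with pytest.raises(ValueError, match="non-empty"):
            compare_dyad_abundance(dyad_abundance([arr], genome))


def test_planted_dyad_contrast_detected():
    """Arrays with 3x planted dyad rate show higher density (power check)."""
    from holocentro.stats import mann_whitney_u

    detected = 0
    n_sim = 10
    for i in range(n_sim):
        r = np.random.default_rng(500 + i)

        def make_group(rate, n):
            densities = []
            for _ in range(n):
                seq = list("".join(r.choice(list("ACGT"), size=3_000)))
                k = r.poisson(rate * 3)
                for _ in range(k):
                    stem = "".join(r.choice(list("ACGT"), size=12))
                    ins = stem + "AAACC" + revcomp(stem)
                    p = int(r.integers(0, 3_000 - len(ins)))
                    seq[p : p + len(ins)] = list(ins)
                hits = find_inverted_repeats("".join(seq), min_stem=10, max_loop=100)
                densities.append(len(hits) / 3.0)
            return densities

        func = make_group(1.5, 12)
        nonf = make_group(0.5, 12)
        p = mann_whitney_u(func, nonf, "greater").p_value
        detected += p < 0.05
    assert detected >= 0.7 * n_sim
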