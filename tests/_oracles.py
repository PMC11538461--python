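"""Independent brute-force oracles shared by unit and acceptance tests."""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pairs(seq: str, p: int, q: int) -> bool:
    a = seq[p]
    return a in _COMP and _COMP[a] == seq[q]


def brute_force_dyads(
    seq: str, min_stem: int, max_stem: int, max_loop: int
) -> set[tuple[int, int, int]]:
    """All maximal exact inverted repeats as (left_start, stem, loop).

    Exhaustive scan over every (inner arm end, loop) position with outward
    extension by direct character comparison — independent of the
    anti-diagonal run algorithm in the production finder.
    """
    n = len(seq)
    hits: set[tuple[int, int, int]] = set()
    for e in range(n - 1):
        for g in range(0, max_loop + 1):
            q0 = e + g + 1  # innermost right-arm position
            if q0 > n - 1:
                break
            if not _pairs(seq, e, q0):
                continue
            # outward run length from the innermost pair
            run = 1
            while (
                run < max_stem
                and e - run >= 0
                and q0 + run <= n - 1
                and _pairs(seq, e - run, q0 + run)
            ):
                run += 1
            # can the run extend past max_stem? needed for outward blocking
            beyond = (
                run == max_stem
                and e - run >= 0
                and q0 + run <= n - 1
                and _pairs(seq, e - run, q0 + run)
            )
            inward_open = (
                g >= 2
                and e + 1 <= n - 1
                and e + g <= n - 1
                and _pairs(seq, e + 1, e + g)
            )
            for stem in range(min_stem, run + 1):
                outward_blocked = (stem == max_stem) or (stem == run and not beyond)
                inward_blocked = (stem == max_stem) or not inward_open
                if outward_blocked and inward_blocked:
                    hits.add((e - stem + 1, stem, g))
    return hits


def naive_dyads(
    seq: str, min_stem: int, max_stem: int, max_loop: int
) -> set[tuple[int, int, int]]:
    """Triple-loop definition-level check; only feasible for short sequences."""
    n = len(seq)
    hits = set()
    for s in range(n):
        for stem in range(min_stem, max_stem + 1):
            e = s + stem - 1
            for g in range(0, max_loop + 1):
                r_end = e + g + stem
                if r_end > n - 1:
                    break
                if not all(_pairs(seq, s + t, r_end - t) for t in range(stem)):
                    continue
                out_blocked = (
                    stem == max_stem
                    or s == 0
                    or r_end + 1 > n - 1
                    or not _pairs(seq, s - 1, r_end + 1)
                )
                in_blocked = (
                    g <= 1
                    or stem == max_stem
                    or not _pairs(seq, e + 1, e + g)
                )
                if out_blocked and in_blocked:
                    hits.add((s, stem, g))
    return hits
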