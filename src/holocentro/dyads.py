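"""Inverted-repeat (dyad symmetry) detection with exact arms.

A dyad symmetry is a pair of arms where the left arm's reverse complement
equals the right arm, separated by a loop. Arms are exact (zero
mismatches); N never pairs. All *maximal* hits are reported: a hit that
cannot be extended by one more base pair on its outer or inner side without
breaking complementarity or the stem/loop limits. Overlapping hits are
allowed, so stricter non-overlap policies can filter downstream.

The finder scans anti-diagonals of the (implicit) self-comparison matrix:
positions p and q pair iff their base codes sum to 3, and all pairs of one
hit share the same coordinate sum p + q. Complexity is
O(n * (max_stem + max_loop)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifiedArray
from .intervals import GenomeIndex, Interval
from .sequence import encode
from .stats import TestResult, mann_whitney_u

__all__ = [
    "DyadHit",
    "find_inverted_repeats",
    "dyad_abundance",
    "compare_dyad_abundance",
]


@dataclass(frozen=True)
class DyadHit:
    """One inverted repeat, in local coordinates of the scanned sequence."""

    left_start: int
    stem_len: int
    loop_len: int

    @property
    def left_arm(self) -> tuple[int, int]:
        return (self.left_start, self.left_start + self.stem_len)

    @property
    def right_arm(self) -> tuple[int, int]:
        s = self.left_start + self.stem_len + self.loop_len
        return (s, s + self.stem_len)

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_start, self.right_arm[1])


def find_inverted_repeats(
    seq: str,
    min_stem: int = 10,
    max_stem: int = 100,
    max_loop: int = 100,
    mismatches: int = 0,
) -> list[DyadHit]:
    """All maximal exact inverted repeats of ``seq``.

    Hits satisfy ``min_stem <= stem <= max_stem`` and ``0 <= loop <=
    max_loop`` and are maximal: no complementary base pair can be added
    outward (widening the hit) or inward (shrinking the loop by two)
    without violating a constraint. Ordered by (left start, stem
    descending).
    """
    if min_stem < 1:
        raise ValueError("min_stem must be >= 1")
    if min_stem > max_stem:
        raise ValueError(f"min_stem {min_stem} exceeds max_stem {max_stem}")
    if max_loop < 0:
        raise ValueError("max_loop must be >= 0")
    if mismatches != 0:
        raise ValueError("only exact arms (mismatches=0) are supported")
    arr = encode(seq).astype(np.int16)
    n = arr.size
    hits: list[DyadHit] = []
    if n < 2 * min_stem:
        return hits
    for d in range(2 * min_stem - 1, 2 * n - 2 * min_stem):
        p_hi = (d - 1) // 2
        e_lo = max(0, -((-(d - 1 - max_loop)) // 2))  # ceil((d-1-max_loop)/2)
        p_lo = max(0, d - n + 1, e_lo - max_stem)
        if p_hi < p_lo:
            continue
        ps = np.arange(p_lo, p_hi + 1)
        match = (arr[ps] + arr[d - ps]) == 3
        if not match.any():
            continue
        # maximal runs of matched pairs along this anti-diagonal
        padded = np.concatenate([[False], match, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        run_starts = edges[0::2] + p_lo
        run_ends = edges[1::2] - 1 + p_lo  # inclusive
        for a, b in zip(run_starts, run_ends):
            if b - a + 1 < min_stem:
                continue
            for e in range(max(a + min_stem - 1, e_lo), b + 1):
                loop = d - 2 * e - 1
                blocked_inward = (e == b) or (loop <= 1)
                len_full = e - a + 1
                took_full = False
                if blocked_inward and min_stem <= len_full <= max_stem:
                    hits.append(DyadHit(int(a), int(len_full), int(loop)))
                    took_full = True
                if len_full >= max_stem and not (took_full and len_full == max_stem):
                    hits.append(
                        DyadHit(int(e - max_stem + 1), int(max_stem), int(loop))
                    )
    hits.sort(key=lambda h: (h.left_start, -h.stem_len, h.loop_len))
    return hits


def dyad_abundance(
    classified: list[ClassifiedArray],
    genome: GenomeIndex,
    min_stem: int = 10,
    max_stem: int = 100,
    max_loop: int = 100,
) -> pd.DataFrame:
    """Per-array dyad counts and densities (hits per kb of array length).

    Each array's whole genomic span is scanned on the forward strand only —
    dyads are strand-symmetric by construction, so the reverse strand would
    double-count every hit.
    """
    rows = []
    for idx, c in enumerate(classified):
        iv = c.array.interval
        if iv.end > genome.chrom_sizes.get(iv.chrom, 0):
            raise ValueError(f"array {idx} outside genome bounds: {iv}")
        seq = genome.fetch(iv)
        hits = find_inverted_repeats(
            seq, min_stem=min_stem, max_stem=max_stem, max_loop=max_loop
        )
        length = len(iv)
        rows.append(
            {
                "array_id": idx,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "family": c.array.family,
                "status": c.status,
                "hit_count": len(hits),
                "array_length": length,
                "density_per_kb": len(hits) / (length / 1000.0),
            }
        )
    return pd.DataFrame(rows)


def compare_dyad_abundance(abundance: pd.DataFrame) -> dict[str, TestResult]:
    """One-tailed Mann–Whitney U per family: functional densities greater
    than nonfunctional?"""
    out: dict[str, TestResult] = {}
    for fam in sorted(abundance["family"].unique()):
        sub = abundance[abundance["family"] == fam]
        func = sub.loc[sub["status"] == "functional", "density_per_kb"].to_numpy()
        nonf = sub.loc[sub["status"] == "nonfunctional", "density_per_kb"].to_numpy()
        if func.size == 0 or nonf.size == 0:
            raise ValueError(
                f"family {fam!r}: both groups must be non-empty "
                f"(functional={func.size}, nonfunctional={nonf.size})"
            )
        out[fam] = mann_whitney_u(func, nonf, alternative="greater")
    return out
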