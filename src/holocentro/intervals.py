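"""Genomic interval algebra.

All coordinates are 0-based half-open ``[start, end)`` — the BED convention.
Conversion from 1-based inclusive coordinates happens only at the GFF3
parsing boundary (see :mod:`holocentro.io`).

The algebra (merge / intersect / subtract / window tiling) is strand-agnostic:
strand information read from input files is preserved as an attribute but
never consulted by the set operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Interval",
    "IntervalSet",
    "GenomeIndex",
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "tile_windows",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    attrs: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An ordered collection of intervals, grouped and sorted by chromosome.

    Internally one ``(n, 2)`` int64 array per chromosome plus an optional
    parallel list of attribute tuples (extra BED columns). Construction
    sorts by ``(chrom, start, end)``; intervals may overlap unless an
    operation states otherwise.
    """

    def __init__(self, intervals: Iterable[Interval] = (), name: str = ""):
        self.name = name
        by_chrom: dict[str, list[Interval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._coords: dict[str, np.ndarray] = {}
        self._attrs: dict[str, list[tuple]] = {}
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
            self._coords[chrom] = np.array(
                [(v.start, v.end) for v in ivs], dtype=np.int64
            ).reshape(-1, 2)
            self._attrs[chrom] = [v.attrs for v in ivs]

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls, coords: Mapping[str, np.ndarray], name: str = ""
    ) -> "IntervalSet":
        """Build from per-chromosome ``(n, 2)`` arrays (copied and sorted)."""
        out = cls(name=name)
        for chrom in sorted(coords):
            arr = np.asarray(coords[chrom], dtype=np.int64).reshape(-1, 2)
            if arr.size and (arr[:, 1] <= arr[:, 0]).any():
                bad = arr[arr[:, 1] <= arr[:, 0]][0]
                raise ValueError(f"invalid interval on {chrom}: {bad.tolist()}")
            if arr.size and (arr[:, 0] < 0).any():
                raise ValueError(f"negative start on {chrom}")
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            arr = arr[order]
            if len(arr):
                out._coords[chrom] = arr
                out._attrs[chrom] = [()] * len(arr)
        return out

    # -- container protocol ---------------------------------------------------

    def __iter__(self) -> Iterator[Interval]:
        for chrom in self.chroms:
            arr = self._coords[chrom]
            attrs = self._attrs[chrom]
            for (s, e), a in zip(arr, attrs):
                yield Interval(chrom, int(s), int(e), a)

    def __len__(self) -> int:
        return sum(len(a) for a in self._coords.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(
            np.array_equal(self._coords[c], other._coords[c]) for c in self.chroms
        )

    def __repr__(self) -> str:
        return (
            f"IntervalSet(name={self.name!r}, n={len(self)}, "
            f"chroms={len(self.chroms)}, bases={self.total_bases})"
        )

    @property
    def chroms(self) -> list[str]:
        return sorted(self._coords)

    def coords(self, chrom: str) -> np.ndarray:
        """The sorted ``(n, 2)`` coordinate array for one chromosome."""
        return self._coords.get(chrom, np.empty((0, 2), dtype=np.int64))

    def attrs(self, chrom: str) -> list[tuple]:
        return self._attrs.get(chrom, [])

    @property
    def total_bases(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._coords.values())
        )

    def restrict(self, chrom: str) -> "IntervalSet":
        out = IntervalSet(name=self.name)
        if chrom in self._coords:
            out._coords[chrom] = self._coords[chrom]
            out._attrs[chrom] = self._attrs[chrom]
        return out


@dataclass
class GenomeIndex:
    """Chromosome sizes plus optional uppercase sequences (A/C/G/T/N)."""

    chrom_sizes: dict[str, int]
    sequences: dict[str, str] | None = None

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def sequence(self, chrom: str) -> str:
        if self.sequences is None or chrom not in self.sequences:
            raise KeyError(f"no sequence loaded for {chrom}")
        return self.sequences[chrom]

    def fetch(self, iv: Interval) -> str:
        return self.sequence(iv.chrom)[iv.start : iv.end]

    def validate(self, ivset: IntervalSet) -> None:
        """Raise if any interval extends past its chromosome end."""
        for chrom in ivset.chroms:
            if chrom not in self.chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            arr = ivset.coords(chrom)
            if len(arr) and arr[:, 1].max() > self.chrom_sizes[chrom]:
                raise ValueError(
                    f"interval exceeds length of {chrom} "
                    f"({self.chrom_sizes[chrom]} bp)"
                )


# -- set operations ----------------------------------------------------------


def _merge_array(arr: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Sweep-merge a sorted (n,2) array; gaps <= max_gap close.

    Returns the merged array and, per merged interval, the count of source
    intervals it absorbed.
    """
    if len(arr) == 0:
        return arr, np.empty(0, dtype=np.int64)
    starts, ends = arr[:, 0], arr[:, 1]
    # new group starts where the gap to the running maximum end exceeds max_gap
    run_end = np.maximum.accumulate(ends)
    new_group = np.empty(len(arr), dtype=bool)
    new_group[0] = True
    new_group[1:] = starts[1:] - run_end[:-1] > max_gap
    group = np.cumsum(new_group) - 1
    n_groups = group[-1] + 1
    out = np.empty((n_groups, 2), dtype=np.int64)
    out[:, 0] = starts[new_group]
    out[:, 1] = np.maximum.reduceat(ends, np.flatnonzero(new_group))
    counts = np.bincount(group, minlength=n_groups)
    return out, counts


def merge_intervals(
    ivset: IntervalSet, max_gap: int = 0
) -> IntervalSet:
    """Merge intervals whose gap is <= ``max_gap`` (overlaps always merge).

    Idempotent: output intervals are pairwise separated by more than
    ``max_gap`` on each chromosome, and their union covers the input union.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    out = IntervalSet(name=ivset.name)
    for chrom in ivset.chroms:
        merged, _ = _merge_array(ivset.coords(chrom), max_gap)
        if len(merged):
            out._coords[chrom] = merged
            out._attrs[chrom] = [()] * len(merged)
    return out


def merge_with_counts(
    ivset: IntervalSet, max_gap: int = 0
) -> list[tuple[Interval, int]]:
    """Like :func:`merge_intervals` but reports how many inputs each merged
    interval absorbed."""
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    out: list[tuple[Interval, int]] = []
    for chrom in ivset.chroms:
        merged, counts = _merge_array(ivset.coords(chrom), max_gap)
        for (s, e), c in zip(merged, counts):
            out.append((Interval(chrom, int(s), int(e)), int(c)))
    return out


def _flatten(arr: np.ndarray) -> np.ndarray:
    """Collapse a sorted (n,2) array to disjoint coverage (gap 0 merge)."""
    merged, _ = _merge_array(arr, 0)
    return merged


def _intersect_flat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Base-level intersection of two disjoint sorted coordinate arrays."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def intersect_intervals(
    a: IntervalSet, b: IntervalSet
) -> tuple[IntervalSet, int]:
    """Exact base-level intersection and its total length in bp."""
    out = IntervalSet(name=f"{a.name}&{b.name}" if a.name or b.name else "")
    total = 0
    for chrom in a.chroms:
        if chrom not in b.chroms:
            continue
        inter = _intersect_flat(_flatten(a.coords(chrom)), _flatten(b.coords(chrom)))
        if len(inter):
            out._coords[chrom] = inter
            out._attrs[chrom] = [()] * len(inter)
            total += int((inter[:, 1] - inter[:, 0]).sum())
    return out, total


def subtract_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-level difference a − b (coverage of a not covered by b)."""
    out = IntervalSet(name=a.name)
    for chrom in a.chroms:
        fa = _flatten(a.coords(chrom))
        fb = _flatten(b.coords(chrom))
        if len(fb) == 0:
            kept = fa
        else:
            pieces: list[tuple[int, int]] = []
            j = 0
            for s, e in fa:
                cur = s
                while j < len(fb) and fb[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(fb) and fb[k, 0] < e:
                    if fb[k, 0] > cur:
                        pieces.append((cur, int(fb[k, 0])))
                    cur = max(cur, int(fb[k, 1]))
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    pieces.append((int(cur), int(e)))
            kept = np.array(pieces, dtype=np.int64).reshape(-1, 2)
        if len(kept):
            out._coords[chrom] = kept
            out._attrs[chrom] = [()] * len(kept)
    return out


def tile_windows(genome: GenomeIndex, width: int) -> IntervalSet:
    """Adjacent non-overlapping windows covering every chromosome.

    The terminal window of each chromosome may be shorter than ``width``;
    it is kept so that windows always tile the full genome.
    """
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    out = IntervalSet(name=f"windows_{width}")
    for chrom in sorted(genome.chrom_sizes):
        length = genome.chrom_sizes[chrom]
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        out._coords[chrom] = np.column_stack([starts, ends])
        out._attrs[chrom] = [()] * len(starts)
    return out


def coverage_mask(ivset: IntervalSet, chrom: str, length: int) -> np.ndarray:
    """Per-base boolean coverage for one chromosome (test/oracle helper)."""
    mask = np.zeros(length, dtype=bool)
    for s, e in ivset.coords(chrom):
        mask[s:e] = True
    return mask
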