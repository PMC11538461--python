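"""Shared fixtures and brute-force oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from holocentro.intervals import GenomeIndex, Interval, IntervalSet


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_interval_set(
    rng: np.random.Generator,
    chroms: dict[str, int],
    n: int,
    max_len: int = 5_000,
    name: str = "",
) -> IntervalSet:
    names = sorted(chroms)
    ivs = []
    for _ in range(n):
        chrom = names[int(rng.integers(0, len(names)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, max(1, chroms[chrom] - length)))
        ivs.append(Interval(chrom, start, start + length))
    return IntervalSet(ivs, name=name)


def mask_of(ivset: IntervalSet, chroms: dict[str, int]) -> dict[str, np.ndarray]:
    out = {}
    for chrom, length in chroms.items():
        m = np.zeros(length, dtype=bool)
        for s, e in ivset.coords(chrom):
            m[s:e] = True
        out[chrom] = m
    return out


def mask_to_intervals(masks: dict[str, np.ndarray]) -> set[tuple[str, int, int]]:
    out = set()
    for chrom, m in masks.items():
        padded = np.concatenate([[False], m, [False]]).astype(np.int8)
        edges = np.flatnonzero(np.diff(padded))
        for s, e in zip(edges[0::2], edges[1::2]):
            out.add((chrom, int(s), int(e)))
    return out


def ivset_to_tuples(ivset: IntervalSet) -> set[tuple[str, int, int]]:
    return {(iv.chrom, iv.start, iv.end) for iv in ivset}


@pytest.fixture
def toy_genome() -> GenomeIndex:
    return GenomeIndex({"chrA": 50_000, "chrB": 30_000})
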