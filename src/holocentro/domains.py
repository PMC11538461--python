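"""CENH3 centromeric unit construction.

Centromere chromatin is defined by CENH3 occupancy. Peak calls from two
callers in two biological replicates are reduced to a high-confidence
consensus (base-level four-way intersection: a position counts only when
every peak set covers it), and consensus peaks separated by no more than a
merge gap (150 kb by default) are joined into uninterrupted centromeric
units. Per-chromosome unit statistics (count, density in units/Mb, length
summaries) describe the holocentric organization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import (
    GenomeIndex,
    Interval,
    IntervalSet,
    intersect_intervals,
    merge_with_counts,
)

__all__ = [
    "PeakSets",
    "CentromericUnit",
    "consensus_peaks",
    "build_units",
    "unit_stats",
    "units_to_interval_set",
]

DEFAULT_MERGE_GAP = 150_000

PEAK_SET_KEYS = (("A", 1), ("A", 2), ("B", 1), ("B", 2))


@dataclass
class PeakSets:
    """Exactly four peak sets: callers A/B x replicates 1/2."""

    sets: dict[tuple[str, int], IntervalSet]

    def __post_init__(self) -> None:
        missing = [k for k in PEAK_SET_KEYS if k not in self.sets]
        if missing or len(self.sets) != 4:
            raise ValueError(
                f"need exactly the four peak sets {PEAK_SET_KEYS}, "
                f"missing {missing}, got {sorted(self.sets)}"
            )


@dataclass(frozen=True)
class CentromericUnit:
    """A merged CENH3 domain and the number of consensus peaks it absorbed."""

    interval: Interval
    source_peak_count: int

    def __post_init__(self) -> None:
        if self.source_peak_count < 1:
            raise ValueError("a unit must derive from >= 1 peak")

    def __len__(self) -> int:
        return len(self.interval)


def consensus_peaks(peaks: PeakSets, genome: GenomeIndex | None = None) -> IntervalSet:
    """Base-level intersection of the four peak sets.

    A genomic position belongs to the consensus only if all four sets cover
    it; maximal covered intervals are returned. The operation is symmetric
    in its four inputs.
    """
    if genome is not None:
        for ivset in peaks.sets.values():
            genome.validate(ivset)
    sets = [peaks.sets[k] for k in PEAK_SET_KEYS]
    acc = sets[0]
    for other in sets[1:]:
        acc, _ = intersect_intervals(acc, other)
    acc.name = "consensus_peaks"
    return acc


def build_units(
    consensus: IntervalSet, merge_gap: int = DEFAULT_MERGE_GAP, min_length: int = 0
) -> list[CentromericUnit]:
    """Merge consensus peaks closer than ``merge_gap`` into centromeric units.

    ``source_peak_count`` records how many consensus peaks each unit
    absorbed. Units shorter than ``min_length`` are dropped (default keeps
    everything).
    """
    units = [
        CentromericUnit(iv, count)
        for iv, count in merge_with_counts(consensus, merge_gap)
        if len(iv) >= min_length
    ]
    return units


def units_to_interval_set(units: list[CentromericUnit]) -> IntervalSet:
    return IntervalSet([u.interval for u in units], name="centromeric_units")


def unit_stats(units: list[CentromericUnit], genome: GenomeIndex) -> pd.DataFrame:
    """Per-chromosome and genome-wide unit statistics.

    Columns: chrom, chrom_length, unit_count, density (units/Mb) and length
    summaries in bp. Size statistics are NaN where a chromosome carries no
    unit. The final row aggregates the whole genome.
    """
    ivset = units_to_interval_set(units)
    genome.validate(ivset)
    rows = []
    all_lengths = []
    for chrom in sorted(genome.chrom_sizes):
        length = genome.chrom_sizes[chrom]
        arr = ivset.coords(chrom)
        sizes = (arr[:, 1] - arr[:, 0]).astype(float)
        all_lengths.append(sizes)
        rows.append(_stat_row(chrom, length, sizes))
    sizes = np.concatenate(all_lengths) if all_lengths else np.empty(0)
    rows.append(_stat_row("genome", genome.total_length, sizes))
    return pd.DataFrame(rows)


def _stat_row(chrom: str, length: int, sizes: np.ndarray) -> dict:
    n = len(sizes)
    return {
        "chrom": chrom,
        "chrom_length": length,
        "unit_count": n,
        "density_per_mb": n / (length / 1e6) if length else 0.0,
        "mean_length": float(sizes.mean()) if n else float("nan"),
        "median_length": float(np.median(sizes)) if n else float("nan"),
        "min_length": float(sizes.min()) if n else float("nan"),
        "max_length": float(sizes.max()) if n else float("nan"),
    }
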