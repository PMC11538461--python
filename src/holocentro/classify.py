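"""Functional vs. nonfunctional satellite array classification.

An array is *functional* when it overlaps a CENH3 centromeric unit (by at
least ``min_overlap`` bases, default 1 bp) and *nonfunctional* otherwise.
The base-level intersection of a functional array with the units is its set
of *functional array fragments* — the precise spans where centromeric
satellite and CENH3 chromatin coincide. Units overlapping no satellite of
any family are *satellite-free*; units are otherwise labeled with every
family they touch (labels are not mutually exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .domains import CentromericUnit, units_to_interval_set
from .intervals import (
    Interval,
    IntervalSet,
    intersect_intervals,
    merge_intervals,
)
from .satellites import SatelliteArray
from .stats import TestResult, mann_whitney_u

__all__ = [
    "ClassifiedArray",
    "classify_arrays",
    "classification_summary",
    "satellite_free_units",
    "label_units",
    "domain_composition",
    "compare_array_sizes",
]


@dataclass
class ClassifiedArray:
    array: SatelliteArray
    status: str  # "functional" | "nonfunctional"
    fragments: IntervalSet = field(default_factory=IntervalSet)
    overlap_bases: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("functional", "nonfunctional"):
            raise ValueError(f"unknown status {self.status!r}")


def classify_arrays(
    arrays: list[SatelliteArray],
    units: list[CentromericUnit],
    min_overlap: int = 1,
) -> list[ClassifiedArray]:
    """Assign every array a functional/nonfunctional status.

    Fragments are the base-level intersection of the array span with the
    centromeric units; status is functional iff the fragment total reaches
    ``min_overlap`` bases.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    unit_set = units_to_interval_set(units)
    out = []
    for arr in arrays:
        single = IntervalSet([arr.interval])
        frags, overlap = intersect_intervals(single, unit_set)
        status = "functional" if overlap >= min_overlap else "nonfunctional"
        out.append(
            ClassifiedArray(
                array=arr,
                status=status,
                fragments=frags if status == "functional" else IntervalSet(),
                overlap_bases=overlap if status == "functional" else 0,
            )
        )
    return out


def classification_summary(classified: list[ClassifiedArray]) -> pd.DataFrame:
    """Per-family counts, base totals and functional fractions.

    Mirrors the reporting style 'x out of n arrays (f%) overlap CENH3
    domains; overlapping bases y out of z in total'.
    """
    rows = []
    families = sorted({c.array.family for c in classified})
    for fam in families:
        fam_arrays = [c for c in classified if c.array.family == fam]
        functional = [c for c in fam_arrays if c.status == "functional"]
        nonfunctional = [c for c in fam_arrays if c.status == "nonfunctional"]
        total_bases = sum(len(c.array) for c in fam_arrays)
        overlap_bases = sum(c.overlap_bases for c in functional)
        rows.append(
            {
                "family": fam,
                "array_count_total": len(fam_arrays),
                "functional_count": len(functional),
                "nonfunctional_count": len(nonfunctional),
                "functional_fraction": len(functional) / len(fam_arrays),
                "total_bases": total_bases,
                "functional_overlap_bases": overlap_bases,
                "overlap_base_fraction": (
                    overlap_bases / total_bases if total_bases else 0.0
                ),
                "mean_length_functional": (
                    sum(len(c.array) for c in functional) / len(functional)
                    if functional
                    else float("nan")
                ),
                "mean_length_nonfunctional": (
                    sum(len(c.array) for c in nonfunctional) / len(nonfunctional)
                    if nonfunctional
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def satellite_free_units(
    units: list[CentromericUnit], all_arrays: list[SatelliteArray]
) -> IntervalSet:
    """Units overlapping zero bases of any satellite array of any family."""
    array_set = IntervalSet([a.interval for a in all_arrays])
    free = []
    for unit in units:
        _, overlap = intersect_intervals(IntervalSet([unit.interval]), array_set)
        if overlap == 0:
            free.append(unit.interval)
    return IntervalSet(free, name="satellite_free_units")


def label_units(
    units: list[CentromericUnit],
    arrays_by_family: dict[str, list[SatelliteArray]],
) -> list[tuple[Interval, frozenset[str]]]:
    """Label every unit with each family it overlaps by >= 1 bp.

    Labels are not mutually exclusive; an empty label set marks a
    satellite-free unit.
    """
    family_sets = {
        fam: IntervalSet([a.interval for a in arrs])
        for fam, arrs in arrays_by_family.items()
    }
    out = []
    for unit in units:
        single = IntervalSet([unit.interval])
        labels = frozenset(
            fam
            for fam, fset in family_sets.items()
            if intersect_intervals(single, fset)[1] > 0
        )
        out.append((unit.interval, labels))
    return out


def domain_composition(
    domains: IntervalSet, annotations: dict[str, IntervalSet]
) -> dict[str, float]:
    """Base fraction of the domains covered by each annotation class.

    Classes may overlap each other, so fractions need not sum to 1.
    """
    total = merge_intervals(domains).total_bases
    if total == 0:
        raise ValueError("domains are empty")
    return {
        cls: intersect_intervals(domains, track)[1] / total
        for cls, track in annotations.items()
    }


def compare_array_sizes(
    classified: list[ClassifiedArray],
) -> dict[str, tuple[TestResult, float, float]]:
    """Two-sided Mann–Whitney U on array lengths, functional vs nonfunctional.

    Returns per family (test, mean functional length, mean nonfunctional
    length). Families with an empty group raise.
    """
    out: dict[str, tuple[TestResult, float, float]] = {}
    for fam in sorted({c.array.family for c in classified}):
        func = [len(c.array) for c in classified
                if c.array.family == fam and c.status == "functional"]
        nonf = [len(c.array) for c in classified
                if c.array.family == fam and c.status == "nonfunctional"]
        if not func or not nonf:
            raise ValueError(
                f"family {fam!r}: both status groups must be non-empty "
                f"(functional={len(func)}, nonfunctional={len(nonf)})"
            )
        res = mann_whitney_u(func, nonf, alternative="two-sided")
        out[fam] = (res, sum(func) / len(func), sum(nonf) / len(nonf))
    return out
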