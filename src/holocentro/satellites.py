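"""Satellite array detection by monomer scanning.

A satellite family is represented by its consensus monomer. Arrays are
found BLAST-like: exact k-mer seeds against all rotations of the monomer
(both strands) anchor a monomer-phased grid; every grid copy is scored by
ungapped per-base identity against the consensus; copies above the identity
threshold are merged into arrays when their gaps stay small. The same
machinery with the 7-bp plant telomere monomer (TTTAGGG) annotates
telomere-like arrays and flags interstitial telomeric sites (ITS) — arrays
far from both chromosome ends, footprints of ancestral chromosome fusions.

The scan assumes a substitution-only divergence model (no indels within a
copy); gaps between well-preserved copies are absorbed by the merge step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomeIndex, Interval, IntervalSet
from .sequence import encode, kmer_codes, revcomp

__all__ = [
    "Monomer",
    "SatelliteArray",
    "TELOMERE_MONOMER",
    "scan_monomer_arrays",
    "scan_its",
    "arrays_to_interval_set",
]

TELOMERE_MONOMER = "TTTAGGG"  # Arabidopsis-type plant telomere repeat


@dataclass(frozen=True)
class Monomer:
    """A satellite family consensus monomer."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 5:
            raise ValueError("monomer must be at least 5 bp")
        if set(seq) - set("ACGT"):
            raise ValueError("monomer alphabet must be A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SatelliteArray:
    """A detected tandem array of one satellite family."""

    interval: Interval
    family: str
    copy_estimate: float
    mean_identity: float
    n_matches: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_identity <= 1.0:
            raise ValueError("mean_identity must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.interval)


def _seed_map(monomer_seq: str, k: int) -> dict[int, int]:
    """code -> monomer offset for every k-mer of the doubled monomer.

    Doubling covers k-mers spanning the copy junction, so a seed can anchor
    any rotation of the repeat phase.
    """
    doubled = monomer_seq + monomer_seq
    codes, valid = kmer_codes(encode(doubled), k)
    m = len(monomer_seq)
    out: dict[int, int] = {}
    for j in range(m):
        if valid[j] and codes[j] not in out:
            out[int(codes[j])] = j
    return out


def _grid_copies(
    chrom_arr: np.ndarray,
    ref_arr: np.ndarray,
    seeds: np.ndarray,
    seed_offsets: dict[int, int],
    seed_codes: np.ndarray,
    group_gap: int,
    extend_copies: int,
) -> list[tuple[int, float]]:
    """Per-copy identities on monomer-phased grids anchored at seed clusters.

    Seeds closer than ``group_gap`` form a segment; the first seed fixes the
    phase, and the grid covers the segment plus ``extend_copies`` monomer
    lengths on each side. Returns (copy_start, identity) pairs.
    """
    m = len(ref_arr)
    n = len(chrom_arr)
    out: list[tuple[int, float]] = []
    if seeds.size == 0:
        return out
    # repeat phase of every seed; segments split where the seed gap is large
    # OR the phase shifts (e.g. across an insertion between copies)
    phases = np.array(
        [(int(s) - seed_offsets[int(c)]) % m for s, c in zip(seeds, seed_codes)]
    )
    new_seg = np.empty(seeds.size, dtype=bool)
    new_seg[0] = True
    new_seg[1:] = (np.diff(seeds) > group_gap) | (np.diff(phases) != 0)
    seg_bounds = np.concatenate([np.flatnonzero(new_seg), [seeds.size]])
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        seg = seeds[a:b]
        j = seed_offsets[int(seed_codes[a])]
        anchor = int(seg[0]) - j
        lo = int(seg[0]) - extend_copies * m
        hi = int(seg[-1]) + (extend_copies + 1) * m
        first = anchor - ((anchor - lo) // m) * m
        for c in range(first, hi, m):
            if c < 0 or c + m > n:
                continue
            ident = float(np.count_nonzero(chrom_arr[c : c + m] == ref_arr)) / m
            out.append((c, ident))
    return out


def _scan_copies(
    genome: GenomeIndex,
    monomer_seq: str,
    seed_k: int,
    group_gap: int,
    extend_copies: int = 2,
) -> dict[str, np.ndarray]:
    """All monomer-phased copy scores per chromosome, both strands.

    Returns chrom -> array of (start, identity) sorted by start, deduplicated
    per start position keeping the best-scoring strand.
    """
    refs = [encode(monomer_seq), encode(revcomp(monomer_seq))]
    maps = [_seed_map(monomer_seq, seed_k), _seed_map(revcomp(monomer_seq), seed_k)]
    out: dict[str, np.ndarray] = {}
    for chrom in sorted(genome.chrom_sizes):
        chrom_arr = encode(genome.sequence(chrom))
        codes, valid = kmer_codes(chrom_arr, seed_k)
        copies: list[tuple[int, float]] = []
        for ref_arr, smap in zip(refs, maps):
            if not smap:
                continue
            keys = np.fromiter(smap.keys(), dtype=np.int64)
            hit = np.isin(codes, keys) & valid
            seeds = np.flatnonzero(hit)
            copies.extend(
                _grid_copies(
                    chrom_arr, ref_arr, seeds, smap, codes[seeds],
                    group_gap, extend_copies,
                )
            )
        if not copies:
            continue
        arr = np.array(copies, dtype=float)
        arr = arr[np.lexsort((-arr[:, 1], arr[:, 0]))]
        keep = np.ones(len(arr), dtype=bool)
        keep[1:] = np.diff(arr[:, 0]) != 0  # best strand per grid position
        out[chrom] = arr[keep]
    return out


def scan_monomer_arrays(
    genome: GenomeIndex,
    monomer: Monomer,
    min_identity: float = 0.95,
    merge_gap: int | None = None,
    seed_k: int = 11,
    min_copies: int = 2,
) -> list[SatelliteArray]:
    """Detect tandem arrays of ``monomer`` at the given identity threshold.

    Monomer-length matches with per-base identity >= ``min_identity`` are
    merged into one array when separated by at most ``merge_gap`` bp
    (default two monomer lengths); arrays spanning fewer than ``min_copies``
    monomer lengths are discarded. ``mean_identity`` averages the member
    match identities.
    """
    m = len(monomer)
    if m < seed_k:
        raise ValueError(
            f"monomer ({m} bp) shorter than seed k ({seed_k}); lower seed_k"
        )
    if merge_gap is None:
        merge_gap = 2 * m
    copies = _scan_copies(genome, monomer.sequence, seed_k, group_gap=m)
    arrays: list[SatelliteArray] = []
    for chrom, arr in copies.items():
        acc = arr[arr[:, 1] >= min_identity]
        if len(acc) == 0:
            continue
        starts = acc[:, 0].astype(np.int64)
        breaks = np.flatnonzero(starts[1:] - (starts[:-1] + m) > merge_gap)
        bounds = np.concatenate([[0], breaks + 1, [len(acc)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            s = int(starts[a])
            e = int(starts[b - 1]) + m
            if e - s < min_copies * m:
                continue
            arrays.append(
                SatelliteArray(
                    interval=Interval(chrom, s, e),
                    family=monomer.name,
                    copy_estimate=(e - s) / m,
                    mean_identity=float(acc[a:b, 1].mean()),
                    n_matches=b - a,
                )
            )
    return arrays


def scan_its(
    genome: GenomeIndex,
    min_len: int = 200,
    stringencies: tuple[float, ...] = (0.75, 0.90),
    merge_gap: int = 10_000,
    terminal_margin: int = 10_000,
    monomer_seq: str = TELOMERE_MONOMER,
    copy_join_gap: int = 50,
) -> dict[float, IntervalSet]:
    """Annotate telomere-like arrays at each stringency level.

    For each stringency s, three stages:

    1. telomere-monomer copies with per-copy identity >= s are joined into
       candidate regions when separated by at most ``copy_join_gap`` bp
       (tight, so chance isolated matches stay isolated);
    2. a candidate qualifies when it is strictly longer than ``min_len``
       AND its aggregate similarity — mean identity over all phased copies
       it spans — reaches s (this is what distinguishes a 75 %-similar
       region from a 90 %-similar one);
    3. qualifying regions closer than ``merge_gap`` are merged.

    Regions farther than ``terminal_margin`` from both chromosome ends are
    flagged interstitial. Returns ``{stringency: IntervalSet}``; each
    interval carries attrs ``(flag, similarity)`` with flag
    ``"interstitial"`` or ``"terminal"``.
    """
    m = len(monomer_seq)
    copies = _scan_copies(
        genome, monomer_seq, seed_k=m, group_gap=max(10 * m, 100),
        extend_copies=4,
    )
    out: dict[float, IntervalSet] = {}
    for s_level in stringencies:
        intervals: list[Interval] = []
        for chrom, arr in copies.items():
            chrom_len = genome.chrom_sizes[chrom]
            starts = arr[:, 0].astype(np.int64)
            idents = arr[:, 1]
            acc = np.flatnonzero(idents >= s_level)
            if acc.size == 0:
                continue
            acc_starts = starts[acc]
            breaks = np.flatnonzero(
                acc_starts[1:] - (acc_starts[:-1] + m) > copy_join_gap
            )
            bounds = np.concatenate([[0], breaks + 1, [acc.size]])
            qualifying: list[tuple[int, int, float]] = []
            for a, b in zip(bounds[:-1], bounds[1:]):
                lo = int(acc_starts[a])
                hi = int(acc_starts[b - 1]) + m
                if hi - lo <= min_len:
                    continue
                inside = (starts >= lo) & (starts + m <= hi)
                similarity = float(idents[inside].mean()) if inside.any() else 0.0
                if similarity < s_level:
                    continue
                qualifying.append((lo, hi, similarity))
            # final merge of qualifying arrays closer than merge_gap
            merged: list[list[float]] = []
            for lo, hi, sim in qualifying:
                if merged and lo - merged[-1][1] <= merge_gap:
                    w_prev = merged[-1][1] - merged[-1][0]
                    w_new = hi - lo
                    merged[-1][2] = (
                        merged[-1][2] * w_prev + sim * w_new
                    ) / (w_prev + w_new)
                    merged[-1][1] = hi
                else:
                    merged.append([lo, hi, sim])
            for lo, hi, sim in merged:
                lo, hi = int(lo), int(hi)
                flag = (
                    "interstitial"
                    if lo > terminal_margin and hi < chrom_len - terminal_margin
                    else "terminal"
                )
                intervals.append(
                    Interval(chrom, lo, hi, attrs=(flag, f"{sim:.4f}"))
                )
        out[s_level] = IntervalSet(intervals, name=f"telomere_{s_level:g}")
    return out


def arrays_to_interval_set(
    arrays: list[SatelliteArray], name: str = ""
) -> IntervalSet:
    return IntervalSet(
        [
            Interval(
                a.interval.chrom,
                a.interval.start,
                a.interval.end,
                attrs=(a.family, f"{a.mean_identity:.4f}"),
            )
            for a in arrays
        ],
        name=name,
    )
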