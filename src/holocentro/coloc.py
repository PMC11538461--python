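"""Windowed feature matrices, correlograms, signal metaprofiles, fusion
regions from synteny, shuffle-based colocalization testing, and ancestral
centromere projection.

The colocalization test mirrors the bedtools-shuffle approach: query
regions are randomly re-placed across the genome (lengths preserved,
optionally avoiding an exclusion mask) for ``n_rounds`` rounds; the real
overlap proportion — overlapping bases divided by all bases the feature
covers — is ranked within the simulated distribution and reported as a
midrank percentile in [0, 100]. High percentiles indicate enrichment, low
percentiles depletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GenomeIndex,
    Interval,
    IntervalSet,
    intersect_intervals,
    merge_intervals,
)
from .io import SignalTrack
from .stats import bh_adjust, empirical_percentile, spearman_rho

__all__ = [
    "SyntenyBlock",
    "PermutationResult",
    "ProjectedCentromere",
    "window_feature_matrix",
    "correlogram",
    "rpkm_log2_ratio",
    "scaled_metaprofile",
    "fusion_regions_from_synteny",
    "shuffle_regions",
    "permutation_colocalization",
    "project_ancestral_centromeres",
    "read_synteny_blocks",
]


# -- feature matrix / correlogram -------------------------------------------


def window_feature_matrix(
    windows: IntervalSet,
    features: dict[str, IntervalSet | SignalTrack],
) -> pd.DataFrame:
    """Per-window feature values over genome-tiling windows.

    Interval features become covered-base proportions in [0, 1]; signal
    tracks become coverage-weighted means (spans missing from the track
    count as 0). Rows follow window order; the index holds
    ``chrom:start-end`` labels.
    """
    labels = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in windows]
    data: dict[str, np.ndarray] = {}
    for name, feat in features.items():
        col = np.zeros(len(labels))
        pos = 0
        for chrom in windows.chroms:
            warr = windows.coords(chrom)
            nw = len(warr)
            if isinstance(feat, SignalTrack):
                vals = _track_window_means(feat, chrom, warr)
            else:
                vals = _coverage_proportion(feat, chrom, warr)
            col[pos : pos + nw] = vals
            pos += nw
        data[name] = col
    return pd.DataFrame(data, index=labels)


def _coverage_proportion(
    feat: IntervalSet, chrom: str, windows: np.ndarray
) -> np.ndarray:
    widths = (windows[:, 1] - windows[:, 0]).astype(float)
    covered = np.zeros(len(windows))
    flat = merge_intervals(feat.restrict(chrom)).coords(chrom)
    if len(flat) == 0:
        return covered
    w0 = windows[0, 0]
    width = int(windows[0, 1] - windows[0, 0])  # uniform except last
    for s, e in flat:
        first = max(0, (s - w0) // width)
        last = min(len(windows) - 1, (e - 1 - w0) // width)
        for wi in range(int(first), int(last) + 1):
            lo = max(s, windows[wi, 0])
            hi = min(e, windows[wi, 1])
            if hi > lo:
                covered[wi] += hi - lo
    return covered / widths


class _TrackSummer:
    """O(1) range sums of value*length over a track chromosome."""

    def __init__(self, track: SignalTrack, chrom: str):
        if chrom in track.bins:
            self.starts, self.ends, values = track.bins[chrom]
            weights = values * (self.ends - self.starts)
            self.prefix = np.concatenate([[0.0], np.cumsum(weights)])
            self.values = values
        else:
            self.starts = np.empty(0, dtype=np.int64)
            self.ends = np.empty(0, dtype=np.int64)
            self.prefix = np.zeros(1)
            self.values = np.empty(0)

    def range_sum(self, s: int, e: int) -> float:
        """Sum of value*overlap for track bins intersecting [s, e)."""
        if self.starts.size == 0 or e <= s:
            return 0.0
        i = int(np.searchsorted(self.ends, s, side="right"))
        j = int(np.searchsorted(self.starts, e, side="left"))
        if i >= j:
            return 0.0
        total = float(self.prefix[j] - self.prefix[i])
        # trim partial coverage of the first and last bins
        if self.starts[i] < s:
            total -= float(self.values[i]) * (s - float(self.starts[i]))
        if self.ends[j - 1] > e:
            total -= float(self.values[j - 1]) * (float(self.ends[j - 1]) - e)
        return total


def _track_window_means(
    track: SignalTrack, chrom: str, windows: np.ndarray
) -> np.ndarray:
    summer = _TrackSummer(track, chrom)
    out = np.empty(len(windows))
    for wi, (s, e) in enumerate(windows):
        out[wi] = summer.range_sum(int(s), int(e)) / (e - s)
    return out


def correlogram(
    matrix: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations with BH-controlled significance.

    Returns (rho, adjusted p, mask) DataFrames; ``mask`` is True where a
    value should be greyed out — the diagonal and pairs whose BH-adjusted
    p exceeds ``alpha``. Constant columns are fully masked with a warning.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 windows")
    cols = list(matrix.columns)
    n = len(cols)
    constant = [c for c in cols if matrix[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant feature columns masked: {constant}", stacklevel=2)
    rho = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    pval = pd.DataFrame(np.ones((n, n)), index=cols, columns=cols)
    mask = pd.DataFrame(np.eye(n, dtype=bool), index=cols, columns=cols)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cols[i], cols[j]
            if a in constant or b in constant:
                mask.loc[a, b] = mask.loc[b, a] = True
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                continue
            res = spearman_rho(matrix[a].to_numpy(), matrix[b].to_numpy())
            rho.loc[a, b] = rho.loc[b, a] = res.statistic
            pairs.append((a, b, res.p_value))
    if pairs:
        adj = bh_adjust([p for _, _, p in pairs])
        for (a, b, _), q in zip(pairs, adj):
            pval.loc[a, b] = pval.loc[b, a] = q
            if q > alpha:
                mask.loc[a, b] = mask.loc[b, a] = True
    return rho, pval, mask


# -- signal normalization and metaprofiles -----------------------------------


def rpkm_log2_ratio(
    chip: SignalTrack,
    input_: SignalTrack,
    pseudocount: float | None = None,
    chip_library: float | None = None,
    input_library: float | None = None,
) -> SignalTrack:
    """log2 of the RPKM ratio ChIP / input, bin by bin.

    RPKM = count / (bin length in kb * mapped reads in millions); library
    sizes default to each track's total count. The pseudocount defaults to
    the RPKM one read would have in one full-size bin of the ChIP library,
    protecting empty bins without swamping real signal.
    """
    if not chip.same_binning(input_):
        raise ValueError("chip and input tracks must share identical binning")
    lib_c = chip_library if chip_library is not None else sum(
        float(v.sum()) for _, _, v in chip.bins.values()
    )
    lib_i = input_library if input_library is not None else sum(
        float(v.sum()) for _, _, v in input_.bins.values()
    )
    if lib_c <= 0 or lib_i <= 0:
        raise ValueError("library sizes must be positive")
    first = chip.bins[chip.chroms[0]]
    full_bin_kb = float(first[1][0] - first[0][0]) / 1000.0
    if pseudocount is None:
        pseudocount = 1.0 / (full_bin_kb * (lib_c / 1e6))
    bins = {}
    for chrom in chip.chroms:
        starts, ends, counts_c = chip.bins[chrom]
        counts_i = input_.bins[chrom][2]
        kb = (ends - starts) / 1000.0
        rpkm_c = counts_c / (kb * (lib_c / 1e6))
        rpkm_i = counts_i / (kb * (lib_i / 1e6))
        ratio = np.log2((rpkm_c + pseudocount) / (rpkm_i + pseudocount))
        bins[chrom] = (starts.copy(), ends.copy(), ratio)
    return SignalTrack(bins=bins, units="log2ratio", name=f"log2({chip.name}/{input_.name})")


@dataclass
class Metaprofile:
    """Mean signal over features scaled to a common body plus fixed flanks."""

    values: np.ndarray  # flank_bins + body_bins + flank_bins
    body_bins: int
    flank: int
    flank_bins: int
    n_features: int
    n_skipped: int

    @property
    def body(self) -> np.ndarray:
        return self.values[self.flank_bins : self.flank_bins + self.body_bins]


def scaled_metaprofile(
    track: SignalTrack,
    features: IntervalSet,
    body_bins: int = 100,
    flank: int = 5000,
    flank_bins: int = 50,
) -> Metaprofile:
    """deeptools-like scale-regions profile of ``track`` over ``features``.

    Each feature body is split into ``body_bins`` equal sub-spans; flanks of
    fixed width ``flank`` are split into ``flank_bins`` bins each side.
    Features on the minus strand (a ``-`` among their attributes) are
    flipped. Features shorter than ``body_bins`` bases are skipped and
    counted. The profile is the unweighted mean across features.
    """
    if len(features) == 0:
        raise ValueError("features are empty")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    total_bins = 2 * flank_bins + body_bins
    acc = np.zeros(total_bins)
    cnt = np.zeros(total_bins)
    n_used = n_skipped = 0
    summers = {chrom: _TrackSummer(track, chrom) for chrom in features.chroms}
    for iv in features:
        length = len(iv)
        if length < body_bins:
            n_skipped += 1
            continue
        summer = summers[iv.chrom]
        edges = np.concatenate(
            [
                np.linspace(iv.start - flank, iv.start, flank_bins + 1)[:-1]
                if flank_bins
                else [],
                np.linspace(iv.start, iv.end, body_bins + 1)[:-1],
                np.linspace(iv.end, iv.end + flank, flank_bins + 1)
                if flank_bins
                else [iv.end],
            ]
        )
        vals = np.empty(total_bins)
        ok = np.ones(total_bins, dtype=bool)
        for b in range(total_bins):
            s, e = edges[b], edges[b + 1]
            if e <= 0 or s < 0:
                ok[b] = False
                continue
            vals[b] = summer.range_sum(int(round(s)), int(round(e))) / (e - s)
        if "-" in iv.attrs:
            vals = vals[::-1]
            ok = ok[::-1]
        acc[ok] += vals[ok]
        cnt[ok] += 1
        n_used += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return Metaprofile(
        values=profile,
        body_bins=body_bins,
        flank=flank,
        flank_bins=flank_bins,
        n_features=n_used,
        n_skipped=n_skipped,
    )


# -- synteny and fusion regions ----------------------------------------------


@dataclass(frozen=True)
class SyntenyBlock:
    """A conserved block between the target (holocentric) genome and a
    reference genome."""

    target: Interval
    source: Interval
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")


def read_synteny_blocks(path: str) -> list[SyntenyBlock]:
    """Read a synteny block TSV (target_chrom, target_start, target_end,
    source_chrom, source_start, source_end, orientation)."""
    df = pd.read_csv(path, sep="\t")
    required = [
        "target_chrom", "target_start", "target_end",
        "source_chrom", "source_start", "source_end", "orientation",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing synteny columns {missing}")
    return [
        SyntenyBlock(
            target=Interval(r.target_chrom, int(r.target_start), int(r.target_end)),
            source=Interval(r.source_chrom, int(r.source_start), int(r.source_end)),
            orientation=str(r.orientation),
        )
        for r in df.itertuples()
    ]


def write_synteny_blocks(blocks: list[SyntenyBlock], path: str) -> None:
    rows = [
        {
            "target_chrom": b.target.chrom,
            "target_start": b.target.start,
            "target_end": b.target.end,
            "source_chrom": b.source.chrom,
            "source_start": b.source.start,
            "source_end": b.source.end,
            "orientation": b.orientation,
        }
        for b in blocks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def fusion_regions_from_synteny(
    blocks: list[SyntenyBlock],
    flank: int = 50_000,
    large_gap: int = 100_000,
) -> tuple[IntervalSet, IntervalSet]:
    """Flanks and large fusion regions around inter-block gaps.

    For each gap between consecutive blocks on a target chromosome, two
    ``flank``-wide intervals just inside the block edges facing the gap are
    emitted (clipped at the block's far end); the gap itself becomes a
    fusion region iff it is longer than ``large_gap``.
    """
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.target.chrom, []).append(b)
    flanks: list[Interval] = []
    fusions: list[Interval] = []
    for chrom, bl in by_chrom.items():
        bl.sort(key=lambda b: b.target.start)
        for left, right in zip(bl[:-1], bl[1:]):
            if right.target.start < left.target.end:
                raise ValueError(
                    f"overlapping synteny blocks on {chrom}: "
                    f"{left.target} / {right.target}"
                )
            gap = right.target.start - left.target.end
            if gap <= 0:
                continue
            flanks.append(
                Interval(
                    chrom,
                    max(left.target.start, left.target.end - flank),
                    left.target.end,
                )
            )
            flanks.append(
                Interval(
                    chrom,
                    right.target.start,
                    min(right.target.end, right.target.start + flank),
                )
            )
            if gap > large_gap:
                fusions.append(Interval(chrom, left.target.end, right.target.start))
    return (
        IntervalSet(flanks, name="fusion_flanks"),
        IntervalSet(fusions, name="large_fusion_regions"),
    )


# -- shuffle test ------------------------------------------------------------


def shuffle_regions(
    regions: IntervalSet,
    genome: GenomeIndex,
    exclusion: IntervalSet | None = None,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 1000,
    per_chromosome: bool = False,
) -> IntervalSet:
    """Randomly re-place each region, preserving its length.

    The chromosome is drawn with probability proportional to its length
    (or kept fixed with ``per_chromosome=True``) and the start uniformly
    among valid positions. Placed regions never overlap each other nor the
    exclusion mask. Deterministic for a given Generator state or seed.
    """
    rng = np.random.default_rng(rng)
    chroms = sorted(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    blocked: dict[str, list[tuple[int, int]]] = {}
    for c in chroms:
        coords = (
            merge_intervals(exclusion.restrict(c)).coords(c)
            if exclusion is not None
            else np.empty((0, 2), dtype=np.int64)
        )
        blocked[c] = [(int(s), int(e)) for s, e in coords]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    todo = sorted(regions, key=len, reverse=True)  # big ones while space lasts
    for iv in todo:
        length = len(iv)
        success = False
        for _ in range(max_retries):
            chrom = iv.chrom if per_chromosome else (
                chroms[int(rng.choice(len(chroms), p=probs))]
            )
            start = _sample_start(
                rng, genome.chrom_sizes[chrom], length, blocked[chrom]
            )
            if start is None:
                continue
            _insert_sorted(blocked[chrom], (start, start + length))
            placed[chrom].append((start, start + length))
            success = True
            break
        if not success:
            densest = max(
                chroms,
                key=lambda c: sum(e - s for s, e in blocked[c])
                / genome.chrom_sizes[c],
            )
            raise RuntimeError(
                f"could not place a {length}-bp region after {max_retries} "
                f"retries; densest chromosome is {densest}"
            )
    out = IntervalSet(
        [Interval(c, s, e) for c, ivs in placed.items() for s, e in ivs],
        name=f"shuffled_{regions.name}",
    )
    return out


def _sample_start(
    rng: np.random.Generator,
    chrom_len: int,
    length: int,
    blocked: list[tuple[int, int]],
) -> int | None:
    """Uniform draw among all starts placing [start, start+length) in a gap
    of the blocked list; None when no gap fits."""
    slots: list[tuple[int, int]] = []  # (first valid start, count)
    total = 0
    prev = 0
    for bs, be in blocked + [(chrom_len, chrom_len)]:
        gap = bs - prev
        if gap >= length:
            count = gap - length + 1
            slots.append((prev, count))
            total += count
        prev = max(prev, be)
    if total == 0:
        return None
    pick = int(rng.integers(0, total))
    for first, count in slots:
        if pick < count:
            return first + pick
        pick -= count
    raise AssertionError("unreachable")


def _insert_sorted(blocked: list[tuple[int, int]], span: tuple[int, int]) -> None:
    import bisect

    bisect.insort(blocked, span)


@dataclass
class PermutationResult:
    feature_name: str
    real_overlap_proportion: float
    simulated: np.ndarray
    percentile: float
    n_rounds: int
    seed: int | None
    p_greater: float = field(init=False)
    p_less: float = field(init=False)

    def __post_init__(self) -> None:
        sims = np.asarray(self.simulated, dtype=float)
        n = sims.size
        real = self.real_overlap_proportion
        # permutation p-values with the +1 correction
        self.p_greater = (1 + int((sims >= real).sum())) / (n + 1)
        self.p_less = (1 + int((sims <= real).sum())) / (n + 1)
        expected = empirical_percentile(real, sims)
        if abs(expected - self.percentile) > 1e-9:
            raise ValueError("percentile inconsistent with simulated values")


def permutation_colocalization(
    regions: IntervalSet,
    feature: IntervalSet,
    genome: GenomeIndex,
    n_rounds: int = 1000,
    exclusion: IntervalSet | None = None,
    seed: int | None = None,
    per_chromosome: bool = False,
) -> PermutationResult:
    """Shuffle-based colocalization test of ``regions`` against ``feature``.

    The statistic is the proportion of feature-covered bases that the
    (real or shuffled) regions overlap. The real statistic's midrank
    percentile within ``n_rounds`` simulated statistics is reported.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    feature_bases = merge_intervals(feature).total_bases
    if feature_bases == 0:
        raise ValueError("feature is empty")
    rng = np.random.default_rng(seed)

    def proportion(q: IntervalSet) -> float:
        return intersect_intervals(q, feature)[1] / feature_bases

    real = proportion(regions)
    sims = np.empty(n_rounds)
    for r in range(n_rounds):
        shuffled = shuffle_regions(
            regions, genome, exclusion=exclusion, rng=rng,
            per_chromosome=per_chromosome,
        )
        sims[r] = proportion(shuffled)
    return PermutationResult(
        feature_name=feature.name,
        real_overlap_proportion=real,
        simulated=sims,
        percentile=empirical_percentile(real, sims),
        n_rounds=n_rounds,
        seed=seed,
    )


# -- ancestral centromere projection -----------------------------------------


@dataclass
class ProjectedCentromere:
    source: Interval
    target: Interval | None
    oversized: bool
    note: str = ""


def project_ancestral_centromeres(
    blocks: list[SyntenyBlock],
    source_centromeres: IntervalSet,
    oversize_factor: float = 5.0,
) -> list[ProjectedCentromere]:
    """Project reference-genome centromeres onto the target genome.

    A centromere fully inside one block is mapped by linear interpolation
    through that block. Otherwise the nearest flanking blocks on each side
    fix the projection as the span between their target-genome images; a
    projection more than ``oversize_factor`` times the source centromere
    length is flagged oversized. Centromeres lacking a flanking block on
    either side are reported unprojectable.
    """
    by_source: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_source.setdefault(b.source.chrom, []).append(b)
    for bl in by_source.values():
        bl.sort(key=lambda b: b.source.start)
    out: list[ProjectedCentromere] = []
    for cen in source_centromeres:
        bl = by_source.get(cen.chrom, [])
        container = next(
            (b for b in bl if b.source.start <= cen.start and cen.end <= b.source.end),
            None,
        )
        if container is not None:
            target = _interpolate(container, cen)
        else:
            left = max(
                (b for b in bl if b.source.end <= cen.start),
                key=lambda b: b.source.end,
                default=None,
            )
            right = min(
                (b for b in bl if b.source.start >= cen.end),
                key=lambda b: b.source.start,
                default=None,
            )
            if left is None or right is None:
                out.append(
                    ProjectedCentromere(cen, None, False, "no flanking block")
                )
                continue
            if left.target.chrom != right.target.chrom:
                out.append(
                    ProjectedCentromere(
                        cen, None, False, "flanking blocks on different target chromosomes"
                    )
                )
                continue
            lo = min(left.target.end, right.target.end)
            hi = max(left.target.start, right.target.start)
            if hi <= lo:  # target images overlap or touch; fall back to union span
                lo = min(left.target.start, right.target.start)
                hi = max(left.target.end, right.target.end)
            target = Interval(left.target.chrom, int(lo), int(hi))
        oversized = len(target) > oversize_factor * len(cen)
        out.append(ProjectedCentromere(cen, target, oversized))
    return out


def _interpolate(block: SyntenyBlock, cen: Interval) -> Interval:
    src_len = len(block.source)
    tgt_len = len(block.target)
    scale = tgt_len / src_len

    def map_pos(pos: int) -> float:
        off = pos - block.source.start
        if block.orientation == "+":
            return block.target.start + off * scale
        return block.target.end - off * scale

    a, b = map_pos(cen.start), map_pos(cen.end)
    lo, hi = (a, b) if a <= b else (b, a)
    return Interval(block.target.chrom, int(round(lo)), max(int(round(hi)), int(round(lo)) + 1))
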