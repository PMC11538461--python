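"""Array homogeneity by windowed k-mer identity.

Sequences of one group (functional array fragments, or whole nonfunctional
arrays) are concatenated in genome order; non-overlapping windows that
never span a source boundary are compared pairwise by the Jaccard index J
of their canonical k-mer sets, converted to an average-nucleotide-identity
estimate through the Mash distance formula:

    identity = 1 + (1/k) * ln(2J / (1 + J))        (0 when J = 0)

Exact k-mer sets are used rather than sketches — at the scale of satellite
array groups, sketching buys nothing and removes determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import GenomeIndex, Interval, IntervalSet
from .sequence import canonical_kmer_set

__all__ = [
    "WindowIndex",
    "IdentityMatrix",
    "concatenate_group",
    "identity_matrix",
    "similarity_summary",
]


@dataclass(frozen=True)
class WindowIndex:
    """Maps each concatenation window back to its source coordinates."""

    source: Interval  # genomic interval the window came from
    local_span: tuple[int, int]  # within the concatenated sequence
    source_span: tuple[int, int]  # genomic coordinates of the window


@dataclass
class IdentityMatrix:
    windows: list[WindowIndex]
    values: np.ndarray  # symmetric, diagonal 1
    k: int
    window: int

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.windows), len(self.windows)):
            raise ValueError("matrix shape does not match window count")
        if len(self.windows):
            if not np.allclose(v, v.T):
                raise ValueError("identity matrix must be symmetric")
            if ((v < 0) | (v > 1)).any():
                raise ValueError("identities must lie in [0, 1]")


def concatenate_group(
    group: IntervalSet, genome: GenomeIndex, window: int = 5000
) -> tuple[str, list[WindowIndex]]:
    """Concatenate group sequences and index windows that respect sources.

    Windows are laid out per source interval so none crosses a
    concatenation join; a short terminal window per source is kept only if
    it reaches ``window / 2``. Sources too short to yield any window are
    skipped with a warning.
    """
    if len(group) == 0:
        raise ValueError("group is empty")
    genome.validate(group)
    parts: list[str] = []
    windows: list[WindowIndex] = []
    offset = 0
    for iv in group:
        seq = genome.fetch(iv)
        length = len(seq)
        pos = 0
        emitted = 0
        while pos < length:
            end = min(pos + window, length)
            if end - pos >= max(window // 2, 1):
                windows.append(
                    WindowIndex(
                        source=iv,
                        local_span=(offset + pos, offset + end),
                        source_span=(iv.start + pos, iv.start + end),
                    )
                )
                emitted += 1
            pos = end
        if emitted == 0:
            warnings.warn(
                f"source {iv.chrom}:{iv.start}-{iv.end} shorter than half a "
                f"window ({window} bp); no window emitted",
                stacklevel=2,
            )
        parts.append(seq)
        offset += length
    return "".join(parts), windows


def _jaccard_identity(a: set[int], b: set[int], k: int) -> float:
    union = len(a | b)
    if union == 0:
        return 0.0
    j = len(a & b) / union
    if j == 0.0:
        return 0.0
    return max(0.0, 1.0 + np.log(2.0 * j / (1.0 + j)) / k)


def identity_matrix(
    seq: str, windows: list[WindowIndex], k: int = 21, window: int = 5000
) -> IdentityMatrix:
    """Pairwise ANI estimates between all windows of a concatenated group."""
    if window < 10 * k:
        raise ValueError(f"window ({window}) must be >= 10*k ({10 * k})")
    sets = [
        canonical_kmer_set(seq[w.local_span[0] : w.local_span[1]], k)
        for w in windows
    ]
    n = len(windows)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _jaccard_identity(sets[i], sets[j], k)
    return IdentityMatrix(windows=windows, values=values, k=k, window=window)


def similarity_summary(
    matrix: IdentityMatrix, label: str = "", bin_width: float = 1.0
) -> dict:
    """Mean off-diagonal identity (percent) plus a similarity histogram.

    The histogram covers [0, 100] percent with ``bin_width``-point bins.
    """
    n = len(matrix.windows)
    if n < 2:
        raise ValueError("need at least 2 windows to summarize similarity")
    iu = np.triu_indices(n, k=1)
    vals = matrix.values[iu] * 100.0
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    return {
        "label": label,
        "n_windows": n,
        "n_pairs": vals.size,
        "mean_similarity_pct": float(vals.mean()),
        "median_similarity_pct": float(np.median(vals)),
        "histogram_edges": edges,
        "histogram_counts": counts,
    }
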