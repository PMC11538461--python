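"""Readers and writers for the plain-text genomics formats the pipeline touches.

Supported: BED3+ (0-based half-open), GFF3 (1-based inclusive, converted on
read), bedGraph (4 columns, half-open spans), FASTA and two-column
chromosome-sizes TSV. Genomes at the scale this package targets fit in
memory, so FASTA sequences are loaded eagerly as uppercase strings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .intervals import GenomeIndex, Interval, IntervalSet

__all__ = [
    "ParseError",
    "SignalTrack",
    "read_intervals",
    "write_intervals",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_chrom_sizes",
]


class ParseError(ValueError):
    """Malformed line in an input file; message names the file and line."""


@dataclass
class SignalTrack:
    """Per-bin numeric values over the genome.

    ``bins`` maps chromosome -> (starts, ends, values) arrays: sorted,
    non-overlapping, uniform width except a possibly short terminal bin.
    ``units`` labels the quantity (reads, RPKM, log2ratio, percent).
    """

    bins: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    units: str = ""
    name: str = ""

    @property
    def chroms(self) -> list[str]:
        return sorted(self.bins)

    def values(self, chrom: str) -> np.ndarray:
        return self.bins[chrom][2]

    def same_binning(self, other: "SignalTrack") -> bool:
        if self.chroms != other.chroms:
            return False
        return all(
            np.array_equal(self.bins[c][0], other.bins[c][0])
            and np.array_equal(self.bins[c][1], other.bins[c][1])
            for c in self.chroms
        )

    @classmethod
    def from_windows(
        cls,
        windows: IntervalSet,
        values: Mapping[str, np.ndarray],
        units: str = "",
        name: str = "",
    ) -> "SignalTrack":
        bins = {}
        for chrom in windows.chroms:
            arr = windows.coords(chrom)
            v = np.asarray(values[chrom], dtype=float)
            if len(v) != len(arr):
                raise ValueError(f"value count mismatch on {chrom}")
            bins[chrom] = (arr[:, 0].copy(), arr[:, 1].copy(), v)
        return cls(bins=bins, units=units, name=name)


# -- interval I/O ------------------------------------------------------------


def _parse_bed_line(line: str, path: str, lineno: int) -> Interval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    if end <= start or start < 0:
        raise ParseError(f"{path}:{lineno}: invalid span [{start}, {end})")
    return Interval(fields[0], start, end, attrs=tuple(fields[3:]))


def _parse_gff3_line(line: str, path: str, lineno: int) -> Interval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 9:
        raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
    try:
        start, end = int(fields[3]), int(fields[4])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start < 1 or end < start:
        raise ParseError(f"{path}:{lineno}: invalid GFF3 span {start}..{end}")
    # 1-based inclusive -> 0-based half-open
    attrs = (fields[2], fields[6], fields[8])  # type, strand, attributes
    return Interval(fields[0], start - 1, end, attrs=attrs)


def read_intervals(path: str, format: str = "BED", name: str = "") -> IntervalSet:
    """Read a BED or GFF3 file into a sorted :class:`IntervalSet`.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    BED columns beyond the third are preserved as interval attributes.
    """
    fmt = format.upper()
    if fmt not in {"BED", "GFF3"}:
        raise ValueError(f"unsupported format {format!r}")
    parse = _parse_bed_line if fmt == "BED" else _parse_gff3_line
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(parse(line, path, lineno))
    return IntervalSet(intervals, name=name or os.path.basename(path))


def write_intervals(ivset: IntervalSet, path: str) -> None:
    """Write a sorted BED file; roundtrip with :func:`read_intervals` is the
    identity (extra columns included)."""
    with open(path, "w") as fh:
        for iv in ivset:
            extra = "".join(f"\t{a}" for a in iv.attrs)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{extra}\n")


# -- bedGraph ----------------------------------------------------------------


def read_bedgraph(path: str, units: str = "", name: str = "") -> SignalTrack:
    """Read a 4-column bedGraph; values apply to half-open spans.

    Spans absent from the file are not materialized — downstream consumers
    treat missing spans as value 0.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad bedGraph fields") from exc
            if e <= s:
                raise ParseError(f"{path}:{lineno}: invalid span [{s}, {e})")
            per_chrom.setdefault(fields[0], []).append((s, e, v))
    bins = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        arr = np.array(rows, dtype=float)
        starts = arr[:, 0].astype(np.int64)
        ends = arr[:, 1].astype(np.int64)
        if (starts[1:] < ends[:-1]).any():
            raise ParseError(f"{path}: overlapping bins on {chrom}")
        bins[chrom] = (starts, ends, arr[:, 2])
    return SignalTrack(bins=bins, units=units, name=name or os.path.basename(path))


def write_bedgraph(track: SignalTrack, path: str, precision: int = 6) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.bins[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.{precision}g}\n")


# -- FASTA -------------------------------------------------------------------


def read_fasta(path: str, load_sequences: bool = True) -> GenomeIndex:
    """Load a FASTA into a :class:`GenomeIndex` (sequences uppercased)."""
    sizes: dict[str, int] = {}
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is not None:
            seq = "".join(chunks).upper()
            sizes[name] = len(seq)
            if load_sequences:
                seqs[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        _flush()
    return GenomeIndex(chrom_sizes=sizes, sequences=seqs if load_sequences else None)


def write_fasta(genome: GenomeIndex, path: str, width: int = 70) -> None:
    if genome.sequences is None:
        raise ValueError("genome holds no sequences")
    with open(path, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: str) -> GenomeIndex:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom\\tlength'")
            sizes[fields[0]] = int(fields[1])
    return GenomeIndex(chrom_sizes=sizes)
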