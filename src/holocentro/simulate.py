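"""Synthetic holocentric genome generator with full ground truth.

Emulates the data shapes of a repeat-based holocentromere study on a small
multi-chromosome genome: tandem satellite arrays of tunable divergence
(monomer sizes default to the 124-bp and 174-bp classes typical of woodrush
centromeric satellites), CENH3 domains over a configurable fraction of
arrays plus satellite-free gene-poor loci, four noisy replicated peak sets
(two callers x two replicates: boundary jitter plus per-set unique false
positives), planted dyad symmetries, telomeric chromosome ends and
interstitial telomeric sites, ChIP/input and per-context methylation tracks
with border-elevated CHG/CHH over arrays, gene/TE/low-complexity
annotations placed preferentially outside arrays, and synteny blocks whose
inter-block gaps model chromosome-fusion regions with optional gene
enrichment.

Everything planted is recorded in a :class:`SyntheticTruth`, the oracle for
recovery tests. One master seed drives stable per-stage sub-seeding, so
identical specs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .coloc import SyntenyBlock, write_synteny_blocks
from .intervals import GenomeIndex, Interval, IntervalSet
from .io import SignalTrack, write_bedgraph, write_fasta, write_intervals
from .satellites import TELOMERE_MONOMER
from .sequence import revcomp

__all__ = [
    "FamilySpec",
    "GenomeSpec",
    "SyntheticTruth",
    "SyntheticDataset",
    "mutate_monomer",
    "random_monomer",
    "simulate_dataset",
    "write_dataset",
    "default_spec",
    "paper_shaped_spec",
]


@dataclass
class FamilySpec:
    """One satellite family: monomer, array counts and length model."""

    name: str
    monomer_length: int
    n_arrays: int
    functional_fraction: float
    divergence: float = 0.02  # per-base substitution rate per copy
    functional_length_mean: float = 18_900.0  # bp, log-normal location
    nonfunctional_length_mean: float = 2_000.0
    length_sigma: float = 0.4  # log-normal shape
    dyad_rate_functional: float = 1.2  # planted dyads per kb
    dyad_rate_nonfunctional: float = 0.2
    monomer_sequence: str | None = None  # random when None

    def __post_init__(self) -> None:
        if not 0.0 <= self.functional_fraction <= 1.0:
            raise ValueError("functional_fraction must lie in [0, 1]")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")


@dataclass
class GenomeSpec:
    """Full description of a synthetic dataset."""

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000,
                                 "chr3": 2_000_000}
    )
    gc: float = 0.33
    families: list[FamilySpec] = field(
        default_factory=lambda: [
            FamilySpec("Lusy1", 124, n_arrays=20, functional_fraction=0.35),
            FamilySpec("Lusy2", 174, n_arrays=16, functional_fraction=0.125,
                       functional_length_mean=9_400.0),
        ]
    )
    satellite_free_domains: int = 3
    satellite_free_length_mean: float = 15_000.0
    domain_separation: int = 165_000  # > default 150-kb merge gap
    peak_jitter: int = 200  # bp, per-boundary, per peak set
    false_positives_per_set: int = 5
    false_positive_length: int = 3_000
    bin_size: int = 100
    read_depth: float = 10.0  # mean input reads per bin
    chip_fold: float = 4.0  # CENH3 enrichment over domains
    methylation_base: dict[str, float] = field(
        default_factory=lambda: {"CpG": 30.0, "CHG": 20.0, "CHH": 5.0}
    )
    methylation_array: dict[str, float] = field(
        default_factory=lambda: {"CpG": 80.0, "CHG": 55.0, "CHH": 10.0}
    )
    border_gradient: dict[str, float] = field(
        default_factory=lambda: {"CpG": 0.0, "CHG": 15.0, "CHH": 8.0}
    )
    methylation_concentration: float = 60.0  # beta noise concentration
    telomere_copies: int = 50
    its_plantings: list[tuple[int, float]] = field(
        default_factory=lambda: [(300, 0.0), (300, 0.0)]
    )
    genes_per_chrom: int = 30
    gene_length: int = 2_000
    tes_per_chrom: int = 15
    te_length: int = 5_000
    lowcomp_per_chrom: int = 10
    lowcomp_length: int = 1_000
    blocks_per_chrom: int = 3
    large_fusion_gap: tuple[int, int] = (120_000, 200_000)
    small_fusion_gap: tuple[int, int] = (10_000, 50_000)
    fusion_gene_fold: float = 1.0  # >1 plants extra genes inside fusion gaps
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    chrom_sizes: dict[str, int]
    domains: list[dict]  # chrom, start, end, kind (family | satellite_free)
    arrays: list[dict]  # chrom, start, end, family, functional, divergence...
    peak_sets: dict[str, list[dict]]
    dyads: list[dict]
    its_sites: list[dict]
    telomeres: list[dict]
    synteny_blocks: list[dict]
    fusion_gaps: list[dict]
    seed: int

    def domain_set(self) -> IntervalSet:
        return IntervalSet(
            [Interval(d["chrom"], d["start"], d["end"]) for d in self.domains],
            name="true_domains",
        )

    def array_set(self, family: str | None = None) -> IntervalSet:
        return IntervalSet(
            [
                Interval(a["chrom"], a["start"], a["end"])
                for a in self.arrays
                if family is None or a["family"] == family
            ],
            name=f"true_arrays_{family or 'all'}",
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its ground truth."""

    spec: GenomeSpec
    genome: GenomeIndex
    truth: SyntheticTruth
    peak_sets: dict[tuple[str, int], IntervalSet]
    chip: SignalTrack
    input_: SignalTrack
    methylation: dict[str, SignalTrack]
    annotations: dict[str, IntervalSet]  # genes, TEs, low_complexity
    monomers: dict[str, str]
    synteny_blocks: list[SyntenyBlock]


# -- primitives --------------------------------------------------------------

_BASES = "ACGT"


def random_monomer(length: int, rng: np.random.Generator, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])


def mutate_monomer(sequence: str, mu: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``mu``.

    A substitution always changes the base (uniform over the three
    alternatives), so the expected Hamming divergence equals ``mu``.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    arr = np.array(list(sequence))
    hit = rng.random(arr.size) < mu
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.array(list(_BASES))[rng.choice(4, size=length, p=p)]


def _tandem_array(
    monomer: str,
    length: int,
    mu: float,
    rng: np.random.Generator,
    dyad_rate_per_kb: float = 0.0,
    dyad_stem: int = 12,
    dyad_loop: int = 5,
) -> tuple[str, list[tuple[int, int, int]]]:
    """Tandem copies of ``monomer`` mutated at rate ``mu``, with dyad
    symmetries inserted *between* copies so copy integrity is preserved.

    Returns (sequence of at least ``length`` bp, dyad records as
    (local offset, stem, loop)).
    """
    m = len(monomer)
    p_dyad = min(0.9, dyad_rate_per_kb * m / 1000.0)  # per inter-copy slot
    parts: list[str] = []
    dyads: list[tuple[int, int, int]] = []
    pos = 0
    n_copies = 0
    while pos < length:
        if n_copies >= 2 and p_dyad > 0 and rng.random() < p_dyad:
            stem = random_monomer(dyad_stem, rng)
            loop = random_monomer(dyad_loop, rng)
            insert = stem + loop + revcomp(stem)
            if pos + len(insert) <= length:
                dyads.append((pos, dyad_stem, dyad_loop))
                parts.append(insert)
                pos += len(insert)
                continue
        copy = mutate_monomer(monomer, mu, rng)
        parts.append(copy)
        pos += m
        n_copies += 1
    return "".join(parts), dyads


class _Placer:
    """Sequential placement with class-based clearances.

    Each placement samples uniformly among all starts that keep the new
    feature at least ``clearance[kind_of_neighbor]`` away from every
    already-placed feature (falling back to ``clearance['default']``) and
    ``end_margin`` away from chromosome ends. Only CENH3 domains require
    the large merge-gap separation from each other; everything else just
    avoids overlap plus a small buffer.
    """

    def __init__(self, length: int, rng: np.random.Generator, end_margin: int):
        self.length = length
        self.rng = rng
        self.end_margin = end_margin
        self.occupied: list[tuple[int, int, str]] = []  # start, end, kind

    def place(
        self,
        size: int,
        kind: str = "other",
        clearance: dict[str, int] | None = None,
    ) -> tuple[int, int]:
        clearance = clearance or {}
        default = clearance.get("default", 2_000)
        lo = self.end_margin
        hi = self.length - self.end_margin - size  # last valid start
        if hi < lo:
            raise ValueError(
                f"cannot fit a {size}-bp feature on a {self.length}-bp chromosome"
            )
        blocked = sorted(
            (
                os_ - clearance.get(k, default),
                oe + clearance.get(k, default),
            )
            for os_, oe, k in self.occupied
        )
        slots: list[tuple[int, int]] = []
        total = 0
        prev = lo
        for bs, be in blocked + [(hi + size + 1, hi + size + 1)]:
            last_ok = min(bs - size, hi)  # start keeping us clear of bs
            if last_ok >= prev:
                count = last_ok - prev + 1
                slots.append((prev, count))
                total += count
            prev = max(prev, be)
        if total == 0:
            raise ValueError(
                f"no room left for a {size}-bp {kind} feature "
                f"on a {self.length}-bp chromosome"
            )
        pick = int(self.rng.integers(0, total))
        for first, count in slots:
            if pick < count:
                s = first + pick
                break
            pick -= count
        e = s + size
        self.occupied.append((s, e, kind))
        return s, e


# -- generator ---------------------------------------------------------------


def simulate_dataset(spec: GenomeSpec) -> SyntheticDataset:
    """Generate the full synthetic dataset described by ``spec``."""
    root = np.random.SeedSequence(spec.seed)
    (
        ss_monomer, ss_layout, ss_seq, ss_peaks, ss_tracks,
        ss_annot, ss_synteny,
    ) = root.spawn(7)
    rng_mono = np.random.default_rng(ss_monomer)
    rng_layout = np.random.default_rng(ss_layout)
    rng_seq = np.random.default_rng(ss_seq)

    monomers = {
        f.name: (f.monomer_sequence or random_monomer(f.monomer_length, rng_mono))
        for f in spec.families
    }

    chroms = sorted(spec.chromosomes)
    sizes = dict(spec.chromosomes)
    tel_len = spec.telomere_copies * len(TELOMERE_MONOMER)

    # ---- layout: domains, arrays, ITS -------------------------------------
    arrays: list[dict] = []
    domains: list[dict] = []
    its_sites: list[dict] = []
    telomeres: list[dict] = []
    placers = {
        c: _Placer(sizes[c], rng_layout, end_margin=tel_len + 15_000)
        for c in chroms
    }

    def round_robin(n: int, offset: int = 0) -> list[str]:
        return [chroms[(i + offset) % len(chroms)] for i in range(n)]

    for fi, fam in enumerate(spec.families):
        n_func = int(round(fam.n_arrays * fam.functional_fraction))
        statuses = [True] * n_func + [False] * (fam.n_arrays - n_func)
        for ai, (chrom, functional) in enumerate(
            zip(round_robin(fam.n_arrays, offset=fi), statuses)
        ):
            mean = (
                fam.functional_length_mean if functional
                else fam.nonfunctional_length_mean
            )
            length = int(
                rng_layout.lognormal(np.log(mean), fam.length_sigma)
            )
            length = max(length, 3 * fam.monomer_length)
            if functional:
                s, e = placers[chrom].place(
                    length, kind="domain",
                    clearance={"domain": spec.domain_separation},
                )
            else:
                s, e = placers[chrom].place(length)
            arrays.append(
                {
                    "chrom": chrom, "start": s, "end": e, "family": fam.name,
                    "functional": functional, "divergence": fam.divergence,
                    "length": e - s,
                }
            )
            if functional:
                domains.append(
                    {"chrom": chrom, "start": s, "end": e, "kind": fam.name}
                )

    for i, chrom in enumerate(round_robin(spec.satellite_free_domains, offset=1)):
        length = int(
            rng_layout.lognormal(np.log(spec.satellite_free_length_mean), 0.3)
        )
        s, e = placers[chrom].place(
            length, kind="domain", clearance={"domain": spec.domain_separation}
        )
        domains.append(
            {"chrom": chrom, "start": s, "end": e, "kind": "satellite_free"}
        )

    for i, (its_len, its_mu) in enumerate(spec.its_plantings):
        chrom = chroms[i % len(chroms)]
        s, e = placers[chrom].place(
            its_len, kind="its", clearance={"its": 12_000, "default": 12_000}
        )
        its_sites.append(
            {"chrom": chrom, "start": s, "end": e, "divergence": its_mu}
        )

    # ---- sequence ----------------------------------------------------------
    sequences: dict[str, str] = {}
    dyads: list[dict] = []
    for chrom in chroms:
        seq = _random_background(sizes[chrom], spec.gc, rng_seq)
        # telomeric ends
        tel = (TELOMERE_MONOMER * spec.telomere_copies)
        seq[:tel_len] = list(tel)
        seq[sizes[chrom] - tel_len :] = list(revcomp(tel))
        telomeres.append({"chrom": chrom, "start": 0, "end": tel_len})
        telomeres.append(
            {"chrom": chrom, "start": sizes[chrom] - tel_len, "end": sizes[chrom]}
        )
        sequences[chrom] = seq  # ndarray for now; joined after edits

    for arr in arrays:
        fam = next(f for f in spec.families if f.name == arr["family"])
        rate = (
            fam.dyad_rate_functional if arr["functional"]
            else fam.dyad_rate_nonfunctional
        )
        body, local_dyads = _tandem_array(
            monomers[fam.name], arr["length"], fam.divergence, rng_seq,
            dyad_rate_per_kb=rate,
        )
        body = body[: arr["length"]]
        sequences[arr["chrom"]][arr["start"] : arr["end"]] = list(body)
        for pos, stem, loop in local_dyads:
            if pos + 2 * stem + loop <= arr["length"]:
                dyads.append(
                    {
                        "chrom": arr["chrom"],
                        "pos": arr["start"] + pos,
                        "stem": stem,
                        "loop": loop,
                        "array_family": fam.name,
                        "functional": arr["functional"],
                    }
                )

    for site in its_sites:
        n_cop = (site["end"] - site["start"]) // len(TELOMERE_MONOMER)
        body = "".join(
            mutate_monomer(TELOMERE_MONOMER, site["divergence"], rng_seq)
            for _ in range(n_cop)
        )
        body = body.ljust(site["end"] - site["start"], "T")
        sequences[site["chrom"]][site["start"] : site["end"]] = list(body)

    genome = GenomeIndex(
        chrom_sizes=sizes,
        sequences={c: "".join(sequences[c]) for c in chroms},
    )

    # ---- peak sets ---------------------------------------------------------
    rng_peaks = np.random.default_rng(ss_peaks)
    peak_sets: dict[tuple[str, int], IntervalSet] = {}
    truth_peaks: dict[str, list[dict]] = {}
    fp_occupied: list[tuple[str, int, int]] = [
        (d["chrom"], d["start"], d["end"]) for d in domains
    ]
    for caller in ("A", "B"):
        for rep in (1, 2):
            ivs = []
            rows = []
            for d in domains:
                j = spec.peak_jitter
                s = d["start"] + (int(rng_peaks.integers(-j, j + 1)) if j else 0)
                e = d["end"] + (int(rng_peaks.integers(-j, j + 1)) if j else 0)
                s = max(0, s)
                e = min(sizes[d["chrom"]], max(e, s + 1))
                ivs.append(Interval(d["chrom"], s, e))
                rows.append({"chrom": d["chrom"], "start": s, "end": e,
                             "false_positive": False})
            for _ in range(spec.false_positives_per_set):
                for _try in range(200):
                    chrom = chroms[int(rng_peaks.integers(0, len(chroms)))]
                    s = int(rng_peaks.integers(
                        0, sizes[chrom] - spec.false_positive_length
                    ))
                    e = s + spec.false_positive_length
                    if not any(
                        c == chrom and s < oe and os_ < e
                        for c, os_, oe in fp_occupied
                    ):
                        break
                else:  # pragma: no cover - only on absurdly full genomes
                    raise ValueError("no room for false-positive peaks")
                fp_occupied.append((chrom, s, e))
                ivs.append(Interval(chrom, s, e))
                rows.append({"chrom": chrom, "start": s, "end": e,
                             "false_positive": True})
            key = (caller, rep)
            peak_sets[key] = IntervalSet(ivs, name=f"peaks_{caller}{rep}")
            truth_peaks[f"{caller}{rep}"] = rows

    # ---- signal tracks -----------------------------------------------------
    rng_tracks = np.random.default_rng(ss_tracks)
    chip_bins: dict[str, tuple] = {}
    input_bins: dict[str, tuple] = {}
    meth_bins: dict[str, dict[str, tuple]] = {ctx: {} for ctx in spec.methylation_base}
    domain_set = IntervalSet(
        [Interval(d["chrom"], d["start"], d["end"]) for d in domains]
    )
    array_set = IntervalSet(
        [Interval(a["chrom"], a["start"], a["end"]) for a in arrays]
    )
    for chrom in chroms:
        starts = np.arange(0, sizes[chrom], spec.bin_size, dtype=np.int64)
        ends = np.minimum(starts + spec.bin_size, sizes[chrom])
        mids = (starts + ends) // 2
        in_domain = np.zeros(len(starts), dtype=bool)
        for s, e in domain_set.coords(chrom):
            in_domain[(mids >= s) & (mids < e)] = True
        lam = np.where(
            in_domain, spec.read_depth * spec.chip_fold, spec.read_depth
        )
        chip_bins[chrom] = (starts, ends, rng_tracks.poisson(lam).astype(float))
        input_bins[chrom] = (
            starts, ends,
            rng_tracks.poisson(np.full(len(starts), spec.read_depth)).astype(float),
        )
        # methylation with border-elevated CHG/CHH over arrays
        edge_weight = np.zeros(len(starts))
        in_array = np.zeros(len(starts), dtype=bool)
        for s, e in array_set.coords(chrom):
            sel = (mids >= s) & (mids < e)
            in_array |= sel
            half = (e - s) / 2.0
            d_edge = np.minimum(mids[sel] - s, e - mids[sel])
            edge_weight[sel] = np.maximum(edge_weight[sel], 1.0 - d_edge / half)
        for ctx in spec.methylation_base:
            mean = np.where(
                in_array, spec.methylation_array[ctx], spec.methylation_base[ctx]
            ).astype(float)
            mean += spec.border_gradient[ctx] * edge_weight * in_array
            frac = np.clip(mean / 100.0, 1e-3, 1 - 1e-3)
            conc = spec.methylation_concentration
            vals = rng_tracks.beta(frac * conc, (1 - frac) * conc) * 100.0
            meth_bins[ctx][chrom] = (starts.copy(), ends.copy(), vals)

    chip = SignalTrack(bins=chip_bins, units="reads", name="CENH3_chip")
    input_ = SignalTrack(bins=input_bins, units="reads", name="input")
    methylation = {
        ctx: SignalTrack(bins=b, units="percent", name=f"meth_{ctx}")
        for ctx, b in meth_bins.items()
    }

    # ---- synteny blocks and fusion gaps ------------------------------------
    rng_syn = np.random.default_rng(ss_synteny)
    blocks: list[SyntenyBlock] = []
    fusion_gaps: list[dict] = []
    for ci, chrom in enumerate(chroms):
        length = sizes[chrom]
        n_blocks = spec.blocks_per_chrom
        gaps = [int(rng_syn.integers(*spec.large_fusion_gap))]
        gaps += [
            int(rng_syn.integers(*spec.small_fusion_gap))
            for _ in range(n_blocks - 2)
        ]
        rng_syn.shuffle(gaps)
        usable = length - sum(gaps)
        cuts = np.sort(rng_syn.choice(
            np.arange(1, usable // 1000), size=n_blocks - 1, replace=False
        )) * 1000
        block_lens = np.diff(np.concatenate([[0], cuts, [usable]]))
        pos = 0
        for bi, blen in enumerate(block_lens):
            tgt = Interval(chrom, int(pos), int(pos + blen))
            src_chrom = f"ref{ci * n_blocks + bi + 1}"
            blocks.append(
                SyntenyBlock(
                    target=tgt,
                    source=Interval(src_chrom, 0, int(blen)),
                    orientation="+",
                )
            )
            pos += int(blen)
            if bi < len(gaps):
                fusion_gaps.append(
                    {"chrom": chrom, "start": int(pos), "end": int(pos + gaps[bi]),
                     "large": gaps[bi] > 100_000}
                )
                pos += gaps[bi]

    # ---- annotations -------------------------------------------------------
    rng_annot = np.random.default_rng(ss_annot)
    genes: list[Interval] = []
    tes: list[Interval] = []
    lowcomp: list[Interval] = []

    def free_place(chrom: str, size: int, tries: int = 300,
                   within: tuple[int, int] | None = None) -> Interval | None:
        lo, hi = within if within else (tel_len, sizes[chrom] - tel_len - size)
        if hi <= lo:
            return None
        arr_coords = array_set.coords(chrom)
        for _ in range(tries):
            s = int(rng_annot.integers(lo, hi + 1))
            e = s + size
            i = np.searchsorted(arr_coords[:, 0], e)
            if i and (arr_coords[:i, 1] > s).any():
                continue
            return Interval(chrom, s, e)
        return None

    for chrom in chroms:
        for _ in range(spec.genes_per_chrom):
            iv = free_place(chrom, spec.gene_length)
            if iv:
                genes.append(iv)
        for _ in range(spec.tes_per_chrom):
            iv = free_place(chrom, spec.te_length)
            if iv:
                tes.append(iv)
        for _ in range(spec.lowcomp_per_chrom):
            iv = free_place(chrom, spec.lowcomp_length)
            if iv:
                lowcomp.append(iv)

    if spec.fusion_gene_fold > 1.0:
        base_rate = spec.genes_per_chrom * spec.gene_length / np.mean(
            [sizes[c] for c in chroms]
        )  # base gene base-fraction
        for gap in fusion_gaps:
            gap_len = gap["end"] - gap["start"]
            n_extra = int(round(
                base_rate * (spec.fusion_gene_fold - 1.0) * gap_len
                / spec.gene_length
            ))
            for _ in range(n_extra):
                iv = free_place(
                    gap["chrom"], spec.gene_length,
                    within=(gap["start"], gap["end"] - spec.gene_length),
                )
                if iv:
                    genes.append(iv)

    # annotate satellite-free domain composition: ~54% low-complexity, ~26% TE
    for d in domains:
        if d["kind"] != "satellite_free":
            continue
        length = d["end"] - d["start"]
        lc_len = int(0.54 * length)
        te_len = int(0.26 * length)
        lowcomp.append(Interval(d["chrom"], d["start"], d["start"] + lc_len))
        tes.append(
            Interval(d["chrom"], d["start"] + lc_len, d["start"] + lc_len + te_len)
        )

    annotations = {
        "genes": IntervalSet(genes, name="genes"),
        "TEs": IntervalSet(tes, name="TEs"),
        "low_complexity": IntervalSet(lowcomp, name="low_complexity"),
    }

    truth = SyntheticTruth(
        chrom_sizes=sizes,
        domains=sorted(domains, key=lambda d: (d["chrom"], d["start"])),
        arrays=sorted(arrays, key=lambda a: (a["chrom"], a["start"])),
        peak_sets=truth_peaks,
        dyads=sorted(dyads, key=lambda d: (d["chrom"], d["pos"])),
        its_sites=sorted(its_sites, key=lambda s: (s["chrom"], s["start"])),
        telomeres=telomeres,
        synteny_blocks=[
            {
                "target_chrom": b.target.chrom, "target_start": b.target.start,
                "target_end": b.target.end, "source_chrom": b.source.chrom,
                "source_start": b.source.start, "source_end": b.source.end,
                "orientation": b.orientation,
            }
            for b in blocks
        ],
        fusion_gaps=fusion_gaps,
        seed=spec.seed,
    )
    return SyntheticDataset(
        spec=spec,
        genome=genome,
        truth=truth,
        peak_sets=peak_sets,
        chip=chip,
        input_=input_,
        methylation=methylation,
        annotations=annotations,
        monomers=monomers,
        synteny_blocks=blocks,
    )


def write_dataset(ds: SyntheticDataset, outdir: str) -> dict[str, str]:
    """Write every dataset component to ``outdir``; returns name -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def path(name: str) -> str:
        paths[os.path.splitext(name)[0]] = p = os.path.join(outdir, name)
        return p

    write_fasta(ds.genome, path("genome.fasta"))
    with open(path("chrom.sizes"), "w") as fh:
        for c in sorted(ds.genome.chrom_sizes):
            fh.write(f"{c}\t{ds.genome.chrom_sizes[c]}\n")
    with open(path("monomers.fasta"), "w") as fh:
        for name in sorted(ds.monomers):
            fh.write(f">{name}\n{ds.monomers[name]}\n")
    for (caller, rep), ivset in sorted(ds.peak_sets.items()):
        write_intervals(ivset, path(f"peaks_caller{caller}_rep{rep}.bed"))
    for fam in sorted({a['family'] for a in ds.truth.arrays}):
        write_intervals(ds.truth.array_set(fam), path(f"arrays_{fam}.bed"))
    write_bedgraph(ds.chip, path("chip.bedgraph"))
    write_bedgraph(ds.input_, path("input.bedgraph"))
    for ctx, track in sorted(ds.methylation.items()):
        write_bedgraph(track, path(f"meth_{ctx}.bedgraph"))
    for name, ivset in sorted(ds.annotations.items()):
        write_intervals(ivset, path(f"{name}.bed"))
    write_synteny_blocks(ds.synteny_blocks, path("synteny_blocks.tsv"))
    with open(path("truth.json"), "w") as fh:
        fh.write(ds.truth.to_json())
    return paths


def default_spec(seed: int = 0) -> GenomeSpec:
    """The default toy-scale study conditions: 3 chromosomes x 2 Mb."""
    return GenomeSpec(seed=seed)


def paper_shaped_spec(seed: int = 0) -> GenomeSpec:
    """A larger preset: 6 chromosomes x 5 Mb with per-chromosome unit
    densities in the 0.6-0.9 units/Mb range (3-5 units per chromosome)."""
    spec = GenomeSpec(
        chromosomes={f"chr{i}": 5_000_000 for i in range(1, 7)},
        families=[
            FamilySpec("Lusy1", 124, n_arrays=40, functional_fraction=0.35),
            FamilySpec("Lusy2", 174, n_arrays=30, functional_fraction=0.13,
                       functional_length_mean=9_400.0),
        ],
        satellite_free_domains=4,
        seed=seed,
    )
    return spec
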