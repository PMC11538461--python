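"""End-to-end orchestration of the holocentromere characterization analysis.

Stages run in dependency order: domains -> arrays -> classify -> dyads ->
homogeneity -> profiles -> coloc. Inputs come either from files named in
the config or from the synthetic generator (``simulate`` config block).
Every stage persists its outputs under the output directory and
contributes to a machine-readable report; the whole run is a pure function
of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import __version__
from .classify import (
    classification_summary,
    classify_arrays,
    compare_array_sizes,
    domain_composition,
    label_units,
    satellite_free_units,
)
from .coloc import (
    correlogram,
    fusion_regions_from_synteny,
    permutation_colocalization,
    read_synteny_blocks,
    rpkm_log2_ratio,
    scaled_metaprofile,
    window_feature_matrix,
)
from .domains import (
    PeakSets,
    build_units,
    consensus_peaks,
    unit_stats,
    units_to_interval_set,
)
from .homogeneity import concatenate_group, identity_matrix, similarity_summary
from .intervals import GenomeIndex, Interval, IntervalSet, tile_windows
from .io import read_bedgraph, read_fasta, read_intervals, write_intervals
from .satellites import (
    Monomer,
    SatelliteArray,
    arrays_to_interval_set,
    scan_its,
    scan_monomer_arrays,
)
from .simulate import GenomeSpec, simulate_dataset, write_dataset

logger = logging.getLogger("holocentro")

DEFAULT_PARAMS: dict[str, Any] = {
    "merge_gap": 150_000,
    "min_identity": 0.95,
    "seed_k": 11,
    "dyad_min_stem": 10,
    "dyad_max_stem": 100,
    "dyad_max_loop": 100,
    "homogeneity_k": 21,
    "homogeneity_window": 5_000,
    "window_width": 100_000,
    "alpha": 0.05,
    "n_rounds": 1000,
    "flank": 50_000,
    "large_gap": 100_000,
    "its_min_len": 200,
    "its_stringencies": (0.75, 0.90),
    "metaprofile_body_bins": 100,
    "metaprofile_flank": 5_000,
    "metaprofile_flank_bins": 50,
    "seed": 0,
}


@dataclass
class PipelineInputs:
    """Everything the analysis consumes, already loaded in memory."""

    genome: GenomeIndex
    peak_sets: dict[tuple[str, int], IntervalSet]
    monomers: dict[str, str] = field(default_factory=dict)
    array_beds: dict[str, IntervalSet] = field(default_factory=dict)
    chip: Any = None
    input_: Any = None
    methylation: dict[str, Any] = field(default_factory=dict)
    annotations: dict[str, IntervalSet] = field(default_factory=dict)
    synteny_blocks: list = field(default_factory=list)


def load_inputs(config: dict) -> PipelineInputs:
    """Load pipeline inputs from config paths or the synthetic generator."""
    if "simulate" in config:
        sim_cfg = dict(config["simulate"] or {})
        sim_cfg.setdefault("seed", config.get("seed", 0))
        spec = GenomeSpec(**sim_cfg)
        ds = simulate_dataset(spec)
        return PipelineInputs(
            genome=ds.genome,
            peak_sets=ds.peak_sets,
            monomers=ds.monomers,
            chip=ds.chip,
            input_=ds.input_,
            methylation=ds.methylation,
            annotations=ds.annotations,
            synteny_blocks=ds.synteny_blocks,
        )
    genome = read_fasta(config["genome_fasta"])
    peak_sets = {}
    for caller in ("A", "B"):
        for rep in (1, 2):
            key = f"caller{caller}_rep{rep}"
            peak_sets[(caller, rep)] = read_intervals(config["peaks"][key])
    monomers = {}
    if config.get("monomers_fasta"):
        mono = read_fasta(config["monomers_fasta"])
        monomers = dict(mono.sequences or {})
    array_beds = {
        fam: read_intervals(path)
        for fam, path in (config.get("array_beds") or {}).items()
    }
    chip = read_bedgraph(config["chip"], units="reads") if config.get("chip") else None
    input_ = (
        read_bedgraph(config["input"], units="reads") if config.get("input") else None
    )
    methylation = {
        ctx: read_bedgraph(path, units="percent")
        for ctx, path in (config.get("methylation") or {}).items()
    }
    annotations = {
        name: read_intervals(path)
        for name, path in (config.get("annotations") or {}).items()
    }
    synteny = (
        read_synteny_blocks(config["synteny"]) if config.get("synteny") else []
    )
    return PipelineInputs(
        genome=genome, peak_sets=peak_sets, monomers=monomers,
        array_beds=array_beds, chip=chip, input_=input_,
        methylation=methylation, annotations=annotations,
        synteny_blocks=synteny,
    )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run the full analysis; returns the report (also written as JSON)."""
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params") or {})
    seed = int(config.get("seed", params["seed"]))
    os.makedirs(outdir, exist_ok=True)
    inputs = load_inputs(config)
    genome = inputs.genome
    report: dict[str, Any] = {
        "provenance": {
            "version": __version__,
            "config_hash": _config_hash(config),
            "seed": seed,
        }
    }
    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s starting", name)
        timings[name] = time.perf_counter()
        return name

    def done(name: str) -> None:
        timings[name] = round(time.perf_counter() - timings[name], 3)
        logger.info("stage %s finished in %.2fs", name, timings[name])

    # ---- domains -----------------------------------------------------------
    stage("domains")
    consensus = consensus_peaks(PeakSets(inputs.peak_sets), genome)
    units = build_units(consensus, merge_gap=int(params["merge_gap"]))
    stats_df = unit_stats(units, genome)
    write_intervals(units_to_interval_set(units), os.path.join(outdir, "units.bed"))
    stats_df.to_csv(os.path.join(outdir, "unit_stats.tsv"), sep="\t", index=False)
    genome_row = stats_df[stats_df["chrom"] == "genome"].iloc[0]
    report["units"] = {
        "total": int(genome_row["unit_count"]),
        "density_per_mb": float(genome_row["density_per_mb"]),
        "mean_length": float(genome_row["mean_length"]),
        "per_chromosome": stats_df[stats_df["chrom"] != "genome"][
            ["chrom", "unit_count", "density_per_mb"]
        ].to_dict("records"),
    }
    done("domains")

    # ---- arrays ------------------------------------------------------------
    stage("arrays")
    arrays_by_family: dict[str, list[SatelliteArray]] = {}
    if inputs.array_beds:
        for fam, ivset in inputs.array_beds.items():
            mono_len = len(inputs.monomers.get(fam, "")) or 1
            arrays_by_family[fam] = [
                SatelliteArray(
                    interval=iv, family=fam,
                    copy_estimate=len(iv) / mono_len,
                    mean_identity=float(iv.attrs[1]) if len(iv.attrs) > 1 else 1.0,
                )
                for iv in ivset
            ]
    elif inputs.monomers and genome.sequences:
        for fam, seq in sorted(inputs.monomers.items()):
            arrays_by_family[fam] = scan_monomer_arrays(
                genome, Monomer(fam, seq),
                min_identity=float(params["min_identity"]),
                seed_k=int(params["seed_k"]),
            )
    its = {}
    if genome.sequences:
        its = scan_its(
            genome,
            min_len=int(params["its_min_len"]),
            stringencies=tuple(params["its_stringencies"]),
        )
        for level, ivset in its.items():
            write_intervals(
                ivset, os.path.join(outdir, f"its_{int(level * 100)}.bed")
            )
    for fam, arrs in arrays_by_family.items():
        write_intervals(
            arrays_to_interval_set(arrs, name=fam),
            os.path.join(outdir, f"arrays_{fam}.bed"),
        )
    report["arrays"] = {
        fam: {"count": len(arrs), "total_bases": sum(len(a) for a in arrs)}
        for fam, arrs in arrays_by_family.items()
    }
    report["its"] = {
        f"{level:g}": {
            "count": len(ivset),
            "interstitial": sum(
                1 for iv in ivset if iv.attrs and iv.attrs[0] == "interstitial"
            ),
        }
        for level, ivset in its.items()
    }
    done("arrays")

    # ---- classification ----------------------------------------------------
    stage("classify")
    all_arrays = [a for arrs in arrays_by_family.values() for a in arrs]
    classified = classify_arrays(all_arrays, units)
    summary = classification_summary(classified)
    summary.to_csv(
        os.path.join(outdir, "classification_summary.tsv"), sep="\t", index=False
    )
    frag_ivs = [
        iv for c in classified if c.status == "functional" for iv in c.fragments
    ]
    write_intervals(
        IntervalSet(frag_ivs, name="functional_fragments"),
        os.path.join(outdir, "functional_fragments.bed"),
    )
    free = satellite_free_units(units, all_arrays)
    write_intervals(free, os.path.join(outdir, "satellite_free_units.bed"))
    labels = label_units(units, arrays_by_family)
    label_counts = {
        fam: sum(1 for _, ls in labels if fam in ls) for fam in arrays_by_family
    }
    report["classification"] = {
        "summary": summary.to_dict("records"),
        "satellite_free_units": len(free),
        "unit_family_counts": label_counts,
    }
    if inputs.annotations and len(free):
        report["classification"]["satellite_free_composition"] = {
            k: round(v, 4)
            for k, v in domain_composition(free, inputs.annotations).items()
        }
    try:
        size_tests = compare_array_sizes(classified)
        report["classification"]["size_tests"] = {
            fam: {
                "p_value": t.p_value,
                "mean_functional": mf,
                "mean_nonfunctional": mn,
            }
            for fam, (t, mf, mn) in size_tests.items()
        }
    except ValueError as exc:
        logger.warning("size comparison skipped: %s", exc)
    done("classify")

    # ---- dyad symmetries ---------------------------------------------------
    stage("dyads")
    from .dyads import compare_dyad_abundance, dyad_abundance

    if genome.sequences:
        abundance = dyad_abundance(
            classified, genome,
            min_stem=int(params["dyad_min_stem"]),
            max_stem=int(params["dyad_max_stem"]),
            max_loop=int(params["dyad_max_loop"]),
        )
        abundance.to_csv(
            os.path.join(outdir, "dyad_abundance.tsv"), sep="\t", index=False
        )
        try:
            dyad_tests = compare_dyad_abundance(abundance)
            report["dyads"] = {
                fam: {
                    "p_one_tailed": t.p_value,
                    "median_density_functional": float(
                        abundance.query(
                            "family == @fam and status == 'functional'"
                        )["density_per_kb"].median()
                    ),
                    "median_density_nonfunctional": float(
                        abundance.query(
                            "family == @fam and status == 'nonfunctional'"
                        )["density_per_kb"].median()
                    ),
                }
                for fam, t in dyad_tests.items()
            }
        except ValueError as exc:
            logger.warning("dyad comparison skipped: %s", exc)
    else:
        logger.info("no genome sequence: dyad stage skipped")
    done("dyads")

    # ---- homogeneity -------------------------------------------------------
    stage("homogeneity")
    report["homogeneity"] = {}
    if genome.sequences:
        for fam in sorted(arrays_by_family):
            for group_name, ivs in (
                (
                    "functional_fragments",
                    [
                        iv
                        for c in classified
                        if c.array.family == fam and c.status == "functional"
                        for iv in c.fragments
                    ],
                ),
                (
                    "nonfunctional_arrays",
                    [
                        c.array.interval
                        for c in classified
                        if c.array.family == fam and c.status == "nonfunctional"
                    ],
                ),
            ):
                if not ivs:
                    continue
                group = IntervalSet(ivs, name=f"{fam}_{group_name}")
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    seq, wins = concatenate_group(
                        group, genome, window=int(params["homogeneity_window"])
                    )
                if len(wins) < 2:
                    continue
                mat = identity_matrix(
                    seq, wins, k=int(params["homogeneity_k"]),
                    window=int(params["homogeneity_window"]),
                )
                summ = similarity_summary(mat, label=f"{fam}/{group_name}")
                report["homogeneity"][f"{fam}/{group_name}"] = {
                    "mean_similarity_pct": round(summ["mean_similarity_pct"], 2),
                    "n_windows": summ["n_windows"],
                }
    done("homogeneity")

    # ---- profiles ----------------------------------------------------------
    stage("profiles")
    windows = tile_windows(genome, int(params["window_width"]))
    features: dict[str, Any] = {"CENH3_units": units_to_interval_set(units)}
    for fam, arrs in arrays_by_family.items():
        features[f"{fam}_functional"] = IntervalSet(
            [c.array.interval for c in classified
             if c.array.family == fam and c.status == "functional"]
        )
        features[f"{fam}_nonfunctional"] = IntervalSet(
            [c.array.interval for c in classified
             if c.array.family == fam and c.status == "nonfunctional"]
        )
    features.update(inputs.annotations)
    log2 = None
    if inputs.chip is not None and inputs.input_ is not None:
        log2 = rpkm_log2_ratio(inputs.chip, inputs.input_)
        features["CENH3_log2"] = log2
    for ctx, track in inputs.methylation.items():
        features[ctx] = track
    matrix = window_feature_matrix(windows, features)
    matrix.to_csv(os.path.join(outdir, "feature_matrix.tsv"), sep="\t")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rho, padj, mask = correlogram(matrix, alpha=float(params["alpha"]))
    rho.to_csv(os.path.join(outdir, "correlogram_rho.tsv"), sep="\t")
    mask.to_csv(os.path.join(outdir, "correlogram_mask.tsv"), sep="\t")
    report["correlogram"] = {
        "n_windows": len(matrix),
        "n_features": matrix.shape[1],
        "significant_pairs": int((~mask.values).sum() // 2),
    }
    if log2 is not None and arrays_by_family:
        fam0 = sorted(arrays_by_family)[0]
        arr_set = IntervalSet([a.interval for a in arrays_by_family[fam0]])
        if len(arr_set):
            prof = scaled_metaprofile(
                log2, arr_set,
                body_bins=int(params["metaprofile_body_bins"]),
                flank=int(params["metaprofile_flank"]),
                flank_bins=int(params["metaprofile_flank_bins"]),
            )
            report["metaprofile"] = {
                "family": fam0,
                "body_mean": float(np.nanmean(prof.body)),
                "flank_mean": float(
                    np.nanmean(
                        np.concatenate(
                            [prof.values[: prof.flank_bins],
                             prof.values[-prof.flank_bins:]]
                        )
                    )
                ),
                "n_features": prof.n_features,
                "n_skipped": prof.n_skipped,
            }
    done("profiles")

    # ---- colocalization ----------------------------------------------------
    stage("coloc")
    if inputs.synteny_blocks:
        flanks, fusions = fusion_regions_from_synteny(
            inputs.synteny_blocks,
            flank=int(params["flank"]),
            large_gap=int(params["large_gap"]),
        )
        write_intervals(flanks, os.path.join(outdir, "fusion_flanks.bed"))
        write_intervals(fusions, os.path.join(outdir, "fusion_regions.bed"))
        coloc_features = {
            name: feat
            for name, feat in features.items()
            if isinstance(feat, IntervalSet) and len(feat) > 0
        }
        all_sat = IntervalSet(
            [a.interval for arrs in arrays_by_family.values() for a in arrs]
        )
        results = {}
        rng = np.random.default_rng(seed)
        for name, feat in sorted(coloc_features.items()):
            feat_named = IntervalSet(list(feat), name=name)
            excl = all_sat if name in ("genes", "satellite_free") else None
            res = permutation_colocalization(
                flanks, feat_named, genome,
                n_rounds=int(params["n_rounds"]),
                exclusion=excl,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            results[name] = {
                "real_overlap_proportion": round(res.real_overlap_proportion, 6),
                "percentile": res.percentile,
                "p_greater": res.p_greater,
                "n_rounds": res.n_rounds,
            }
        report["colocalization"] = {
            "regions": "fusion_flanks",
            "n_flanks": len(flanks),
            "n_large_fusion_regions": len(fusions),
            "features": results,
        }
        with open(os.path.join(outdir, "colocalization.json"), "w") as fh:
            json.dump(report["colocalization"], fh, indent=1, sort_keys=True)
    else:
        logger.info("no synteny blocks: colocalization skipped")
    done("coloc")

    report["timings"] = {}  # kept out of report.json determinism; see log
    report.pop("timings")
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    _write_markdown_report(report, os.path.join(outdir, "report.md"))
    return report


def _write_markdown_report(report: dict, path: str) -> None:
    lines = ["# Holocentromere characterization report", ""]
    units = report.get("units", {})
    lines.append(
        f"- CENH3 centromeric units: {units.get('total')} "
        f"({units.get('density_per_mb', 0):.2f} units/Mb genome-wide)"
    )
    for rec in report.get("classification", {}).get("summary", []):
        lines.append(
            f"- {rec['family']}: {rec['functional_count']} of "
            f"{rec['array_count_total']} arrays functional "
            f"({100 * rec['functional_fraction']:.0f}%), "
            f"{rec['functional_overlap_bases']} of {rec['total_bases']} bases "
            f"({100 * rec['overlap_base_fraction']:.0f}%) under CENH3"
        )
    for fam, t in report.get("classification", {}).get("size_tests", {}).items():
        lines.append(
            f"- {fam} array sizes functional vs nonfunctional: "
            f"{t['mean_functional']:.0f} vs {t['mean_nonfunctional']:.0f} bp "
            f"(two-sided MWU p = {t['p_value']:.2e})"
        )
    for fam, t in report.get("dyads", {}).items():
        lines.append(
            f"- {fam} dyad density functional > nonfunctional: "
            f"one-tailed MWU p = {t['p_one_tailed']:.3g}"
        )
    for key, h in report.get("homogeneity", {}).items():
        lines.append(
            f"- homogeneity {key}: mean similarity "
            f"{h['mean_similarity_pct']:.1f}% over {h['n_windows']} windows"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def simulate_to_dir(spec: GenomeSpec, outdir: str) -> dict[str, str]:
    """Generate a synthetic dataset and write it to ``outdir``."""
    return write_dataset(simulate_dataset(spec), outdir)
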