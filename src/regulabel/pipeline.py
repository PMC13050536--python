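"""Pipeline orchestration: config, validation, staged execution, manifest.

Stage outputs are pure functions of (inputs, config); the manifest
records input checksums and a config hash so reruns are auditable and
the expensive quantification stage can be resumed from its TSV when
nothing upstream changed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifier import DEFAULT_TIE_BREAK, classify_all
from .downstream import (
    annotate_tss_distances,
    build_tss_registry,
    class_distribution,
    compute_metaplot,
    intersect_variants,
)
from .genome_io import (
    AlignmentSource,
    CoverageTrack,
    ensure_bam_index,
    read_bed,
    read_gene_annotation,
    read_variants,
    write_annotation_bed,
)
from .intervals import validate_chrom_namespaces
from .regions import build_union_regions, compute_coverage_matrix, order_by_mark_difference
from .signal import TRACKS, SignalMatrix, compute_signal_matrix

logger = logging.getLogger(__name__)

DEFAULT_BIOTYPES = ("protein-coding", "miRNA", "lncRNA")


@dataclass
class PipelineConfig:
    """Everything a run needs: input paths and the exposed parameters."""

    tracks: dict  # track name -> {"bam": ..., "bigwig": ..., "bed": ...}
    accessibility_bed: str
    outdir: str
    blacklist_bed: str | None = None
    accessibility_bam: str | None = None  # accepted but unused (peaks suffice)
    genes: dict | None = None  # {"path": ..., "biotypes": [...]}
    variants: dict | None = None  # {"path": ..., "one_based": bool}
    anchor_mode: str = "union"
    auc_mode: str = "area"
    activity_threshold: float = 0.0
    hybrid_scope: str = "all"
    tie_break_priority: tuple = DEFAULT_TIE_BREAK
    metaplot_flank: int = 2000
    metaplot_bin: int = 10
    write_metaplots: bool = False
    n_workers: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = raw.pop("params", {}) or {}
        kwargs = {
            "tracks": raw.get("tracks", {}),
            "accessibility_bed": raw.get("accessibility_bed"),
            "outdir": raw.get("outdir", "regulabel_out"),
            "blacklist_bed": raw.get("blacklist_bed"),
            "accessibility_bam": raw.get("accessibility_bam"),
            "genes": raw.get("genes"),
            "variants": raw.get("variants"),
        }
        for key in (
            "anchor_mode", "auc_mode", "activity_threshold", "hybrid_scope",
            "tie_break_priority", "metaplot_flank", "metaplot_bin",
            "write_metaplots", "n_workers",
        ):
            if key in params:
                kwargs[key] = params[key]
        cfg = cls(**kwargs)
        cfg.tie_break_priority = tuple(cfg.tie_break_priority)
        return cfg

    def param_hash(self) -> str:
        payload = {
            "anchor_mode": self.anchor_mode,
            "auc_mode": self.auc_mode,
            "activity_threshold": self.activity_threshold,
            "hybrid_scope": self.hybrid_scope,
            "tie_break_priority": list(self.tie_break_priority),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(cfg: PipelineConfig) -> ValidationReport:
    """Check input presence, indexes and chromosome-namespace coherence.

    Every required input cell (per-track BAM/bigWig/BED, accessibility
    BED) must exist; peak chromosomes are heuristically required to be a
    subset of the matching BAM's references (reported, not proven, since
    true same-origin cannot be verified from file contents alone).
    """
    report = ValidationReport()
    for t in TRACKS:
        spec = cfg.tracks.get(t)
        if spec is None:
            report.errors.append(f"missing track configuration: {t}")
            continue
        for kind, key in (("BAM", "bam"), ("bigWig", "bigwig"), ("BED", "bed")):
            path = spec.get(key)
            if not path or not Path(path).exists():
                report.errors.append(f"missing required input: {t} / {kind}")
    if not cfg.accessibility_bed or not Path(cfg.accessibility_bed).exists():
        report.errors.append("missing required input: Chromatin accessibility / BED")
    if cfg.accessibility_bam:
        report.warnings.append(
            "accessibility BAM supplied but unused: only the accessibility "
            "peak BED is required"
        )
    if cfg.blacklist_bed and not Path(cfg.blacklist_bed).exists():
        report.errors.append(f"blacklist BED not found: {cfg.blacklist_bed}")
    if cfg.genes and not Path(cfg.genes["path"]).exists():
        report.errors.append(f"gene annotation not found: {cfg.genes['path']}")
    if cfg.variants and not Path(cfg.variants["path"]).exists():
        report.errors.append(f"variant file not found: {cfg.variants['path']}")
    if report.errors:
        return report

    namespaces = {}
    try:
        acc = read_bed(cfg.accessibility_bed)
        namespaces["accessibility BED"] = {p.chrom for p in acc}
        for t in TRACKS:
            peaks = read_bed(cfg.tracks[t]["bed"])
            peak_chroms = {p.chrom for p in peaks}
            namespaces[f"{t} BED"] = peak_chroms
            ensure_bam_index(cfg.tracks[t]["bam"])
            with AlignmentSource(cfg.tracks[t]["bam"]) as src:
                refs = src.references()
            if peak_chroms and not peak_chroms <= refs:
                report.warnings.append(
                    f"{t}: peak chromosomes {sorted(peak_chroms - refs)} absent "
                    "from its BAM header — files may not originate from each other"
                )
        validate_chrom_namespaces({k: v for k, v in namespaces.items() if v})
    except ValueError as exc:
        report.errors.append(str(exc))
    return report


def run_pipeline(cfg: PipelineConfig, resume: bool = True) -> dict:
    """Execute regions -> signal -> classification -> downstream.

    Writes the annotation BED6+, the signal-matrix and coverage-matrix
    TSVs, the class distribution, optional meta-plot matrices and
    TSS/variant outputs, and a manifest with config hash, input
    checksums, package version and per-stage wall time. With ``resume``,
    an existing signal_matrix.tsv whose manifest-recorded checksums still
    match is loaded instead of recomputed.
    """
    report = validate_config(cfg)
    for w in report.warnings:
        logger.warning(w)
    if not report.ok:
        raise ValueError("configuration invalid: " + "; ".join(report.errors))

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    input_paths = {"accessibility_bed": cfg.accessibility_bed}
    for t in TRACKS:
        for key in ("bam", "bigwig", "bed"):
            input_paths[f"{t}.{key}"] = cfg.tracks[t][key]
    if cfg.blacklist_bed:
        input_paths["blacklist_bed"] = cfg.blacklist_bed
    checksums = {k: _sha256(v) for k, v in sorted(input_paths.items())}

    # --- stage: regions -------------------------------------------------
    acc_peaks = read_bed(cfg.accessibility_bed)
    ctcf_peaks = read_bed(cfg.tracks["CTCF"]["bed"])
    blacklist = read_bed(cfg.blacklist_bed) if cfg.blacklist_bed else []
    region_set = build_union_regions(
        acc_peaks, ctcf_peaks, blacklist, anchor_mode=cfg.anchor_mode
    )
    logger.info("stage regions: %d candidate regions", len(region_set))
    timings["regions"] = time.perf_counter() - t0

    # --- stage: coverage ordering ---------------------------------------
    t1 = time.perf_counter()
    with CoverageTrack(cfg.tracks["H3K4me1"]["bigwig"]) as me1, CoverageTrack(
        cfg.tracks["H3K4me3"]["bigwig"]
    ) as me3:
        cov = compute_coverage_matrix(region_set, me1, me3)
    order = order_by_mark_difference(cov, region_set)
    cov_out = region_set.to_frame().drop(columns="source")
    cov_out[["H3K4me1_cov", "H3K4me3_cov"]] = cov.to_numpy()
    cov_out["metaplot_rank"] = np.argsort(order)
    cov_out.to_csv(outdir / "coverage_matrix.tsv", sep="\t", index=False)
    timings["coverage"] = time.perf_counter() - t1

    # --- stage: signal ---------------------------------------------------
    t2 = time.perf_counter()
    signal_tsv = outdir / "signal_matrix.tsv"
    manifest_path = outdir / "manifest.json"
    signal_matrix = None
    if resume and signal_tsv.exists() and manifest_path.exists():
        try:
            with open(manifest_path) as fh:
                prev = json.load(fh)
            if (
                prev.get("input_checksums") == checksums
                and prev.get("config_hash") == cfg.param_hash()
            ):
                signal_matrix = SignalMatrix.from_tsv(signal_tsv)
                logger.info("stage signal: resumed from %s", signal_tsv)
        except (ValueError, KeyError, json.JSONDecodeError):
            signal_matrix = None
    if signal_matrix is None:
        track_peaks = {t: read_bed(cfg.tracks[t]["bed"]) for t in TRACKS}
        track_bams = {t: cfg.tracks[t]["bam"] for t in TRACKS}
        signal_matrix = compute_signal_matrix(
            region_set,
            track_peaks,
            track_bams,
            auc_mode=cfg.auc_mode,
            n_workers=cfg.n_workers,
        )
        signal_matrix.to_tsv(signal_tsv)
    timings["signal"] = time.perf_counter() - t2

    # --- stage: classification ------------------------------------------
    t3 = time.perf_counter()
    records = classify_all(
        signal_matrix,
        activity_threshold=cfg.activity_threshold,
        hybrid_scope=cfg.hybrid_scope,
        tie_break_priority=tuple(cfg.tie_break_priority),
    )
    dist = class_distribution(records)
    for label, row in dist.iterrows():
        logger.info("class %s: %d regions (%.1f%%)", label, row["count"], row["percentage"])
    dist.to_csv(outdir / "class_distribution.tsv", sep="\t")
    timings["classify"] = time.perf_counter() - t3

    # --- stage: downstream ----------------------------------------------
    t4 = time.perf_counter()
    registry = None
    if cfg.genes:
        biotypes = cfg.genes.get("biotypes", list(DEFAULT_BIOTYPES))
        genes = read_gene_annotation(cfg.genes["path"], biotypes)
        registry = build_tss_registry(genes)
        if not registry.empty:
            annotate_tss_distances(records, registry)
    variant_summary = None
    if cfg.variants:
        variants = read_variants(
            cfg.variants["path"], one_based=bool(cfg.variants.get("one_based"))
        )
        variant_summary, per_variant = intersect_variants(variants, records)
        variant_summary.to_csv(outdir / "variants_per_label.tsv", sep="\t")
        per_variant.to_csv(outdir / "variants_annotated.tsv", sep="\t", index=False)
    if cfg.write_metaplots:
        ordered = [region_set.regions[i] for i in order]
        for t in TRACKS:
            with CoverageTrack(cfg.tracks[t]["bigwig"]) as track:
                mat = compute_metaplot(
                    ordered, track, flank=cfg.metaplot_flank, bin_width=cfg.metaplot_bin
                )
            np.savetxt(outdir / f"metaplot_{t}.tsv", mat, delimiter="\t", fmt="%.6g")
    timings["downstream"] = time.perf_counter() - t4

    annotation_bed = outdir / "annotation.bed"
    write_annotation_bed(records, annotation_bed)

    manifest = {
        "version": __version__,
        "config_hash": cfg.param_hash(),
        "input_checksums": checksums,
        "n_regions": len(region_set),
        "stage_seconds": {k: round(v, 4) for k, v in timings.items()},
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "region_set": region_set,
        "signal_matrix": signal_matrix,
        "records": records,
        "class_distribution": dist,
        "variant_summary": variant_summary,
        "metaplot_order": order,
        "annotation_bed": str(annotation_bed),
        "outdir": str(outdir),
    }
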