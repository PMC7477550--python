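"""Pairwise-comparison pipeline: simulate -> preprocess -> rhythm -> compare -> enrich.

Conditions are analysed in pairs (control vs treated, sharing the
preprocessing), mirroring a pairwise experimental design.  Every stage
output is written under the output directory and checksummed into a run
manifest, so a re-run with the same config and seed is verifiable by
checksum equality.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .compare import (classify_amplitude_change, heatmap_matrix,
                      partition_rhythm_sets, phase_histogram)
from .enrichment import (PromoterWindow, SiteFilter, build_target_set,
                         fisher_enrichment, gene_set_enrichment,
                         meta_exclusive_tfs)
from .io import (read_bed_intervals, read_expression_matrix,
                 read_gene_annotation, read_gene_sets,
                 write_expression_matrix)
from .jtk import build_grid, call_rhythmic, jtk_scan_matrix
from .preprocess import filter_low_expression, prune_outliers
from .simulate import default_spec, generate_timecourse, generate_motif_annotation, inject_outliers

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with study defaults.

    Defaults: rhythm cutoff alpha = 0.01 on the Bonferroni-adjusted p,
    period window 20-28 h, enrichment promoter window -10000/+2000 bp and
    target window -3000/+1000 bp, site filters BBLS > 1 / FDR < 0.25 /
    50000-site degenerate-motif cap, low-expression threshold 1 (FPKM-like
    units).  Either ``simulate`` is true (synthetic inputs generated at
    ``n_genes`` x the default design) or ``expression_paths`` etc. point
    at files on disk.
    """

    out_dir: str = "rhythmix_run"
    seed: int = 0
    # input: synthetic ...
    simulate: bool = True
    n_genes: int = 2000
    # ... or from files
    expression_paths: dict[str, str] = field(default_factory=dict)
    times_h: list[float] = field(default_factory=lambda: [3, 7, 11, 15, 19, 23])
    n_replicates: int = 3
    tss_path: str | None = None
    sites_path: str | None = None
    peaks_path: str | None = None
    gene_sets_path: str | None = None
    # analysis parameters
    pairs: list[list[str]] = field(
        default_factory=lambda: [["wt_sal", "wt_coc"], ["ko_sal", "ko_coc"]])
    alpha: float = 0.01
    period_min: float = 20.0
    period_max: float = 28.0
    fpkm_min: float = 1.0
    low_expr_mode: str = "all"
    prune_replicates: bool = True
    phase_bin_h: float = 2.0
    amp_tol: float = 0.05
    window_up: int = 10_000
    window_down: int = 2_000
    target_window_up: int = 3_000
    target_window_down: int = 1_000
    min_bbls: float = 1.0
    max_site_fdr: float = 0.25
    max_sites_per_tf: int = 50_000
    alpha_tf: float = 0.01
    focal_tf: str | None = "PPARG"
    require_peak: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    """Config snapshot, seeds and per-output checksums of one run."""

    config: dict
    version: str
    seed: int
    checksums: dict[str, str]
    started: float
    finished: float
    valid: bool = True

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Guard()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pairwise analysis; returns the run manifest.

    Outputs under ``config.out_dir``: per-condition pruned expression
    TSVs, per-pair rhythm result TSVs and heatmap TSVs, a ``report.json``
    with partitions, phase histograms, amplitude taxonomy, enrichment and
    exclusivity tables, and ``manifest.json``.  Deterministic given the
    seed.
    """
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    report: dict = {"alpha": config.alpha, "pairs": config.pairs}

    # ---- inputs -----------------------------------------------------------
    annotation = sites = peaks = collection = None
    truth = None
    with _stage("inputs"):
        if config.simulate:
            spec = default_spec(n_genes=config.n_genes, seed=config.seed)
            matrices, truth = generate_timecourse(spec)
            for i, cond in enumerate(list(matrices)):
                if spec.outlier_rate > 0:
                    matrices[cond], _ = inject_outliers(
                        matrices[cond], spec.outlier_rate,
                        spec.outlier_factor, seed=config.seed * 1000 + i)
            annotation, sites, peaks = generate_motif_annotation(spec, truth)
        else:
            if not config.expression_paths:
                raise PipelineError("stage 'inputs' failed: no expression_paths "
                                    "and simulate is false")
            n_t = len(config.times_h)
            matrices = {
                cond: read_expression_matrix(
                    path, cond, config.times_h, [config.n_replicates] * n_t)
                for cond, path in config.expression_paths.items()
            }
            if config.tss_path:
                annotation = read_gene_annotation(config.tss_path)
            if config.sites_path:
                sites = read_bed_intervals(config.sites_path, kind="sites")
            if config.peaks_path:
                peaks = read_bed_intervals(config.peaks_path, kind="peaks")
        if config.gene_sets_path:
            collection = read_gene_sets(config.gene_sets_path)

    for a, b in config.pairs:
        for c in (a, b):
            if c not in matrices:
                raise PipelineError(
                    f"stage 'inputs' failed: pair condition {c!r} has no matrix")

    # ---- preprocess -------------------------------------------------------
    with _stage("preprocess"):
        pruned = {}
        prune_counts = {}
        for cond, m in matrices.items():
            if config.prune_replicates:
                pm, rep = prune_outliers(m)
                prune_counts[cond] = rep.n_pruned()
            else:
                pm, prune_counts[cond] = m, 0
            pruned[cond] = pm
            p = out / f"pruned_{cond}.tsv"
            write_expression_matrix(pm, p)
            outputs[f"pruned_{cond}"] = p
        _, global_report = filter_low_expression(
            list(pruned.values()), threshold=config.fpkm_min,
            mode=config.low_expr_mode)
        background = set(global_report.background)
        report["preprocess"] = {
            "pruned_replicates": prune_counts,
            "background_size": len(background),
        }

    # ---- per-pair rhythm + comparison ------------------------------------
    rhythm_sets: dict[str, set[str]] = {}
    results_by_cond: dict[str, object] = {}
    report["comparisons"] = {}
    for a, b in config.pairs:
        pair_key = f"{a}_vs_{b}"
        with _stage(f"rhythm[{pair_key}]"):
            (ma, mb), _ = filter_low_expression(
                [pruned[a], pruned[b]], threshold=config.fpkm_min,
                mode=config.low_expr_mode)
            grid = build_grid(ma.times_h, config.period_min, config.period_max)
            res_a = jtk_scan_matrix(ma, grid, alpha=config.alpha)
            res_b = jtk_scan_matrix(mb, grid, alpha=config.alpha)
            for cond, res in ((a, res_a), (b, res_b)):
                p = out / f"rhythm_{pair_key}_{cond}.tsv"
                res.to_csv(p, sep="\t", float_format="%.6g")
                outputs[f"rhythm_{pair_key}_{cond}"] = p
            set_a = call_rhythmic(res_a, config.alpha)
            set_b = call_rhythmic(res_b, config.alpha)
            rhythm_sets.setdefault(a, set_a)
            rhythm_sets.setdefault(b, set_b)
            results_by_cond.setdefault(a, res_a)
            results_by_cond.setdefault(b, res_b)

        with _stage(f"compare[{pair_key}]"):
            part = partition_rhythm_sets(set_a, set_b, a, b)
            hists = {
                "exclusive_a": phase_histogram(res_a, part.exclusive_a,
                                               config.phase_bin_h).tolist(),
                "common": phase_histogram(res_b, part.common,
                                          config.phase_bin_h).tolist(),
                "exclusive_b": phase_histogram(res_b, part.exclusive_b,
                                               config.phase_bin_h).tolist(),
            }
            amp = classify_amplitude_change(res_a, res_b, part.common,
                                            tol=config.amp_tol)
            for name, gene_set, m_, res_ in (
                    ("exclusive_a", part.exclusive_a, ma, res_a),
                    ("common", part.common, mb, res_b),
                    ("exclusive_b", part.exclusive_b, mb, res_b)):
                hm = heatmap_matrix(m_, res_, gene_set)
                p = out / f"heatmap_{pair_key}_{name}.tsv"
                hm.to_csv(p, sep="\t", float_format="%.4g")
                outputs[f"heatmap_{pair_key}_{name}"] = p
            report["comparisons"][pair_key] = {
                "partition": part.to_dict(),
                "phase_histograms": {"bin_h": config.phase_bin_h, **hists},
                "amplitude": amp.to_dict(),
            }

    # ---- enrichment meta-analysis ----------------------------------------
    if annotation is not None and sites is not None:
        with _stage("enrichment"):
            window = PromoterWindow(config.window_up, config.window_down)
            site_filter = SiteFilter(config.min_bbls, config.max_site_fdr,
                                     config.max_sites_per_tf)
            tf_names = sites.tf_names()
            bg = background & set(annotation.records)
            records_by_cond = {}
            for cond, gene_set in rhythm_sets.items():
                records_by_cond[cond] = fisher_enrichment(
                    gene_set & bg, bg, tf_names, sites, annotation,
                    window=window, site_filter=site_filter)
            meta = meta_exclusive_tfs(records_by_cond, alpha_tf=config.alpha_tf)
            p = out / "tf_exclusivity.tsv"
            meta.to_csv(p, sep="\t", float_format="%.6g")
            outputs["tf_exclusivity"] = p
            report["enrichment"] = {
                cond: [r.to_dict() for r in recs[:25]]
                for cond, recs in records_by_cond.items()
            }
            report["tf_exclusivity"] = meta["exclusive_to"].to_dict()

        if config.focal_tf is not None:
            with _stage("targets"):
                tw = PromoterWindow(config.target_window_up,
                                    config.target_window_down)
                targets = build_target_set(
                    config.focal_tf, sites,
                    peaks if peaks is not None else _empty_peaks(),
                    annotation, window=tw, site_filter=site_filter,
                    require_peak=config.require_peak and peaks is not None)
                report["targets"] = {
                    "tf": config.focal_tf,
                    "n_targets": len(targets),
                    "rhythmic_overlap": {
                        cond: len(targets & s)
                        for cond, s in rhythm_sets.items()},
                }

    if collection is not None:
        with _stage("gene_sets"):
            report["gene_set_enrichment"] = {}
            for cond, gene_set in rhythm_sets.items():
                df = gene_set_enrichment(gene_set & background, background,
                                         collection)
                report["gene_set_enrichment"][cond] = (
                    df.reset_index().to_dict(orient="records"))

    # ---- report + manifest ------------------------------------------------
    with _stage("report"):
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        outputs["report"] = report_path

    checksums = {name: _sha256(p) for name, p in sorted(outputs.items())}
    manifest = RunManifest(
        config=dataclasses.asdict(config), version=__version__,
        seed=config.seed, checksums=checksums,
        started=started, finished=time.time())
    manifest.to_json(out / "manifest.json")
    return manifest


def _empty_peaks():
    import pandas as pd

    from .io import PeakTable
    return PeakTable(pd.DataFrame(columns=list(PeakTable.COLUMNS)))
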