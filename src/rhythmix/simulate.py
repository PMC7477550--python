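"""Synthetic multi-condition circadian expression data with known truth.

The generator emulates the structure of a striatal circadian RNA-seq
study: four conditions (2 genotypes x 2 treatments), six timepoints four
hours apart (ZT 3..23) with three replicates, a mixture of flat genes and
~24 h oscillators whose membership differs between conditions — including
a "de novo" set that oscillates only under treatment, with phases
clustered near ZT7 — multiplicative lognormal noise, occasional
single-replicate outliers, and a matched promoter annotation in which one
focal TF's binding sites are enriched in the de-novo genes' promoters.

The model for an oscillating gene g in condition c is

    value(g, c, t, r) = mu_g * (1 + a * cos(2 pi (t - phi) / P)) * exp(eps)

with eps ~ Normal(0, noise_sd^2) drawn independently per sample and
mu_g lognormal across genes.  Non-oscillators have a = 0.  All randomness
flows from a single seed via named child streams, so outputs are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    GeneAnnotation,
    PeakTable,
    SiteTable,
    TimecourseMatrix,
    write_expression_matrix,
    write_gene_annotation,
    write_peaks_bed,
    write_sites_bed,
)

__all__ = [
    "Oscillation",
    "SimulationSpec",
    "GroundTruth",
    "default_spec",
    "generate_timecourse",
    "inject_outliers",
    "generate_motif_annotation",
    "write_simulation",
]

DEFAULT_TIMES = (3.0, 7.0, 11.0, 15.0, 19.0, 23.0)
DEFAULT_CONDITIONS = ("wt_sal", "wt_coc", "ko_sal", "ko_coc")


@dataclass(frozen=True)
class Oscillation:
    """A planted oscillator: peak phase (ZT h), relative amplitude, period."""

    phase: float
    amplitude: float
    period: float = 24.0


@dataclass
class SimulationSpec:
    """Full description of one synthetic dataset.

    ``rhythm_plan`` maps condition -> {gene_id -> Oscillation}; genes
    absent from a condition's plan are flat there.  ``denovo_genes`` names
    the genes planted as treatment-only oscillators in the focal condition
    (the set whose promoters are seeded with focal-TF sites at rate
    ``p_in``; every other gene is seeded at rate ``p_out``).
    """

    n_genes: int
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    times_h: tuple[float, ...] = DEFAULT_TIMES
    n_replicates: int = 3
    rhythm_plan: dict[str, dict[str, Oscillation]] = field(default_factory=dict)
    denovo_genes: tuple[str, ...] = ()
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.1
    outlier_rate: float = 0.02
    outlier_factor: float = 8.0
    focal_tf: str = "PPARG"
    p_in: float = 0.5
    p_out: float = 0.05
    n_decoy_tfs: int = 20
    seed: int = 0

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        for p, name in [(self.p_in, "p_in"), (self.p_out, "p_out"),
                        (self.outlier_rate, "outlier_rate")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        times = np.asarray(self.times_h)
        if np.any(times < 0) or np.any(times >= 24):
            raise ValueError("times_h must lie in [0, 24)")
        for cond, plan in self.rhythm_plan.items():
            if cond not in self.conditions:
                raise ValueError(f"rhythm_plan condition {cond!r} unknown")
            for g, osc in plan.items():
                if osc.amplitude <= 0 or osc.amplitude > 1:
                    raise ValueError(
                        f"{cond}/{g}: relative amplitude must be in (0, 1], "
                        f"got {osc.amplitude}"
                    )
                if osc.amplitude >= 1 and self.noise_sd > 0:
                    raise ValueError(
                        f"{cond}/{g}: amplitude {osc.amplitude} with noise "
                        "would not keep the mean factor positive"
                    )


@dataclass
class GroundTruth:
    """Planted truth for recovery tests.

    ``oscillators[cond]`` maps gene_id -> Oscillation for every planted
    oscillator; ``focal_targets`` is the set of genes that actually
    received at least one focal-TF site inside their -3000/+1000 promoter
    window (filled in by :func:`generate_motif_annotation`).
    """

    oscillators: dict[str, dict[str, Oscillation]]
    denovo_genes: set[str]
    focal_targets: set[str] = field(default_factory=set)
    baselines: dict[str, float] = field(default_factory=dict)

    def is_oscillator(self, gene_id: str, condition: str) -> bool:
        return gene_id in self.oscillators.get(condition, {})


def default_spec(n_genes: int = 2000, seed: int = 0, **overrides) -> SimulationSpec:
    """The standard study-shaped plan.

    Gene blocks (fractions of ``n_genes``):

    * 10% oscillate only in wt_sal (control-only; uniform phases),
    * 5% oscillate in both wt_sal and wt_coc (common; shared phase, the
      treated amplitude rescaled by a lognormal factor so the amplitude
      taxonomy has all three classes),
    * 10% de novo in wt_coc only, phases ~ ZT7 with 1.5 h circular jitter,
    * 2.5% oscillate only in ko_sal, 2.5% common to ko_sal/ko_coc,
      2.5% de novo in ko_coc (uniform phases),
    * the remainder are flat everywhere.

    Amplitudes are uniform on [0.3, 0.8]; the period is 24 h.
    """
    spec = SimulationSpec(n_genes=n_genes, seed=seed, **overrides)
    genes = spec.gene_ids()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    def draw(genes_, phase=None):
        out = {}
        for g in genes_:
            ph = rng.uniform(0, 24) if phase is None else (
                rng.normal(phase, 1.5) % 24.0)
            out[g] = Oscillation(phase=float(ph),
                                 amplitude=float(rng.uniform(0.3, 0.8)))
        return out

    n = n_genes
    b = {
        "wt_sal_only": genes[: n // 10],
        "wt_common": genes[n // 10: n // 10 + n // 20],
        "wt_denovo": genes[n // 10 + n // 20: n // 10 + n // 20 + n // 10],
    }
    ko_start = n // 10 + n // 20 + n // 10
    step = n // 40
    b["ko_sal_only"] = genes[ko_start: ko_start + step]
    b["ko_common"] = genes[ko_start + step: ko_start + 2 * step]
    b["ko_denovo"] = genes[ko_start + 2 * step: ko_start + 3 * step]

    wt_sal = {**draw(b["wt_sal_only"]), **draw(b["wt_common"])}
    wt_coc = {}
    for g, osc in list(wt_sal.items()):
        if g in set(b["wt_common"]):
            factor = float(np.exp(rng.normal(0.0, 0.4)))
            amp = float(np.clip(osc.amplitude * factor, 0.05, 0.95))
            wt_coc[g] = Oscillation(phase=osc.phase, amplitude=amp)
    wt_coc.update(draw(b["wt_denovo"], phase=7.0))

    ko_sal = {**draw(b["ko_sal_only"]), **draw(b["ko_common"])}
    ko_coc = {g: ko_sal[g] for g in b["ko_common"]}
    ko_coc.update(draw(b["ko_denovo"]))

    spec.rhythm_plan = {"wt_sal": wt_sal, "wt_coc": wt_coc,
                        "ko_sal": ko_sal, "ko_coc": ko_coc}
    spec.denovo_genes = tuple(b["wt_denovo"])
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------


def generate_timecourse(spec: SimulationSpec):
    """Generate one TimecourseMatrix per condition plus the ground truth.

    Deterministic for a fixed ``spec.seed``; identical seeds give bitwise
    identical matrices.
    """
    spec.validate()
    genes = spec.gene_ids()
    times = np.asarray(spec.times_h, dtype=float)
    n_rep = spec.n_replicates
    sample_t = np.repeat(times, n_rep)

    base_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    mu = np.exp(base_rng.normal(spec.baseline_log_mean, spec.baseline_log_sd,
                                size=spec.n_genes))

    matrices: dict[str, TimecourseMatrix] = {}
    for ci, cond in enumerate(spec.conditions):
        plan = spec.rhythm_plan.get(cond, {})
        phase = np.zeros(spec.n_genes)
        amp = np.zeros(spec.n_genes)
        period = np.full(spec.n_genes, 24.0)
        for gi, g in enumerate(genes):
            osc = plan.get(g)
            if osc is not None:
                phase[gi], amp[gi], period[gi] = osc.phase, osc.amplitude, osc.period
        mean_factor = 1.0 + amp[:, None] * np.cos(
            2.0 * np.pi * (sample_t[None, :] - phase[:, None]) / period[:, None]
        )
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 2, ci]))
        eps = (noise_rng.normal(0.0, spec.noise_sd,
                                size=(spec.n_genes, sample_t.size))
               if spec.noise_sd > 0 else 0.0)
        values = mu[:, None] * mean_factor * np.exp(eps)
        matrices[cond] = TimecourseMatrix(
            gene_ids=list(genes),
            condition=cond,
            times_h=times,
            n_replicates=np.full(times.size, n_rep, dtype=int),
            values=values,
        )

    truth = GroundTruth(
        oscillators={c: dict(spec.rhythm_plan.get(c, {})) for c in spec.conditions},
        denovo_genes=set(spec.denovo_genes),
        baselines=dict(zip(genes, mu)),
    )
    return matrices, truth


def inject_outliers(matrix: TimecourseMatrix, q: float, factor: float,
                    seed: int):
    """Corrupt single replicates at random gene x timepoints.

    For each gene x timepoint independently with probability ``q``,
    exactly one replicate (uniform) is multiplied by ``factor``.  Returns
    the corrupted matrix and a log of (gene_id, timepoint_index,
    replicate_index) triples.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"outlier rate must lie in [0, 1], got {q}")
    if factor <= 0:
        raise ValueError(f"outlier factor must be > 0, got {factor}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out = matrix.copy()
    slices = matrix.timepoint_slices()
    n_t = len(slices)
    hit = rng.random((matrix.n_genes, n_t)) < q
    which = rng.integers(0, matrix.n_replicates, size=(matrix.n_genes, n_t))
    log = []
    for gi, ti in np.argwhere(hit):
        rep = int(which[gi, ti])
        out.values[gi, slices[ti].start + rep] *= factor
        log.append((matrix.gene_ids[gi], int(ti), rep))
    return out, log


# ---------------------------------------------------------------------------
# motif / peak annotation
# ---------------------------------------------------------------------------

TERRITORY_BP = 20_000
_TSS_OFFSET = 10_000
_TARGET_WINDOW = (3000, 1000)  # upstream, downstream of TSS


def generate_motif_annotation(spec: SimulationSpec, truth: GroundTruth):
    """Matched TSS annotation, TF binding sites and ChIP-like peaks.

    Genes occupy non-overlapping 20 kb territories on one synthetic
    chromosome, TSS mid-territory, strands alternating.  The focal TF
    receives a site inside the strand-aware -3000/+1000 promoter window of
    each de-novo gene with probability ``p_in`` and of every other gene
    with probability ``p_out``; genes that actually received a site are
    recorded as ``truth.focal_targets``.  Decoy TFs get sites uniformly
    over the chromosome.  bbls ~ Exponential(mean 2), site_fdr ~
    Uniform(0, 0.5).  Peaks cover focal sites of target genes with
    probability 0.9.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    genes = spec.gene_ids()
    chrom = "chrS"
    records: dict[str, tuple[str, int, str]] = {}
    for i, g in enumerate(genes):
        tss = i * TERRITORY_BP + _TSS_OFFSET
        strand = "+" if i % 2 == 0 else "-"
        records[g] = (chrom, tss, strand)
    annotation = GeneAnnotation(records)

    up, down = _TARGET_WINDOW
    site_rows = []
    peak_rows = []
    focal_targets: set[str] = set()
    denovo = truth.denovo_genes
    site_len = 10
    for g in genes:
        _, tss, strand = records[g]
        p = spec.p_in if g in denovo else spec.p_out
        if rng.random() >= p:
            continue
        if strand == "+":
            lo, hi = tss - up, tss + down
        else:
            lo, hi = tss - down, tss + up
        start = int(rng.integers(lo, hi - site_len))
        site_rows.append((chrom, start, start + site_len, spec.focal_tf,
                          float(rng.exponential(2.0)), float(rng.uniform(0, 0.5))))
        focal_targets.add(g)
        if rng.random() < 0.9:
            peak_rows.append((chrom, start - 200, start + site_len + 200))

    chrom_len = len(genes) * TERRITORY_BP
    for d in range(spec.n_decoy_tfs):
        name = f"DECOY{d:02d}"
        n_sites = spec.n_genes  # ~1 site per territory on average
        starts = rng.integers(0, chrom_len - site_len, size=n_sites)
        bbls = rng.exponential(2.0, size=n_sites)
        fdrs = rng.uniform(0, 0.5, size=n_sites)
        site_rows.extend(
            (chrom, int(s), int(s) + site_len, name, float(b), float(f))
            for s, b, f in zip(starts, bbls, fdrs)
        )

    sites = SiteTable(pd.DataFrame(site_rows, columns=list(SiteTable.COLUMNS)))
    peaks = PeakTable(pd.DataFrame(peak_rows, columns=list(PeakTable.COLUMNS)))
    truth.focal_targets = focal_targets
    return annotation, sites, peaks


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------


def write_simulation(spec: SimulationSpec, out_dir) -> dict:
    """Write per-condition TSVs, annotation BEDs and a ground-truth JSON.

    Outlier injection (at ``spec.outlier_rate``) is applied to each
    condition before writing.  Returns a manifest of written paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, truth = generate_timecourse(spec)
    paths: dict[str, str] = {}
    outlier_log = {}
    for i, (cond, m) in enumerate(matrices.items()):
        if spec.outlier_rate > 0:
            m, log = inject_outliers(m, spec.outlier_rate, spec.outlier_factor,
                                     seed=spec.seed * 1000 + i)
            outlier_log[cond] = log
        p = out / f"expression_{cond}.tsv"
        write_expression_matrix(m, p)
        paths[f"expression_{cond}"] = str(p)

    annotation, sites, peaks = generate_motif_annotation(spec, truth)
    write_gene_annotation(annotation, out / "tss.bed")
    write_sites_bed(sites, out / "sites.bed")
    write_peaks_bed(peaks, out / "peaks.bed")
    paths.update(tss=str(out / "tss.bed"), sites=str(out / "sites.bed"),
                 peaks=str(out / "peaks.bed"))

    truth_json = {
        "oscillators": {
            c: {g: asdict(o) for g, o in osc.items()}
            for c, osc in truth.oscillators.items()
        },
        "denovo_genes": sorted(truth.denovo_genes),
        "focal_targets": sorted(truth.focal_targets),
        "outliers": outlier_log,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    paths["ground_truth"] = str(out / "ground_truth.json")
    return paths
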