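"""Replicate-level outlier pruning and low-expression filtering.

Dixon's Q test is applied per gene x timepoint to the replicate values,
removing at most one outlier replicate per timepoint.  Genes whose
expression is consistently low (all values below an FPKM-like threshold in
both compared conditions) are dropped from the rhythm analysis, while the
enrichment background keeps every gene with any positive value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import TimecourseMatrix

logger = logging.getLogger(__name__)

__all__ = ["FilterReport", "dixon_q", "prune_outliers", "filter_low_expression",
           "DIXON_Q_CRIT"]

# Dean-Dixon r10 critical values, one-sided alpha = 0.05 (n = 3 is the
# three-replicate design's case).
DIXON_Q_CRIT = {3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507}


@dataclass
class FilterReport:
    """What was pruned and filtered, and the enrichment background."""

    # (gene_id, timepoint_index) -> (replicate_index_within_timepoint, Q)
    pruned: dict[tuple[str, int], tuple[int, float]] = field(default_factory=dict)
    dropped_low_expression: list[str] = field(default_factory=list)
    background: list[str] = field(default_factory=list)
    skipped_timepoints: list[tuple[str, int]] = field(default_factory=list)

    def n_pruned(self) -> int:
        return len(self.pruned)


def dixon_q(values) -> tuple[float, int | None]:
    """Dixon's Q test on a small replicate sample (3 <= n <= 7).

    Q is the gap between the suspect extreme and its nearest neighbour
    divided by the range; the suspect is whichever extreme has the larger
    gap (ties go to the maximum).  Returns ``(Q, index_of_outlier)`` with
    the index None when Q does not exceed the one-sided 95% critical value
    or the range is zero.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError(f"Dixon's test needs at least 3 values, got {n}")
    if n > max(DIXON_Q_CRIT):
        raise ValueError(f"Dixon's r10 table covers n <= {max(DIXON_Q_CRIT)}")
    order = np.argsort(values, kind="stable")
    srt = values[order]
    rng = srt[-1] - srt[0]
    if rng == 0:
        return 0.0, None
    gap_low = srt[1] - srt[0]
    gap_high = srt[-1] - srt[-2]
    if gap_high >= gap_low:
        q = gap_high / rng
        suspect = int(order[-1])
    else:
        q = gap_low / rng
        suspect = int(order[0])
    if q > DIXON_Q_CRIT[n]:
        return float(q), suspect
    return float(q), None


def prune_outliers(matrix: TimecourseMatrix) -> tuple[TimecourseMatrix, FilterReport]:
    """Apply Dixon's Q per gene x timepoint, masking flagged replicates.

    At most one replicate is removed per gene x timepoint.  Timepoints with
    fewer than 3 non-missing replicates are skipped (and logged), which
    also makes the operation idempotent: once a replicate is pruned the
    remaining pair is below the test's minimum n.
    """
    out = matrix.copy()
    report = FilterReport()
    slices = matrix.timepoint_slices()
    skipped_tp = set()
    for gi, gene in enumerate(matrix.gene_ids):
        for ti, sl in enumerate(slices):
            vals = out.values[gi, sl]
            mask = out.missing_mask[gi, sl]
            usable = np.flatnonzero(~mask)
            if usable.size < 3:
                if usable.size < (sl.stop - sl.start):
                    skipped_tp.add((gene, ti))
                continue
            q, idx = dixon_q(vals[usable])
            if idx is not None:
                rep_idx = int(usable[idx])
                out.missing_mask[gi, sl.start + rep_idx] = True
                report.pruned[(gene, ti)] = (rep_idx, q)
    report.skipped_timepoints = sorted(skipped_tp)
    if report.skipped_timepoints:
        logger.info(
            "prune_outliers: skipped %d gene/timepoint cells with < 3 replicates",
            len(report.skipped_timepoints),
        )
    return out, report


def filter_low_expression(
    matrices: list[TimecourseMatrix],
    threshold: float = 1.0,
    mode: str = "all",
) -> tuple[list[TimecourseMatrix], FilterReport]:
    """Drop consistently low genes; build the enrichment background.

    A gene leaves the analysis when, across every supplied condition, all
    its non-missing values fall below ``threshold`` (``mode='all'``) or its
    mean does (``mode='mean'``).  The background keeps every gene with any
    non-missing value strictly above zero in any condition — the universe
    later used for promoter enrichment.
    """
    if mode not in ("all", "mean"):
        raise ValueError(f"mode must be 'all' or 'mean', got {mode!r}")
    gene_ids = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != gene_ids:
            raise ValueError("matrices must share gene_ids in the same order")

    n_genes = len(gene_ids)
    low = np.ones(n_genes, dtype=bool)
    any_positive = np.zeros(n_genes, dtype=bool)
    for m in matrices:
        ok = ~m.missing_mask
        vals = np.where(ok, m.values, np.nan)
        with np.errstate(invalid="ignore"):
            if mode == "all":
                cond_low = np.all((vals < threshold) | ~ok, axis=1)
            else:
                cond_low = np.nanmean(vals, axis=1) < threshold
        low &= cond_low
        any_positive |= np.any((vals > 0) & ok, axis=1)

    keep = [g for g, is_low in zip(gene_ids, low) if not is_low]
    report = FilterReport(
        dropped_low_expression=[g for g, is_low in zip(gene_ids, low) if is_low],
        background=[g for g, pos in zip(gene_ids, any_positive) if pos],
    )
    return [m.subset(keep) for m in matrices], report
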