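"""Rhythm-set comparison between two conditions.

Covers the set algebra behind Venn diagrams of rhythmic genes (exclusive /
common / de-novo oscillators), phase histograms (radar-plot data),
amplitude-change taxonomy of common oscillators, and phase-sorted
row-normalised heatmap matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TimecourseMatrix

__all__ = [
    "RhythmPartition",
    "AmplitudeTaxonomy",
    "partition_rhythm_sets",
    "phase_histogram",
    "classify_amplitude_change",
    "heatmap_matrix",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class RhythmPartition:
    """Disjoint decomposition of two rhythmic gene sets.

    ``exclusive_a`` are rhythmic only in condition a, ``common`` in both,
    ``exclusive_b`` only in b (the de-novo set when b is the treated
    condition).  Percentages are of the combined union, rounded half-up to
    integers; raw fractions are kept alongside.  ``total_a``/``total_b``
    report the per-condition totals (|exclusive| + |common|) since figure
    legends quote sets in both conventions.
    """

    label_a: str
    label_b: str
    exclusive_a: set[str]
    common: set[str]
    exclusive_b: set[str]

    @property
    def union_size(self) -> int:
        return len(self.exclusive_a) + len(self.common) + len(self.exclusive_b)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "exclusive_a": len(self.exclusive_a),
            "common": len(self.common),
            "exclusive_b": len(self.exclusive_b),
        }

    @property
    def total_a(self) -> int:
        return len(self.exclusive_a) + len(self.common)

    @property
    def total_b(self) -> int:
        return len(self.exclusive_b) + len(self.common)

    @property
    def fractions(self) -> dict[str, float]:
        n = self.union_size
        if n == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / n for k, v in self.counts.items()}

    @property
    def percentages(self) -> dict[str, int]:
        return {k: _round_half_up(100.0 * f) for k, f in self.fractions.items()}

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "counts": self.counts,
            "total": self.union_size,
            "total_a": self.total_a,
            "total_b": self.total_b,
            "percentages": self.percentages,
            "fractions": self.fractions,
        }


def partition_rhythm_sets(set_a, set_b, label_a: str = "a",
                          label_b: str = "b") -> RhythmPartition:
    """Split two rhythmic gene-id sets into exclusive/common components."""
    a, b = set(set_a), set(set_b)
    return RhythmPartition(
        label_a=label_a,
        label_b=label_b,
        exclusive_a=a - b,
        common=a & b,
        exclusive_b=b - a,
    )


def phase_histogram(results: pd.DataFrame, gene_set, bin_h: float = 2.0) -> np.ndarray:
    """Counts of peak phases in half-open ZT bins [k*bin, (k+1)*bin).

    ``results`` is a rhythm-scan frame indexed by gene_id with a
    ``phase_zt`` column; every member of ``gene_set`` must be present.
    ``bin_h`` must divide 24.
    """
    n_bins = 24.0 / bin_h
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_h} h must divide 24")
    n_bins = int(round(n_bins))
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in results.index]
    if missing:
        raise KeyError(f"genes without rhythm results: {missing[:5]}")
    phases = results.loc[gene_set, "phase_zt"].to_numpy(dtype=float) % 24.0
    idx = np.floor(phases / bin_h).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return counts


@dataclass
class AmplitudeTaxonomy:
    """Amplitude change of common oscillators between two conditions."""

    ratios: dict[str, float]
    classes: dict[str, str]  # gene -> higher | lower | equal
    tol: float

    @property
    def counts(self) -> dict[str, int]:
        out = {"higher": 0, "lower": 0, "equal": 0}
        for c in self.classes.values():
            out[c] += 1
        return out

    @property
    def percentages(self) -> dict[str, int]:
        n = len(self.classes)
        if n == 0:
            return {k: 0 for k in ("higher", "lower", "equal")}
        return {k: _round_half_up(100.0 * v / n) for k, v in self.counts.items()}

    def to_dict(self) -> dict:
        return {"tol": self.tol, "counts": self.counts,
                "percentages": self.percentages}


def classify_amplitude_change(results_a: pd.DataFrame, results_b: pd.DataFrame,
                              common, tol: float = 0.05) -> AmplitudeTaxonomy:
    """Class each common oscillator by its amplitude ratio A_b / A_a.

    ``equal`` when |ratio - 1| <= tol, ``higher``/``lower`` otherwise.  A
    zero amplitude in a with a positive one in b counts as higher; both
    zero counts as equal.
    """
    ratios: dict[str, float] = {}
    classes: dict[str, str] = {}
    for g in common:
        a = float(results_a.loc[g, "amplitude"])
        b = float(results_b.loc[g, "amplitude"])
        if a == 0.0:
            ratios[g] = math.inf if b > 0 else 1.0
            classes[g] = "higher" if b > 0 else "equal"
            continue
        r = b / a
        ratios[g] = r
        if abs(r - 1.0) <= tol:
            classes[g] = "equal"
        elif r > 1.0 + tol:
            classes[g] = "higher"
        else:
            classes[g] = "lower"
    return AmplitudeTaxonomy(ratios=ratios, classes=classes, tol=tol)


def heatmap_matrix(matrix: TimecourseMatrix, results: pd.DataFrame,
                   gene_set) -> pd.DataFrame:
    """Phase-sorted, row z-scored per-timepoint means for heatmap display.

    Per gene: missing-aware replicate mean at each timepoint, then row
    z-score (population sd; constant rows map to all zeros).  Rows are
    ordered by ascending peak phase, ties broken by gene id.
    """
    gene_set = [g for g in gene_set]
    order = sorted(gene_set,
                   key=lambda g: (float(results.loc[g, "phase_zt"]), g))
    idx = matrix.gene_index()
    slices = matrix.timepoint_slices()
    rows = []
    for g in order:
        gi = idx[g]
        means = []
        for sl in slices:
            vals = matrix.values[gi, sl]
            mask = matrix.missing_mask[gi, sl]
            ok = vals[~mask]
            means.append(float(np.mean(ok)) if ok.size else np.nan)
        arr = np.asarray(means, dtype=float)
        mu = np.nanmean(arr)
        sd = np.nanstd(arr)
        rows.append(np.zeros_like(arr) if sd == 0 or np.isnan(sd)
                    else (arr - mu) / sd)
    cols = [f"ZT{int(t) if float(t).is_integer() else t}" for t in matrix.times_h]
    return pd.DataFrame(rows, index=pd.Index(order, name="gene_id"), columns=cols)
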