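"""Readers/writers for the tabular and interval formats used throughout.

Three families of files are handled:

* expression time courses — TSV, genes as rows, samples as columns named
  ``<ZT>_r<rep>`` in timepoint-major order, missing cells written as ``NA``;
* genomic intervals — BED-like TSV, 0-based half-open.  Two dialects:
  TF binding sites (``chrom start end tf_name bbls site_fdr``) and plain
  peaks (``chrom start end``); gene TSS annotation is BED6 with the gene id
  in the name column and the strand in column 6;
* gene sets — GMT (name, description, then member ids, tab-separated).

All intervals are 0-based half-open end-exclusive: a 1-bp site at position
``k`` is ``(k, k + 1)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "TimecourseMatrix",
    "GeneAnnotation",
    "SiteTable",
    "PeakTable",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_bed_intervals",
    "write_sites_bed",
    "write_peaks_bed",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_gene_sets",
    "write_gene_sets",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class TimecourseMatrix:
    """Gene x sample expression values for one condition.

    Samples are ordered timepoint-major then replicate.  ``missing_mask``
    is True where a cell has been pruned (e.g. by the replicate outlier
    test) or was NA on disk; values under the mask are undefined.
    """

    gene_ids: list[str]
    condition: str
    times_h: np.ndarray
    n_replicates: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.n_replicates = np.asarray(self.n_replicates, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        if len(self.gene_ids) != len(set(self.gene_ids)):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise ParseError(f"duplicate gene id {g!r}")
                seen.add(g)
        if self.times_h.ndim != 1 or np.any(np.diff(self.times_h) <= 0):
            raise ParseError("times_h must be strictly increasing")
        if np.any(self.times_h < 0) or np.any(self.times_h >= 24):
            raise ParseError("times_h must lie in [0, 24)")
        if self.n_replicates.shape != self.times_h.shape:
            raise ParseError("n_replicates must have one entry per timepoint")
        n_cols = int(self.n_replicates.sum())
        if self.values.shape != (len(self.gene_ids), n_cols):
            raise ParseError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {n_cols} samples"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ParseError("missing_mask shape must match values")
        ok = self.values[~self.missing_mask]
        if ok.size and (np.any(~np.isfinite(ok)) or np.any(ok < 0)):
            raise ParseError("expression values must be finite and >= 0")

    # -- sample bookkeeping -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return int(self.n_replicates.sum())

    def sample_times(self) -> np.ndarray:
        """Time in ZT hours of every sample column (timepoint-major)."""
        return np.repeat(self.times_h, self.n_replicates)

    def sample_names(self) -> list[str]:
        names = []
        for t, r in zip(self.times_h, self.n_replicates):
            zt = int(t) if float(t).is_integer() else t
            names.extend(f"{zt}_r{i + 1}" for i in range(r))
        return names

    def timepoint_slices(self) -> list[slice]:
        """Column slice of each timepoint's replicate block."""
        edges = np.concatenate([[0], np.cumsum(self.n_replicates)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.gene_index()[gene_id]
        return self.values[i], self.missing_mask[i]

    def subset(self, gene_ids: list[str]) -> "TimecourseMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in gene_ids]
        return TimecourseMatrix(
            gene_ids=list(gene_ids),
            condition=self.condition,
            times_h=self.times_h.copy(),
            n_replicates=self.n_replicates.copy(),
            values=self.values[rows].copy(),
            missing_mask=self.missing_mask[rows].copy(),
        )

    def copy(self) -> "TimecourseMatrix":
        return self.subset(self.gene_ids)


@dataclass
class GeneAnnotation:
    """Per-gene transcription start sites on a genome, strand-aware."""

    records: dict[str, tuple[str, int, str]]  # gene_id -> (chrom, tss, strand)

    def __post_init__(self) -> None:
        for g, (chrom, tss, strand) in self.records.items():
            if tss < 0:
                raise ParseError(f"gene {g!r}: tss must be >= 0, got {tss}")
            if strand not in ("+", "-"):
                raise ParseError(f"gene {g!r}: strand must be + or -, got {strand!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def tss(self, gene_id: str) -> tuple[str, int, str]:
        return self.records[gene_id]


@dataclass
class SiteTable:
    """TF binding sites with conservation score (bbls) and per-site FDR.

    Backed by a DataFrame with columns chrom, start, end, tf, bbls, site_fdr.
    """

    df: pd.DataFrame

    COLUMNS = ("chrom", "start", "end", "tf", "bbls", "site_fdr")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ParseError(f"site table missing columns {sorted(missing)}")
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if len(self.df):
            if (self.df["start"] >= self.df["end"]).any():
                bad = int((self.df["start"] >= self.df["end"]).idxmax())
                raise ParseError(f"site record {bad}: start >= end")
            if ((self.df["site_fdr"] < 0) | (self.df["site_fdr"] > 1)).any():
                raise ParseError("site_fdr must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    def tf_names(self) -> list[str]:
        return sorted(self.df["tf"].unique())

    def sites_per_tf(self) -> pd.Series:
        return self.df.groupby("tf").size()

    def for_tf(self, tf: str) -> pd.DataFrame:
        return self.df[self.df["tf"] == tf]


@dataclass
class PeakTable:
    """Plain genomic intervals (e.g. ChIP-seq peaks)."""

    df: pd.DataFrame

    COLUMNS = ("chrom", "start", "end")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ParseError(f"peak table missing columns {sorted(missing)}")
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            bad = int((self.df["start"] >= self.df["end"]).idxmax())
            raise ParseError(f"peak record {bad}: start >= end")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. pathways or GO terms."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ParseError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

_SAMPLE_RE = re.compile(r"^(?P<zt>\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


def read_expression_matrix(path, condition_label, times_h, n_replicates) -> TimecourseMatrix:
    """Read a gene x sample TSV into a validated :class:`TimecourseMatrix`.

    The header row carries sample names; the first column carries gene ids.
    The column count must equal ``sum(n_replicates)``.  ``NA`` cells become
    masked entries; any other non-numeric or negative cell is rejected with
    the offending gene/sample named.
    """
    times_h = np.asarray(times_h, dtype=float)
    n_replicates = np.asarray(n_replicates, dtype=int)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if raw.index.name is None and raw.index.hasnans:
        raise ParseError(f"{path}: malformed header or missing gene-id column")
    n_expected = int(n_replicates.sum())
    if raw.shape[1] != n_expected:
        raise ParseError(
            f"{path}: expected {n_expected} sample columns "
            f"(sum of replicates), found {raw.shape[1]}"
        )
    gene_ids = [str(g) for g in raw.index]
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise ParseError(f"{path}: duplicate gene id {g!r}")
        seen.add(g)

    missing = raw.isna() | (raw == "NA")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing
    if bad.to_numpy().any():
        gi, ci = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[gi, ci]!r} at gene "
            f"{gene_ids[gi]!r}, column {raw.columns[ci]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    mask = missing.to_numpy(dtype=bool)
    values = np.where(mask, 0.0, values)
    neg = (values < 0) & ~mask
    if neg.any():
        gi, ci = np.argwhere(neg)[0]
        raise ParseError(
            f"{path}: negative value at gene {gene_ids[gi]!r}, "
            f"column {raw.columns[ci]!r}"
        )
    return TimecourseMatrix(
        gene_ids=gene_ids,
        condition=condition_label,
        times_h=times_h,
        n_replicates=n_replicates,
        values=values,
        missing_mask=mask,
    )


def write_expression_matrix(matrix: TimecourseMatrix, path) -> None:
    """Write a TimecourseMatrix as TSV, masked cells as ``NA``."""
    out = pd.DataFrame(
        np.where(matrix.missing_mask, np.nan, matrix.values),
        index=pd.Index(matrix.gene_ids, name="gene_id"),
        columns=matrix.sample_names(),
    )
    # shortest round-trippable float repr, so write/read is value-identical
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# BED-like interval files
# ---------------------------------------------------------------------------


def _bed_rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed_intervals(path, kind: str):
    """Read a BED-like file as a :class:`SiteTable` or :class:`PeakTable`.

    ``kind='sites'`` interprets columns 4-6 as tf_name, bbls, site_fdr;
    ``kind='peaks'`` uses only the first three columns.  Extra columns are
    ignored with a warning.  Coordinates are kept 0-based half-open exactly
    as in the file.
    """
    if kind not in ("sites", "peaks"):
        raise ValueError(f"kind must be 'sites' or 'peaks', got {kind!r}")
    n_needed = 6 if kind == "sites" else 3
    records = []
    warned = False
    for lineno, cols in _bed_rows(path):
        if len(cols) < n_needed:
            raise ParseError(f"{path}:{lineno}: expected >= {n_needed} columns")
        if len(cols) > n_needed and not warned:
            logger.warning("%s: ignoring columns beyond %d", path, n_needed)
            warned = True
        chrom = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        if kind == "sites":
            tf = cols[3]
            try:
                bbls, fdr = float(cols[4]), float(cols[5])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric bbls/fdr") from None
            if not 0.0 <= fdr <= 1.0:
                raise ParseError(f"{path}:{lineno}: site_fdr {fdr} outside [0, 1]")
            records.append((chrom, start, end, tf, bbls, fdr))
        else:
            records.append((chrom, start, end))
    if kind == "sites":
        df = pd.DataFrame(records, columns=list(SiteTable.COLUMNS))
        return SiteTable(df)
    df = pd.DataFrame(records, columns=list(PeakTable.COLUMNS))
    return PeakTable(df)


def write_sites_bed(sites: SiteTable, path) -> None:
    sites.df.to_csv(path, sep="\t", header=False, index=False)


def write_peaks_bed(peaks: PeakTable, path) -> None:
    peaks.df.to_csv(path, sep="\t", header=False, index=False)


def read_gene_annotation(path) -> GeneAnnotation:
    """Read gene TSS annotation from BED6 (name = gene id, col 6 = strand).

    The TSS is the start of the interval for + strand genes and ``end - 1``
    for - strand genes (for the 1-bp intervals this package writes, both
    reduce to the same coordinate).
    """
    records: dict[str, tuple[str, int, str]] = {}
    for lineno, cols in _bed_rows(path):
        if len(cols) < 6:
            raise ParseError(f"{path}:{lineno}: TSS annotation needs 6 columns")
        chrom, start, end, gene_id, _score, strand = cols[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if start_i >= end_i:
            raise ParseError(f"{path}:{lineno}: start >= end")
        if gene_id in records:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
        tss = start_i if strand == "+" else end_i - 1
        records[gene_id] = (chrom, tss, strand)
    return GeneAnnotation(records)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for gene_id, (chrom, tss, strand) in annotation.records.items():
            fh.write(f"{chrom}\t{tss}\t{tss + 1}\t{gene_id}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file; duplicate members collapse, duplicate names error."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description, >= 1 member"
                )
            name, desc, members = cols[0], cols[1], [c for c in cols[2:] if c]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")
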