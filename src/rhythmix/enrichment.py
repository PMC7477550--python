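"""Promoter TFBS enrichment, cross-condition meta-analysis and target sets.

For each TF, genes are marked as "has a binding site" when a quality-
filtered site (conservation score bbls strictly above threshold, per-site
FDR strictly below threshold) overlaps the strand-aware promoter window
around their TSS (-10000/+2000 bp by default).  A one-sided Fisher exact
test compares the rhythmic gene set against the rest of the expressed
background, TFs are ranked by -log10 p, and TFs with degenerate motifs
(more than 50000 filtered sites genome-wide) are excluded.  A meta-
analysis across conditions flags TFs significant in exactly one condition
as condition-exclusive.  Target-gene sets combine motif sites in a
narrower -3000/+1000 window with ChIP-peak support.  A generic gene-set
(GMT) hypergeometric enrichment with Benjamini-Hochberg q-values is also
provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import GeneAnnotation, GeneSetCollection, PeakTable, SiteTable

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterWindow",
    "SiteFilter",
    "EnrichmentRecord",
    "ENRICHMENT_WINDOW",
    "TARGET_WINDOW",
    "promoter_interval",
    "genes_with_site",
    "fisher_enrichment",
    "meta_exclusive_tfs",
    "build_target_set",
    "gene_set_enrichment",
]


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware window around the TSS, in bp (both arms >= 0)."""

    upstream_bp: int
    downstream_bp: int

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window arms must be >= 0")
        if self.upstream_bp == 0 and self.downstream_bp == 0:
            raise ValueError("window must be nonempty")


ENRICHMENT_WINDOW = PromoterWindow(10_000, 2_000)
TARGET_WINDOW = PromoterWindow(3_000, 1_000)


@dataclass(frozen=True)
class SiteFilter:
    """Site-quality thresholds; all comparisons are strict."""

    min_bbls: float = 1.0
    max_site_fdr: float = 0.25
    max_sites_per_tf: int = 50_000

    def __post_init__(self) -> None:
        if self.max_sites_per_tf < 1:
            raise ValueError("max_sites_per_tf must be >= 1")

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        return df[(df["bbls"] > self.min_bbls)
                  & (df["site_fdr"] < self.max_site_fdr)]


DEFAULT_FILTER = SiteFilter()


@dataclass
class EnrichmentRecord:
    """One TF's 2x2 test against the background.

    k: set genes with a site, m: set genes without, big_k: background-
    complement genes with a site, big_m: without.  ``excluded_reason`` is
    set (and the test skipped) for degenerate motifs.
    """

    tf_name: str
    k: int
    m: int
    big_k: int
    big_m: int
    odds_ratio: float
    p_one_sided: float
    neg_log10_p: float
    excluded_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "tf": self.tf_name, "k": self.k, "m": self.m,
            "K": self.big_k, "M": self.big_m,
            "odds_ratio": None if math.isinf(self.odds_ratio) else self.odds_ratio,
            "p": self.p_one_sided, "neg_log10_p": self.neg_log10_p,
            "excluded_reason": self.excluded_reason,
        }


# ---------------------------------------------------------------------------
# promoter-window site lookup
# ---------------------------------------------------------------------------


def promoter_interval(chrom: str, tss: int, strand: str,
                      window: PromoterWindow) -> tuple[str, int, int]:
    """Half-open genomic interval of a strand-aware promoter window.

    For + strand genes the window is [tss - up, tss + down); for - strand
    genes "upstream" extends to larger coordinates, giving
    [tss - down + 1, tss + up + 1) so that the window covers the same
    offsets relative to the direction of transcription.
    """
    if strand == "+":
        lo, hi = tss - window.upstream_bp, tss + window.downstream_bp
    else:
        lo = tss - window.downstream_bp + 1
        hi = tss + window.upstream_bp + 1
    return chrom, max(0, lo), max(0, hi)


def _interval_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int)))
    return trees


def _genes_hit(trees: dict[str, IntervalTree], annotation: GeneAnnotation,
               genes, window: PromoterWindow) -> set[str]:
    hits = set()
    for g in genes:
        if g not in annotation:
            continue
        chrom, tss, strand = annotation.tss(g)
        c, lo, hi = promoter_interval(chrom, tss, strand, window)
        tree = trees.get(c)
        if tree is not None and tree.overlap(lo, hi):
            hits.add(g)
    return hits


def genes_with_site(tf: str, site_table: SiteTable, annotation: GeneAnnotation,
                    window: PromoterWindow = ENRICHMENT_WINDOW,
                    site_filter: SiteFilter = DEFAULT_FILTER,
                    genes=None) -> set[str]:
    """Genes with >= 1 quality-filtered site of ``tf`` in their promoter.

    A site qualifies when it overlaps the strand-aware window by >= 1 bp
    (intervals half-open).  Unknown TFs yield an empty set with a warning.
    """
    sub = site_table.for_tf(tf)
    if len(sub) == 0:
        logger.warning("genes_with_site: TF %r has no sites", tf)
        return set()
    sub = site_filter.apply(sub)
    if len(sub) == 0:
        return set()
    trees = _interval_trees(sub)
    genes = annotation.records.keys() if genes is None else genes
    return _genes_hit(trees, annotation, genes, window)


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(gene_set, background, tf_names, site_table: SiteTable,
                      annotation: GeneAnnotation,
                      window: PromoterWindow = ENRICHMENT_WINDOW,
                      site_filter: SiteFilter = DEFAULT_FILTER,
                      ) -> list[EnrichmentRecord]:
    """One-sided Fisher promoter enrichment for each TF, ranked by -log10 p.

    The 2x2 table is {in set} x {has site} with the non-set margin equal to
    ``background - gene_set`` (disjoint cells).  TFs whose filtered site
    count exceeds the degenerate-motif cap are excluded from testing but
    still reported with ``excluded_reason`` set.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of the background")
    complement = background - gene_set
    records = []
    for tf in tf_names:
        filtered = site_filter.apply(site_table.for_tf(tf))
        if len(filtered) > site_filter.max_sites_per_tf:
            records.append(EnrichmentRecord(
                tf_name=tf, k=0, m=len(gene_set), big_k=0, big_m=len(complement),
                odds_ratio=float("nan"), p_one_sided=1.0, neg_log10_p=0.0,
                excluded_reason="degenerate motif (site count above cap)"))
            continue
        if len(filtered) == 0:
            hit: set[str] = set()
        else:
            trees = _interval_trees(filtered)
            hit = _genes_hit(trees, annotation, background, window)
        k = len(gene_set & hit)
        m = len(gene_set) - k
        big_k = len(complement & hit)
        big_m = len(complement) - big_k
        odds, p = stats.fisher_exact([[k, m], [big_k, big_m]],
                                     alternative="greater")
        p = float(min(max(p, 5e-324), 1.0))
        records.append(EnrichmentRecord(
            tf_name=tf, k=k, m=m, big_k=big_k, big_m=big_m,
            odds_ratio=float(odds), p_one_sided=p,
            neg_log10_p=float(-math.log10(p))))
    records.sort(key=lambda r: (-r.neg_log10_p, r.tf_name))
    return records


def meta_exclusive_tfs(records_by_condition: dict[str, list[EnrichmentRecord]],
                       alpha_tf: float = 0.01) -> pd.DataFrame:
    """Cross-condition meta-analysis flagging condition-exclusive TFs.

    A TF is exclusive to condition c when p(c) <= alpha_tf and p > alpha_tf
    everywhere else; significant in several conditions -> "shared",
    nowhere -> "none".  Excluded (degenerate) TFs count as non-significant.
    Requires a common TF universe across conditions.
    """
    conditions = list(records_by_condition)
    universes = {c: {r.tf_name for r in recs}
                 for c, recs in records_by_condition.items()}
    universe = set.union(*universes.values())
    for c, u in universes.items():
        if not u & set.union(*(universes[o] for o in conditions if o != c)) \
                and len(conditions) > 1:
            raise ValueError(f"condition {c!r} shares no TFs with the others")
    by_cond = {c: {r.tf_name: r for r in recs}
               for c, recs in records_by_condition.items()}
    rows = []
    for tf in sorted(universe):
        ps = {}
        nlps = {}
        for c in conditions:
            rec = by_cond[c].get(tf)
            if rec is None or rec.excluded_reason is not None:
                ps[c], nlps[c] = 1.0, 0.0
            else:
                ps[c], nlps[c] = rec.p_one_sided, rec.neg_log10_p
        sig = [c for c in conditions if ps[c] <= alpha_tf]
        label = sig[0] if len(sig) == 1 else ("shared" if sig else "none")
        rows.append({"tf": tf, **{f"neg_log10_p_{c}": nlps[c] for c in conditions},
                     "exclusive_to": label})
    return pd.DataFrame(rows).set_index("tf")


# ---------------------------------------------------------------------------
# target sets and generic gene-set enrichment
# ---------------------------------------------------------------------------


def build_target_set(tf: str, site_table: SiteTable, peaks: PeakTable,
                     annotation: GeneAnnotation,
                     window: PromoterWindow = TARGET_WINDOW,
                     site_filter: SiteFilter = DEFAULT_FILTER,
                     require_peak: bool = True) -> set[str]:
    """Putative target genes of a TF from motif plus ChIP evidence.

    A gene qualifies when it has a filtered motif site in the (narrow)
    promoter window and, when ``require_peak``, at least one ChIP peak
    overlapping the same window.
    """
    motif_genes = genes_with_site(tf, site_table, annotation,
                                  window=window, site_filter=site_filter)
    if not require_peak:
        return motif_genes
    if len(peaks) == 0:
        return set()
    trees = _interval_trees(peaks.df)
    return _genes_hit(trees, annotation, motif_genes, window)


def gene_set_enrichment(gene_set, background,
                        collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric enrichment of ``gene_set`` against a GMT collection.

    Set members are intersected with the background before testing; the
    one-sided p is P(X >= k).  q-values are Benjamini-Hochberg across all
    tested sets; output ranked by -log10 p.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of the background")
    n_bg = len(background)
    n_set = len(gene_set)
    rows = []
    for name, members in collection.sets.items():
        eff = members & background
        if not eff:
            continue
        k = len(gene_set & eff)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(eff), n_set))
        p = min(max(p, 5e-324), 1.0)
        rows.append({"set_name": name, "n_members": len(eff), "k": k,
                     "p": p, "neg_log10_p": -math.log10(p),
                     "description": collection.descriptions.get(name, "")})
    if not rows:
        logger.warning("gene_set_enrichment: no set overlaps the background")
        return pd.DataFrame(columns=["set_name", "n_members", "k", "p",
                                     "neg_log10_p", "q", "description"]
                            ).set_index("set_name")
    df = pd.DataFrame(rows).set_index("set_name")
    df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    return df.sort_values(["neg_log10_p", "set_name"],
                          ascending=[False, True])
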