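"""Assign transposable elements (TEs) to genes by genomic proximity.

Two window definitions are provided, matching the two analyses they feed:

* ``pair_by_tss_window`` — a TE is assigned to a gene when its interval lies
  within ``window_kb`` of the gene's transcription start site (TSS), edge to
  point, boundary inclusive.  Feeds the relative-coexpression analysis
  (default 10 kb).
* ``pair_by_upstream_promoter`` — a TE is assigned when it overlaps the
  strand-aware promoter interval covering ``promoter_kb`` upstream of the
  gene's longest transcript (windowBed-style half-open overlap, default
  20 kb).  Feeds the binomial enrichment analysis.

All internal arithmetic is 0-based half-open; GTF input (1-based closed) is
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "TEElement",
    "TEAnnotation",
    "GeneTEPairing",
    "pair_by_tss_window",
    "pair_by_upstream_promoter",
    "te_gene_indicator",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS and transcript extents.

    ``transcripts`` are (start, end) pairs in 0-based half-open coordinates,
    all on ``chrom``/``strand``.  The TSS is the 5' end of the strand: the
    smallest start on '+', one less than the largest end on '-' (i.e. the
    last covered base).
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: at least one transcript required")
        for s, e in self.transcripts:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty transcript interval [{s}, {e})")
        # canonical order so equality is representation-independent
        object.__setattr__(self, "transcripts", tuple(sorted(self.transcripts)))

    @property
    def tss(self) -> int:
        """0-based coordinate of the transcription start site."""
        if self.strand == "+":
            return min(s for s, _ in self.transcripts)
        return max(e for _, e in self.transcripts) - 1

    @property
    def longest_transcript(self) -> tuple[int, int]:
        return max(self.transcripts, key=lambda t: (t[1] - t[0], -t[0]))

    def promoter_interval(self, promoter_kb: float) -> tuple[int, int]:
        """Half-open interval covering promoter_kb kb upstream of the
        longest transcript's 5' end, truncated at position 0."""
        span = int(round(promoter_kb * 1000))
        s, e = self.longest_transcript
        if self.strand == "+":
            return max(0, s - span), s
        return e, e + span


@dataclass(frozen=True)
class TEElement:
    te_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"
    family: str = "THE1B"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.te_id}: start must be < end")
        if not self.family:
            raise ValueError(f"{self.te_id}: empty family label")


@dataclass
class TEAnnotation:
    elements: list[TEElement]

    def __iter__(self):
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class GeneTEPairing:
    gene_id: str
    te_id: str
    distance: int
    mode: str  # "tss_window" | "upstream_promoter"
    window_kb: float


def _point_interval_distance(point: int, start: int, end: int) -> int:
    """Gap (bp) between a point and a half-open interval; 0 if the point is
    inside.  For an interval entirely left of the point the gap is measured
    from the interval's (exclusive) end, windowBed-style."""
    if point < start:
        return start - point
    if point >= end:
        return point - end
    return 0


def pair_by_tss_window(
    te: TEAnnotation,
    genes: Sequence[GeneModel],
    window_kb: float = 10,
) -> list[GeneTEPairing]:
    """Pair every (gene, TE) whose TE interval lies within ``window_kb`` of
    the gene's TSS (unsigned edge-to-point distance, boundary inclusive)."""
    span = int(round(window_kb * 1000))
    gene_chroms = {g.chrom for g in genes}
    trees: dict[str, IntervalTree] = {}
    for i, el in enumerate(te):
        if el.chrom not in gene_chroms:
            logger.warning("TE %s on chromosome %s absent from gene models; skipped",
                           el.te_id, el.chrom)
            continue
        trees.setdefault(el.chrom, IntervalTree()).addi(el.start, el.end, i)
    out: list[GeneTEPairing] = []
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        tss = g.tss
        # query window widened by 1 so an exact-boundary TE edge is found
        for iv in sorted(tree.overlap(tss - span, tss + span + 1)):
            el = te.elements[iv.data]
            d = _point_interval_distance(tss, el.start, el.end)
            if d <= span:
                out.append(GeneTEPairing(g.gene_id, el.te_id, d, "tss_window", window_kb))
    return out


def pair_by_upstream_promoter(
    te: TEAnnotation,
    genes: Sequence[GeneModel],
    promoter_kb: float = 20,
) -> list[GeneTEPairing]:
    """Pair every (gene, TE) where the TE overlaps (>=1 bp, half-open
    arithmetic) the strand-aware promoter interval upstream of the gene's
    longest transcript."""
    gene_chroms = {g.chrom for g in genes}
    trees: dict[str, IntervalTree] = {}
    for i, el in enumerate(te):
        if el.chrom not in gene_chroms:
            logger.warning("TE %s on chromosome %s absent from gene models; skipped",
                           el.te_id, el.chrom)
            continue
        trees.setdefault(el.chrom, IntervalTree()).addi(el.start, el.end, i)
    out: list[GeneTEPairing] = []
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        ps, pe = g.promoter_interval(promoter_kb)
        if ps >= pe:
            continue
        for iv in sorted(tree.overlap(ps, pe)):
            el = te.elements[iv.data]
            out.append(GeneTEPairing(g.gene_id, el.te_id, 0, "upstream_promoter", promoter_kb))
    return out


def te_gene_indicator(
    pairings: Iterable[GeneTEPairing],
    genes: Sequence[GeneModel],
) -> tuple[pd.Series, pd.Series]:
    """Collapse pairings to a per-gene TE indicator and raw TE count.

    Returns ``(has_te, count)`` as boolean / integer Series over the full
    gene universe (genes with no pairing get False / 0).
    """
    gene_ids = [g.gene_id for g in genes]
    count = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), dtype=int)
    for p in pairings:
        if p.gene_id in count.index:
            count[p.gene_id] += 1
    return count > 0, count
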