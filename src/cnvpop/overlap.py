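"""Interval comparison: external CNVR catalogues, QTL tables, gene capture.

All operations use 0-based half-open coordinates internally; files in
1-based inclusive dialects are converted on load via an explicit dialect
flag.  Overlap accounting follows the convention of cross-study CNVR
comparisons: a reference record counts as overlapped when it shares at
least one base with any query region, and the reported percentage is taken
over the reference catalogue's size.  Gene capture keeps genes whose length
is covered completely or at least 50 % by the query regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from cnvpop.cnvr import Cnvr, round_half_up

__all__ = [
    "LabelledIntervalSet",
    "OverlapReport",
    "QtlReport",
    "GeneCapture",
    "overlap_sets",
    "overlap_qtl",
    "annotate_genes",
]


@dataclass(frozen=True)
class LabelledIntervalSet:
    """Named collection of labelled intervals on one coordinate convention."""

    name: str
    records: tuple[tuple[str, int, int, str, str], ...]  # chrom,start,end,label,payload

    def __post_init__(self) -> None:
        for chrom, start, end, label, _payload in self.records:
            if end <= start:
                raise ValueError(
                    f"{self.name}: record {label!r} on {chrom} has end <= start"
                )

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(cls, name: str, records) -> "LabelledIntervalSet":
        rows = []
        for rec in records:
            chrom, start, end, label = rec[0], int(rec[1]), int(rec[2]), str(rec[3])
            payload = str(rec[4]) if len(rec) > 4 else ""
            rows.append((str(chrom), start, end, label, payload))
        return cls(name, tuple(rows))

    @classmethod
    def read(cls, path, name: str | None = None, dialect: str = "bed") -> "LabelledIntervalSet":
        """Load a 4+-column TSV of intervals.

        ``dialect="bed"`` means 0-based half-open as stored;
        ``dialect="one-based"`` means 1-based inclusive and is converted
        (start-1, end unchanged) on load.
        """
        if dialect not in ("bed", "one-based"):
            raise ValueError(f"unknown coordinate dialect {dialect!r}")
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str}, comment="#")
        if df.shape[1] < 4:
            raise ValueError(f"{path}: need at least 4 columns (chrom,start,end,label)")
        rows = []
        for r in df.itertuples(index=False):
            chrom, start, end, label = str(r[0]), int(r[1]), int(r[2]), str(r[3])
            payload = str(r[4]) if df.shape[1] > 4 else ""
            if dialect == "one-based":
                start -= 1
            rows.append((chrom, start, end, label, payload))
        return cls(name or str(path), tuple(rows))


@dataclass(frozen=True)
class OverlapReport:
    query_name: str
    reference_name: str
    n_reference: int
    n_reference_overlapped: int
    overlap_percentage: float
    pairs: tuple[tuple[str, str], ...]  # (query id, reference label)


@dataclass(frozen=True)
class QtlReport:
    n_cnvrs_associated: int
    n_qtl_labels_hit: int
    label_counts: dict[str, int]  # label -> number of CNVR/QTL overlap pairs
    pairs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class GeneCapture:
    captured: dict[str, float]  # gene label -> fraction of gene covered
    by_cnvr: dict[str, tuple[tuple[str, float], ...]]  # cnvr id -> (gene, pair fraction)


def _query_trees(query: list[Cnvr]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for c in query:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, c.id)
    return trees


def overlap_sets(query: list[Cnvr], reference: LabelledIntervalSet) -> OverlapReport:
    """Count reference records overlapped (>= 1 bp) by any query CNVR.

    The percentage denominator is the reference catalogue's record count,
    matching how CNVR surveys report agreement with earlier studies.
    """
    trees = _query_trees(query)
    pairs: list[tuple[str, str]] = []
    n_overlapped = 0
    for chrom, start, end, label, _payload in reference.records:
        hits = trees[chrom].overlap(start, end) if chrom in trees else ()
        if hits:
            n_overlapped += 1
            for h in sorted(hits, key=lambda iv: (iv.begin, iv.end, iv.data)):
                pairs.append((h.data, label))
    n_ref = len(reference)
    pct = round_half_up(100.0 * n_overlapped / n_ref) if n_ref else 0.0
    return OverlapReport(
        query_name="query",
        reference_name=reference.name,
        n_reference=n_ref,
        n_reference_overlapped=n_overlapped,
        overlap_percentage=pct,
        pairs=tuple(pairs),
    )


def overlap_qtl(query: list[Cnvr], qtl: LabelledIntervalSet) -> QtlReport:
    """Associate query CNVRs with QTL intervals carrying trait labels.

    Returns the number of CNVRs hitting at least one QTL, the number of
    distinct trait labels hit, and per-label overlap-pair counts.
    """
    qtl_trees: dict[str, IntervalTree] = {}
    for chrom, start, end, label, _payload in qtl.records:
        qtl_trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
    associated: set[str] = set()
    labels_hit: set[str] = set()
    label_counts: dict[str, int] = {}
    pairs: list[tuple[str, str]] = []
    for c in query:
        hits = qtl_trees[c.chrom].overlap(c.start, c.end) if c.chrom in qtl_trees else ()
        if hits:
            associated.add(c.id)
        for h in sorted(hits, key=lambda iv: (iv.begin, iv.end, iv.data)):
            labels_hit.add(h.data)
            label_counts[h.data] = label_counts.get(h.data, 0) + 1
            pairs.append((c.id, h.data))
    return QtlReport(len(associated), len(labels_hit), label_counts, tuple(pairs))


def annotate_genes(
    query: list[Cnvr],
    genes: LabelledIntervalSet,
    min_fraction: float = 0.5,
) -> GeneCapture:
    """Capture genes completely or partially (>= ``min_fraction``) overlapped.

    The fraction is taken over the GENE's length, summed across all query
    CNVRs touching it (merged CNVRs are disjoint so overlaps never double
    count).  The inclusive bound means a gene exactly half covered is kept.
    """
    trees = _query_trees(query)
    captured: dict[str, float] = {}
    by_cnvr: dict[str, list[tuple[str, float]]] = {}
    for chrom, start, end, label, _payload in genes.records:
        gene_len = end - start
        if gene_len <= 0:
            raise ValueError(f"zero-length gene {label!r}")
        hits = trees[chrom].overlap(start, end) if chrom in trees else ()
        total_ov = 0
        pair_fracs: list[tuple[str, float]] = []
        for h in sorted(hits, key=lambda iv: (iv.begin, iv.end, iv.data)):
            ov = min(end, h.end) - max(start, h.begin)
            total_ov += ov
            pair_fracs.append((h.data, ov / gene_len))
        fraction = total_ov / gene_len
        if fraction >= min_fraction:
            captured[label] = fraction
            for cnvr_id, frac in pair_fracs:
                by_cnvr.setdefault(cnvr_id, []).append((label, frac))
    return GeneCapture(
        captured, {k: tuple(v) for k, v in by_cnvr.items()}
    )
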