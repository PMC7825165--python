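"""Brute-force interval oracles used to cross-check the fast implementations.

Everything here is deliberately naive (all-pairs scans, per-base boolean
masks on toy chromosomes) and shares no code with the package's sweep-line
and interval-tree implementations.
"""

from __future__ import annotations

import numpy as np


def has_overlap(a_start, a_end, b_start, b_end) -> bool:
    """Half-open intervals share at least one base."""
    return a_start < b_end and b_start < a_end


def connected_components_regions(intervals):
    """Brute-force Redon aggregation: all-pairs overlap graph components.

    ``intervals`` is a list of (chrom, start, end).  Returns the sorted list
    of (chrom, start, end) component hulls plus, for each input index, the
    component it belongs to.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and has_overlap(si, ei, sj, ej):
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    regions = []
    labels = [0] * n
    for members in comps.values():
        chrom = intervals[members[0]][0]
        start = min(intervals[m][1] for m in members)
        end = max(intervals[m][2] for m in members)
        regions.append((chrom, start, end))
        for m in members:
            labels[m] = (chrom, start, end)
    return sorted(regions), labels


def count_overlapped_references(queries, references) -> int:
    """All-pairs: number of reference intervals hit by >= 1 query interval."""
    n = 0
    for rc, rs, re in references:
        if any(qc == rc and has_overlap(qs, qe, rs, re) for qc, qs, qe in queries):
            n += 1
    return n


def qtl_associations(queries, qtls):
    """All-pairs (CNVR index, QTL label) overlap pairs."""
    pairs = []
    for qi, (qc, qs, qe) in enumerate(queries):
        for tc, ts, te, label in qtls:
            if qc == tc and has_overlap(qs, qe, ts, te):
                pairs.append((qi, label))
    return pairs


def gene_coverage_fraction(queries, gene, chrom_len: int) -> float:
    """Per-base mask: fraction of the gene covered by the union of queries."""
    gc, gs, ge = gene
    mask = np.zeros(chrom_len, dtype=bool)
    for qc, qs, qe in queries:
        if qc == gc:
            mask[qs:qe] = True
    return float(mask[gs:ge].mean())
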