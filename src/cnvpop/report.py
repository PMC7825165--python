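"""Report rendering and the printed-table arithmetic used in CNV surveys.

Rounding rules match how cohort CNV tables are printed: lengths to 2
decimals in Mb/kb, percentages to 2 decimals.  Coordinates are converted to
1-based inclusive spans only here, at the report boundary.

The :mod:`cnvpop.data` TSVs bundle the published per-group summary and
cross-study comparison entries for resequenced Chinese fine-wool sheep
cohorts; they serve as worked-example inputs whose derived columns (event
totals, mean lengths, overlap percentages) this module recomputes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from cnvpop.cnvr import CnvrSummary, round_half_up
from cnvpop.overlap import OverlapReport

__all__ = [
    "mean_length_kb",
    "mean_per_individual",
    "overlap_percentage",
    "one_based_span",
    "load_cohort_tables",
    "load_comparison_table",
    "render_summary_table",
    "render_overlap_table",
]


def mean_length_kb(total_mb: float, count: int) -> float:
    """Mean region length in kb from a printed total (Mb) and a count."""
    if count <= 0:
        raise ValueError("count must be positive")
    return round_half_up(total_mb * 1e3 / count)


def mean_per_individual(total_events: int, n_individuals: int) -> float:
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return round_half_up(total_events / n_individuals)


def overlap_percentage(n_overlapped: int, n_reference: int) -> float:
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    return round_half_up(100.0 * n_overlapped / n_reference)


def one_based_span(chrom: str, start: int, end: int) -> str:
    """Render a 0-based half-open interval as a 1-based inclusive span."""
    return f"{chrom}:{start + 1}-{end}"


def _data(name: str) -> pd.DataFrame:
    with resources.files("cnvpop.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["."])


def load_cohort_tables() -> pd.DataFrame:
    """Published per-group CNV/CNVR summary entries (counts, Mb, %)."""
    return _data("sheep_cohort_tables.tsv")


def load_comparison_table() -> pd.DataFrame:
    """Published cross-study CNVR catalogue sizes and overlap counts."""
    return _data("sheep_cnvr_comparisons.tsv")


_SUMMARY_HEADER = (
    "scope", "count", "duplication", "deletion", "both",
    "length_mb", "average_kb", "genome_pct",
)


def render_summary_table(summaries: list[CnvrSummary]) -> str:
    """Text table of CNVR summaries in the style of cohort CNV surveys."""
    rows = [_SUMMARY_HEADER]
    for s in summaries:
        rows.append(
            (
                s.scope,
                str(s.n_cnvrs),
                str(s.n_duplication),
                str(s.n_deletion),
                str(s.n_both),
                f"{s.total_length_mb:.2f}",
                "n.a." if s.n_cnvrs == 0 else f"{s.mean_length_kb:.2f}",
                "n.a." if s.genome_fraction_pct != s.genome_fraction_pct
                else f"{s.genome_fraction_pct:.2f}",
            )
        )
    widths = [max(len(r[i]) for r in rows) for i in range(len(_SUMMARY_HEADER))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
    )


def render_overlap_table(reports: list[OverlapReport]) -> str:
    rows = [("reference", "cnvr_count", "overlapping_count", "overlapping_pct")]
    for r in reports:
        rows.append(
            (
                r.reference_name,
                str(r.n_reference),
                str(r.n_reference_overlapped),
                f"{r.overlap_percentage:.2f}%",
            )
        )
    widths = [max(len(row[i]) for row in rows) for i in range(4)]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
    )
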