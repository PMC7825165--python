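"""CNVR construction, copy-number classification and cohort summaries.

CNV regions (CNVRs) are the connected components of the interval-overlap
graph over filtered per-individual calls (Redon-style aggregation: any two
calls sharing at least one base join the same region; abutting intervals do
not merge).  Each region is classified from its supporting individuals'
copy-number states — deleted (CN < 0.4), conserved (0.4 <= CN <= 1.6) or
duplicated (CN > 1.6) — and summarized per cohort or group the way CNV
surveys tabulate them (counts by type, total Mb, mean kb, genome fraction,
chromosome count-versus-length regression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cnvpop.caller import CnvCall
from cnvpop.synthetic import GenomeLayout

__all__ = [
    "Cnvr",
    "CnvrClassification",
    "CnvrSummary",
    "GroupPresence",
    "merge_calls",
    "classify_cnvr",
    "individual_copy_numbers",
    "summarize",
    "group_presence",
    "write_cnvrs",
    "read_cnvrs",
    "DELETED_BELOW",
    "DUPLICATED_ABOVE",
]

# Redon-style copy-number state bounds on the diploid scale
DELETED_BELOW = 0.4
DUPLICATED_ABOVE = 1.6


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention of printed tables
    (Python's built-in round is banker's and would turn 54612.625 into
    54612.62)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Cnvr:
    """A merged cross-individual copy-number-variable region."""

    id: str
    chrom: str
    start: int
    end: int
    region_type: str  # "deletion" | "duplication" | "both"
    supporting_calls: tuple[CnvCall, ...]
    groups_present: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.id}")
        for c in self.supporting_calls:
            if c.chrom != self.chrom or c.end <= self.start or c.start >= self.end:
                raise ValueError(f"supporting call {c} does not overlap {self.id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def individuals(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.supporting_calls:
            if c.individual_id not in seen:
                seen.append(c.individual_id)
        return tuple(seen)


@dataclass(frozen=True)
class CnvrClassification:
    region_type: str
    states: dict[str, str]  # individual -> deleted | conserved | duplicated
    copy_numbers: dict[str, float]  # individual -> length-weighted mean CN


@dataclass(frozen=True)
class CnvrSummary:
    scope: str
    n_cnvrs: int
    n_deletion: int
    n_duplication: int
    n_both: int
    total_length_mb: float
    mean_length_kb: float
    genome_fraction_pct: float
    per_chromosome_counts: tuple[tuple[str, int], ...]
    count_length_r2: float  # NaN when undefined


@dataclass(frozen=True)
class GroupPresence:
    per_group: dict[str, set[str]]  # group -> CNVR ids present
    venn_cells: dict[frozenset, int]  # exact group combination -> count

    def shared_by_all(self) -> int:
        all_groups = frozenset(self.per_group)
        return self.venn_cells.get(all_groups, 0)


def _region_type_from_call_types(calls) -> str:
    types = {c.call_type for c in calls}
    if types == {"deletion"}:
        return "deletion"
    if types == {"duplication"}:
        return "duplication"
    return "both"


def merge_calls(
    calls: list[CnvCall],
    population: dict[str, str] | None = None,
    min_support: int = 1,
) -> list[Cnvr]:
    """Aggregate overlapping calls from different individuals into CNVRs.

    Overlap must be at least 1 bp: abutting half-open intervals ([100,200)
    and [200,300)) stay separate.  Every input call lands in exactly one
    CNVR; output is sorted by (chrom, start) with sequential ids.
    ``population`` (individual -> group) fills ``groups_present``.
    ``min_support`` keeps only regions supported by at least that many
    distinct individuals (default 1: any single call founds a region).
    """
    for c in calls:
        if c.end <= c.start:
            raise ValueError(f"malformed interval in call {c}")
    if not calls:
        return []

    chrom_order: list[str] = []
    for c in calls:
        if c.chrom not in chrom_order:
            chrom_order.append(c.chrom)
    chrom_order.sort()

    ordered = sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.individual_id))
    cnvrs: list[Cnvr] = []
    cluster: list[CnvCall] = []

    def flush() -> None:
        if not cluster:
            return
        start = min(c.start for c in cluster)
        end = max(c.end for c in cluster)
        groups: set[str] = set()
        if population is not None:
            for c in cluster:
                if c.individual_id not in population:
                    raise KeyError(
                        f"individual {c.individual_id!r} missing from population table"
                    )
                groups.add(population[c.individual_id])
        cnvrs.append(
            Cnvr(
                f"CNVR_{len(cnvrs) + 1:05d}",
                cluster[0].chrom,
                start,
                end,
                _region_type_from_call_types(cluster),
                tuple(cluster),
                frozenset(groups),
            )
        )
        cluster.clear()

    cur_chrom, cur_end = None, -1
    for c in ordered:
        if c.chrom != cur_chrom or c.start >= cur_end:
            flush()
            cur_chrom, cur_end = c.chrom, c.end
        else:
            cur_end = max(cur_end, c.end)
        cluster.append(c)
    flush()
    if min_support > 1:
        kept = [c for c in cnvrs if len(c.individuals) >= min_support]
        cnvrs = [
            Cnvr(f"CNVR_{i + 1:05d}", c.chrom, c.start, c.end, c.region_type,
                 c.supporting_calls, c.groups_present)
            for i, c in enumerate(kept)
        ]
    return cnvrs


def individual_copy_numbers(cnvr: Cnvr) -> dict[str, float]:
    """Length-weighted mean CN per supporting individual."""
    weights: dict[str, float] = {}
    sums: dict[str, float] = {}
    for c in cnvr.supporting_calls:
        if c.cn < 0:
            raise ValueError(f"negative copy number in call {c}")
        w = c.size
        sums[c.individual_id] = sums.get(c.individual_id, 0.0) + w * c.cn
        weights[c.individual_id] = weights.get(c.individual_id, 0.0) + w
    return {ind: sums[ind] / weights[ind] for ind in sums}


def classify_cnvr(
    cnvr: Cnvr,
    deleted_below: float = DELETED_BELOW,
    duplicated_above: float = DUPLICATED_ABOVE,
) -> CnvrClassification:
    """Assign per-individual CN states and the region type.

    States follow the diploid-scale bounds: deleted (CN < 0.4), conserved
    (0.4 <= CN <= 1.6, bounds inclusive) or duplicated (CN > 1.6).  The
    region type is deletion/duplication/both according to which non-conserved
    states occur; conserved states never set the type, and a region whose
    states are all conserved keeps the call-type-derived label it was built
    with.
    """
    cns = individual_copy_numbers(cnvr)
    states = {}
    for ind, cn in cns.items():
        if cn < deleted_below:
            states[ind] = "deleted"
        elif cn <= duplicated_above:
            states[ind] = "conserved"
        else:
            states[ind] = "duplicated"
    present = set(states.values())
    if "deleted" in present and "duplicated" in present:
        region_type = "both"
    elif "deleted" in present:
        region_type = "deletion"
    elif "duplicated" in present:
        region_type = "duplication"
    else:
        region_type = cnvr.region_type
    return CnvrClassification(region_type, states, cns)


def summarize(
    cnvrs: list[Cnvr],
    layout: GenomeLayout | None = None,
    scope: str = "cohort",
    genome_length: int | None = None,
) -> CnvrSummary:
    """Tabulate CNVR counts by type, lengths and the count~length regression.

    Total length is reported in Mb and mean length in kb, both to 2
    decimals; genome fraction is a percentage of the analysed chromosome
    lengths.  ``count_length_r2`` is the R² of an ordinary least-squares fit
    of per-chromosome CNVR count on chromosome length (NaN when fewer than
    two chromosomes are available).
    """
    if genome_length is None and layout is not None:
        genome_length = layout.total_length
    if not cnvrs:
        return CnvrSummary(scope, 0, 0, 0, 0, 0.0, float("nan"), 0.0, (), float("nan"))

    types = [c.region_type for c in cnvrs]
    total_bp = sum(c.length for c in cnvrs)
    per_chrom: dict[str, int] = {}
    for c in cnvrs:
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1

    r2 = float("nan")
    if layout is not None and len(layout.chromosomes) >= 2:
        lengths = np.array([l for _, l in layout.chromosomes], dtype=float)
        counts = np.array(
            [per_chrom.get(name, 0) for name, _ in layout.chromosomes], dtype=float
        )
        if np.ptp(lengths) > 0 and np.ptp(counts) > 0:
            r2 = float(stats.linregress(lengths, counts).rvalue ** 2)

    return CnvrSummary(
        scope=scope,
        n_cnvrs=len(cnvrs),
        n_deletion=types.count("deletion"),
        n_duplication=types.count("duplication"),
        n_both=types.count("both"),
        total_length_mb=round_half_up(total_bp / 1e6),
        mean_length_kb=round_half_up(total_bp / 1e3 / len(cnvrs)),
        genome_fraction_pct=(
            round_half_up(100.0 * total_bp / genome_length) if genome_length else float("nan")
        ),
        per_chromosome_counts=tuple(sorted(per_chrom.items())),
        count_length_r2=r2,
    )


def group_presence(
    cnvrs: list[Cnvr], population: dict[str, str]
) -> GroupPresence:
    """Per-group CNVR presence sets and exact-combination (Venn) cell counts.

    A CNVR is present in a group iff at least one supporting individual
    belongs to it.  Venn cells partition the CNVRs, so cell counts sum to
    the number of regions.
    """
    groups = sorted(set(population.values()))
    per_group: dict[str, set[str]] = {g: set() for g in groups}
    cells: dict[frozenset, int] = {}
    for cnvr in cnvrs:
        present: set[str] = set()
        for ind in cnvr.individuals:
            if ind not in population:
                raise KeyError(f"individual {ind!r} missing from population table")
            present.add(population[ind])
        for g in present:
            per_group[g].add(cnvr.id)
        key = frozenset(present)
        cells[key] = cells.get(key, 0) + 1
    return GroupPresence(per_group, cells)


def write_cnvrs(cnvrs: list[Cnvr], path) -> None:
    """BED-like TSV: region, type, supporting individuals, groups present."""
    rows = []
    for c in cnvrs:
        rows.append(
            (
                c.chrom,
                c.start,
                c.end,
                c.id,
                c.region_type,
                ",".join(c.individuals),
                ",".join(sorted(c.groups_present)) or ".",
            )
        )
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "id", "type", "individuals", "groups"],
    ).to_csv(path, sep="\t", header=False, index=False)


def read_cnvrs(path) -> list[Cnvr]:
    """Read regions written by :func:`write_cnvrs` (supporting calls are not
    round-tripped; coordinate/type/group information is)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "id", "type", "individuals", "groups"],
        dtype={"chrom": str},
    )
    out = []
    for r in df.itertuples():
        groups = frozenset() if r.groups == "." else frozenset(str(r.groups).split(","))
        out.append(
            Cnvr(r.id, r.chrom, int(r.start), int(r.end), r.type, (), groups)
        )
    return out
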