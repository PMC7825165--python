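"""VST: population differentiation of copy number between two groups.

VST = (VT - VS) / VT, the copy-number analogue of FST: VT is the sample
variance of the signal pooled over both groups and VS the size-weighted mean
of the within-group sample variances.  The per-window signal here is
normalized read depth on the diploid scale (resequencing has no SNP-array
log-R ratio; normalized RD carries the same copy-number information).
Window values are averaged within a CNVR to give a region-level VST, and
sweep candidates are the regions in the top fraction (default 5 %) or the
top k of the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from cnvpop.caller import NormalizedRd
from cnvpop.cnvr import Cnvr

__all__ = [
    "VstRecord",
    "window_vst",
    "vst_components",
    "cnvr_vst",
    "select_candidates",
    "write_vst_table",
]


@dataclass(frozen=True)
class VstRecord:
    """Region-level VST with its variance components (window averages)."""

    cnvr_id: str
    chrom: str
    start: int
    end: int
    vt: float
    vs: float
    vst: float
    n_windows_averaged: int
    group_sizes: tuple[int, int]


def vst_components(group_a, group_b) -> tuple[float, float, float]:
    """Return (vt, vs, vst) for two per-individual value vectors.

    Sample variances use the n-1 denominator.  A monomorphic window
    (vt == 0) is undifferentiated by convention: vst = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 individuals for a variance")
    pooled = np.concatenate([a, b])
    vt = float(pooled.var(ddof=1))
    vs = float(
        (a.size * a.var(ddof=1) + b.size * b.var(ddof=1)) / (a.size + b.size)
    )
    vst = (vt - vs) / vt if vt > 0 else 0.0
    return vt, vs, vst


def window_vst(group_a, group_b) -> float:
    """VST of one window: (VT - VS)/VT with VS size-weighted; 0 when VT = 0."""
    return vst_components(group_a, group_b)[2]


def cnvr_vst(
    cnvr: Cnvr,
    norm_tracks: dict[str, NormalizedRd],
    groups: dict[str, str],
) -> VstRecord:
    """Average window VST over a CNVR using normalized depth as the signal.

    Every individual in ``groups`` must have a track covering the region;
    exactly two group labels are required.  Windows with zero pooled
    variance contribute 0 to the average.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    members = {g: sorted(i for i, gg in groups.items() if gg == g) for g in labels}

    any_track = next(iter(norm_tracks.values()))
    ws = any_track.layout.window_size
    i0, i1 = cnvr.start // ws, -(-cnvr.end // ws)  # windows overlapping the region
    for ind in groups:
        if ind not in norm_tracks:
            raise KeyError(f"no normalized track for individual {ind!r}")
        track = norm_tracks[ind]
        if cnvr.chrom not in track.rd or i1 > len(track.rd[cnvr.chrom]):
            raise ValueError(f"CNVR {cnvr.id} outside track extent for {ind!r}")

    sig = {
        g: np.stack([norm_tracks[ind].rd[cnvr.chrom][i0:i1] for ind in members[g]])
        for g in labels
    }
    vts, vss, vsts = [], [], []
    for w in range(i1 - i0):
        vt, vs, vst = vst_components(sig[labels[0]][:, w], sig[labels[1]][:, w])
        vts.append(vt)
        vss.append(vs)
        vsts.append(vst)
    return VstRecord(
        cnvr_id=cnvr.id,
        chrom=cnvr.chrom,
        start=cnvr.start,
        end=cnvr.end,
        vt=float(np.mean(vts)),
        vs=float(np.mean(vss)),
        vst=float(np.mean(vsts)),
        n_windows_averaged=i1 - i0,
        group_sizes=(len(members[labels[0]]), len(members[labels[1]])),
    )


def select_candidates(
    records: list[VstRecord],
    mode: str = "top_fraction",
    value: float = 0.05,
) -> tuple[list[VstRecord], float]:
    """Pick sweep candidates: top fraction (ceil) or top k, ties at the cut kept.

    Returns the kept records (sorted by descending VST) and the threshold
    VST actually applied.
    """
    if not records:
        raise ValueError("no VST records to select from")
    if value <= 0:
        raise ValueError("selection size must be positive")
    ranked = sorted(records, key=lambda r: (-r.vst, r.cnvr_id))
    if mode == "top_fraction":
        k = ceil(value * len(ranked))
    elif mode == "top_k":
        k = int(value)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    k = min(k, len(ranked))
    threshold = ranked[k - 1].vst
    kept = [r for r in ranked if r.vst >= threshold]
    return kept, threshold


def write_vst_table(records: list[VstRecord], candidates: set[str], path) -> None:
    rows = [
        (
            r.cnvr_id, r.chrom, r.start, r.end,
            f"{r.vt:.6g}", f"{r.vs:.6g}", f"{r.vst:.6g}",
            int(r.cnvr_id in candidates),
        )
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["cnvr_id", "chrom", "start", "end", "vt", "vs", "vst", "candidate"],
    ).to_csv(path, sep="\t", index=False)
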