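"""Read-depth CNV caller: normalization, segmentation, genotyping, filtering.

The calling chain mirrors the standard read-depth approach for resequencing
data: per-window counts are rescaled so the diploid expectation is 2.0,
chromosomes are partitioned into constant-copy-number segments, segments
deviating from the diploid baseline become candidate calls genotyped by their
mean normalized depth, and calls are filtered on t-test significance
(p < 0.01), size (> 1 kb) and the fraction of zero-mapping-quality reads
(q0 < 0.5).

The segmentation here is a deterministic, explicit stand-in for mean-shift
partitioners: multi-scale Gaussian smoothing, breakpoints where the smoothed
adjacent difference is large relative to a robust noise estimate at that
scale, then merging of adjacent segments with close means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from cnvpop.synthetic import DepthProfile, GenomeLayout

__all__ = [
    "NormalizedRd",
    "Segment",
    "CnvCall",
    "normalize",
    "segment",
    "call_from_segments",
    "filter_calls",
    "call_cnvs",
    "write_calls",
    "read_calls",
    "DEFAULT_SEX_CHROMS",
]

DEFAULT_SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY", "OARX", "OARY"})


@dataclass
class NormalizedRd:
    """Genome-mean-scaled read depth: diploid expectation 2.0."""

    individual_id: str
    layout: GenomeLayout
    rd: dict[str, np.ndarray]
    global_mean_raw: float

    def autosomal_values(self, sex_chroms=DEFAULT_SEX_CHROMS) -> np.ndarray:
        return np.concatenate(
            [self.rd[c] for c in self.layout.names if c not in sex_chroms]
        )

    def genome_mean(self, sex_chroms=DEFAULT_SEX_CHROMS) -> float:
        return float(self.autosomal_values(sex_chroms).mean())


@dataclass(frozen=True)
class Segment:
    """A contiguous run of windows with homogeneous normalized depth."""

    chrom: str
    start: int
    end: int
    mean_rd: float
    n_windows: int


@dataclass(frozen=True)
class CnvCall:
    """One individual's candidate CNV with genotype and filter statistics."""

    individual_id: str
    chrom: str
    start: int
    end: int
    call_type: str  # "deletion" | "duplication"
    cn: float
    e_val: float
    q0: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")
        if self.cn < 0:
            raise ValueError(f"cn must be non-negative: {self}")
        if not 0.0 <= self.e_val <= 1.0:
            raise ValueError(f"e_val outside [0, 1]: {self}")
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError(f"q0 outside [0, 1]: {self}")

    @property
    def size(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# normalization


def _gc_correct(counts: np.ndarray, gc: np.ndarray, n_bins: int = 50) -> np.ndarray:
    """Median-per-GC-bin correction: count * global_median / bin_median."""
    bins = np.clip((gc * n_bins).astype(int), 0, n_bins - 1)
    global_median = np.median(counts)
    corrected = counts.astype(float).copy()
    for b in np.unique(bins):
        mask = bins == b
        med = np.median(counts[mask])
        if med > 0:
            corrected[mask] = counts[mask] * (global_median / med)
    return corrected


def normalize(
    depth: DepthProfile,
    trimmed: bool = True,
    trim_fraction: float = 0.1,
    gc_correct: bool = False,
    sex_chroms=DEFAULT_SEX_CHROMS,
) -> NormalizedRd:
    """Rescale windowed counts so the diploid expectation is 2.0.

    ``rd_w = 2 * count_w / mean(count)`` with the mean taken over autosomal
    windows.  By default a 10 %-trimmed mean (``trim_fraction`` cut from each
    tail) is used so large CNVs do not bias the diploid baseline; set
    ``trimmed=False`` for the plain mean.  With ``gc_correct=True`` and a GC
    track present, counts are first median-corrected per GC bin.
    """
    layout = depth.layout
    if layout.total_windows < 100:
        raise ValueError("need at least 100 windows genome-wide to normalize")

    counts = {c: depth.counts[c].astype(float) for c in layout.names}
    if gc_correct:
        if depth.gc is None:
            raise ValueError("gc_correct=True but the profile has no GC track")
        all_counts = np.concatenate([counts[c] for c in layout.names])
        all_gc = np.concatenate([depth.gc[c] for c in layout.names])
        corrected = _gc_correct(all_counts, all_gc)
        offset = 0
        for c in layout.names:
            n = layout.n_windows(c)
            counts[c] = corrected[offset : offset + n]
            offset += n

    autosomal = np.concatenate(
        [counts[c] for c in layout.names if c not in sex_chroms]
    )
    if autosomal.size == 0:
        autosomal = np.concatenate([counts[c] for c in layout.names])
    if not autosomal.any():
        raise ValueError("all-zero depth track cannot be normalized")

    if trimmed:
        mean = float(stats.trim_mean(autosomal, trim_fraction))
        if mean == 0:  # heavily zero-inflated track: fall back to plain mean
            mean = float(autosomal.mean())
    else:
        mean = float(autosomal.mean())

    rd = {c: 2.0 * counts[c] / mean for c in layout.names}
    return NormalizedRd(depth.individual_id, layout, rd, mean)


# ---------------------------------------------------------------------------
# segmentation


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def _breakpoints_one_scale(x: np.ndarray, h: float, t: float) -> list[int]:
    """Boundary indices where the smoothed adjacent difference exceeds t·σ̂.

    σ̂ is the robust (MAD-based) SD of the smoothed differences at this
    scale, so the threshold self-calibrates to the noise remaining after
    smoothing.  Within each above-threshold run only the peak difference is
    kept, placing one breakpoint per transition.
    """
    s = gaussian_filter1d(x, sigma=h, mode="nearest")
    d = np.diff(s)
    if d.size == 0:
        return []
    sd = _robust_sd(d)
    thr = max(t * sd, 1e-8)
    above = np.abs(d) > thr
    bps: list[int] = []
    i = 0
    n = len(d)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            peak = i + int(np.argmax(np.abs(d[i:j])))
            bps.append(peak + 1)  # boundary between windows peak and peak+1
            i = j
        else:
            i += 1
    return bps


def _merge_close_segments(
    bounds: list[int], means: list[float], counts: list[int], eps: float
) -> tuple[list[int], list[float], list[int]]:
    """Iteratively merge the adjacent pair with the smallest mean gap < eps."""
    bounds, means, counts = list(bounds), list(means), list(counts)
    while len(means) > 1:
        gaps = [abs(means[i + 1] - means[i]) for i in range(len(means) - 1)]
        k = int(np.argmin(gaps))
        if gaps[k] >= eps:
            break
        total = counts[k] + counts[k + 1]
        means[k] = (means[k] * counts[k] + means[k + 1] * counts[k + 1]) / total
        counts[k] = total
        del means[k + 1], counts[k + 1], bounds[k + 1]
    return bounds, means, counts


def segment(
    norm: NormalizedRd,
    bandwidths: tuple[float, ...] = (2, 4, 8, 16),
    t: float = 3.5,
    merge_eps: float = 0.3,
) -> list[Segment]:
    """Deterministically partition each chromosome into constant-RD segments.

    (1) Gaussian smoothing at each bandwidth in ``bandwidths`` (windows);
    (2) breakpoints where the smoothed adjacent difference exceeds ``t``
    robust SDs of that scale's differences, smallest scale first so precise
    boundaries win; (3) adjacent segments whose means differ by less than
    ``merge_eps`` are merged.  Segments tile every chromosome.
    """
    ws = norm.layout.window_size
    segments: list[Segment] = []
    for chrom in norm.layout.names:
        x = norm.rd[chrom]
        n = len(x)
        if n == 0:
            continue
        bps: list[int] = []
        for h in sorted(bandwidths):
            for bp in _breakpoints_one_scale(x, h, t):
                if all(abs(bp - existing) > h for existing in bps):
                    bps.append(bp)
        bps = sorted(set(bps))
        bounds = [0] + bps + [n]
        means = [float(x[bounds[i] : bounds[i + 1]].mean()) for i in range(len(bounds) - 1)]
        counts = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        bounds, means, counts = _merge_close_segments(bounds, means, counts, merge_eps)
        for i in range(len(means)):
            segments.append(
                Segment(
                    chrom,
                    bounds[i] * ws,
                    bounds[i + 1] * ws,
                    means[i],
                    counts[i],
                )
            )
    return segments


# ---------------------------------------------------------------------------
# calling and filtering


def call_from_segments(
    segments: list[Segment],
    norm: NormalizedRd,
    depth: DepthProfile,
    call_threshold: float = 0.5,
    sex_chroms=DEFAULT_SEX_CHROMS,
) -> list[CnvCall]:
    """Turn segments deviating from the diploid baseline into CNV calls.

    A segment with ``|mean_rd - 2| > call_threshold`` becomes a candidate;
    its significance is the two-sided one-sample t-test p-value of the
    per-window rd against the genome mean rd, its copy number is the segment
    mean rd (already on the diploid scale) and its q0 is the read-weighted
    zero-MAPQ fraction over the interval.  One-window segments cannot carry
    a t-test and are emitted with ``e_val = 1`` and a flag.
    """
    ws = norm.layout.window_size
    genome_mean = norm.genome_mean(sex_chroms)
    calls: list[CnvCall] = []
    for seg in segments:
        if abs(seg.mean_rd - 2.0) <= call_threshold:
            continue
        i0, i1 = seg.start // ws, seg.end // ws
        rd_win = norm.rd[seg.chrom][i0:i1]
        flags: list[str] = []
        if seg.chrom in sex_chroms:
            flags.append("sex_chrom")
        if seg.n_windows < 2:
            e_val = 1.0
            flags.append("single_window")
        else:
            sd = rd_win.std(ddof=1)
            if sd == 0.0:
                e_val = 0.0 if rd_win[0] != genome_mean else 1.0
            else:
                e_val = float(stats.ttest_1samp(rd_win, genome_mean).pvalue)
        counts = depth.counts[seg.chrom][i0:i1]
        total = counts.sum()
        if total > 0:
            q0 = float(
                (depth.q0_fraction[seg.chrom][i0:i1] * counts).sum() / total
            )
        else:
            q0 = 0.0  # no reads at all (homozygous deletion): q0 is moot
        cn = max(seg.mean_rd, 0.0)
        calls.append(
            CnvCall(
                norm.individual_id,
                seg.chrom,
                seg.start,
                seg.end,
                "deletion" if cn < 2.0 else "duplication",
                cn,
                min(max(e_val, 0.0), 1.0),
                min(max(q0, 0.0), 1.0),
                tuple(flags),
            )
        )
    return calls


def filter_calls(
    calls: list[CnvCall],
    max_pval: float = 0.01,
    min_size: int = 1000,
    max_q0: float = 0.5,
) -> list[CnvCall]:
    """Keep calls with p < 0.01, size strictly > 1 kb and q0 < 0.5.

    The size bound is strict: a 1000 bp call is removed.  Order preserved;
    pure predicate (idempotent).
    """
    return [
        c
        for c in calls
        if c.e_val < max_pval and c.size > min_size and c.q0 < max_q0
    ]


def call_cnvs(
    depth: DepthProfile,
    call_threshold: float = 0.5,
    max_pval: float = 0.01,
    min_size: int = 1000,
    max_q0: float = 0.5,
    trimmed: bool = True,
    gc_correct: bool = False,
    bandwidths: tuple[float, ...] = (2, 4, 8, 16),
    t: float = 3.5,
    merge_eps: float = 0.3,
    sex_chroms=DEFAULT_SEX_CHROMS,
) -> list[CnvCall]:
    """Full per-individual chain: normalize → segment → call → filter."""
    norm = normalize(depth, trimmed=trimmed, gc_correct=gc_correct, sex_chroms=sex_chroms)
    segs = segment(norm, bandwidths=bandwidths, t=t, merge_eps=merge_eps)
    calls = call_from_segments(segs, norm, depth, call_threshold, sex_chroms)
    return filter_calls(calls, max_pval, min_size, max_q0)


# ---------------------------------------------------------------------------
# IO

_CALL_COLS = ["chrom", "start", "end", "individual", "type", "cn", "e_val", "q0"]


def write_calls(calls: list[CnvCall], path) -> None:
    """Write calls as BED-like TSV (0-based half-open)."""
    rows = [
        (c.chrom, c.start, c.end, c.individual_id, c.call_type,
         f"{c.cn:.6g}", f"{c.e_val:.6g}", f"{c.q0:.6g}")
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CALL_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_calls(path) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t", names=_CALL_COLS, dtype={"chrom": str})
    return [
        CnvCall(
            r.individual, r.chrom, int(r.start), int(r.end), r.type,
            float(r.cn), float(r.e_val), float(r.q0),
        )
        for r in df.itertuples()
    ]
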