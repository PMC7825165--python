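"""Synthetic cohort generator: genome layouts, planted CNV truth sets, depth tracks.

Emulates what the downstream read-depth caller assumes about resequencing
coverage: per-window counts with negative-binomial (or Poisson) noise whose
mean scales linearly with local copy number, a per-window fraction of
zero-mapping-quality reads, and a two-group cohort carrying both shared and
group-differentiated CNV loci.  It does not simulate reads, alignments, GC
waves (unless the optional bias knob is turned on) or SNP genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomeLayout",
    "PopulationDesign",
    "TruthCnv",
    "DepthProfile",
    "make_layout",
    "plant_truth",
    "simulate_depth",
    "simulate_cohort",
    "write_depth_tracks",
    "read_depth_tracks",
    "write_truth",
    "read_truth",
    "design_from_config",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes cut into fixed, non-overlapping windows.

    A trailing partial window (``length % window_size``) is dropped: every
    analysed window has exactly ``window_size`` bases.
    """

    chromosomes: tuple[tuple[str, int], ...]
    window_size: int = 100

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError(f"window_size must be positive, got {self.window_size}")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromosome names in {names}")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if length < self.window_size:
                raise ValueError(
                    f"chromosome {name!r} ({length} bp) is shorter than one "
                    f"window ({self.window_size} bp)"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def n_windows(self, chrom: str) -> int:
        """Whole windows on ``chrom`` (final partial window dropped)."""
        return self.length(chrom) // self.window_size

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(name) for name in self.names)


def make_layout(chrom_spec, window_size: int = 100) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from ``[(name, length), ...]``."""
    return GenomeLayout(tuple((str(n), int(l)) for n, l in chrom_spec), int(window_size))


@dataclass(frozen=True)
class PopulationDesign:
    """Cohort composition and noise/CNV parameters of a simulated study.

    Parameters
    ----------
    individuals
        ``(id, group)`` pairs; every individual belongs to exactly one group.
    n_shared_cnvs, n_group_specific_cnvs
        Numbers of CNV loci segregating in all groups versus loci whose
        carrier frequency differs between groups.
    cnv_length_range
        Inclusive bp range CNV lengths are drawn from (then snapped to whole
        windows).  Default (1200, 8000) emulates the >1 kb size class that
        survives standard read-depth filtering, with a mean near the ~4.3 kb
        average reported for resequencing CNV calls in sheep.
    duplication_fraction
        Probability a locus is a duplication rather than a deletion.
    mean_depth
        Expected reads per window at diploid copy number.
    overdispersion
        Negative-binomial overdispersion alpha with ``var = mu + alpha*mu^2``;
        0 gives Poisson counts.
    q0_baseline
        Mean per-window fraction of zero-mapping-quality reads.
    shared_frequency
        Carrier probability of a shared locus (every group is guaranteed at
        least one carrier).
    diff_freq_high, diff_freq_low
        Carrier frequencies of a differentiated locus in its high- and
        low-frequency group.
    deletion_cn_choices, duplication_cn_choices
        Menus the true copy number of a locus is drawn from.
    seed
        Mandatory; fixes truth sets and depth tracks bit-for-bit.
    """

    individuals: tuple[tuple[str, str], ...]
    seed: int
    n_shared_cnvs: int = 10
    n_group_specific_cnvs: int = 2
    cnv_length_range: tuple[int, int] = (1200, 8000)
    duplication_fraction: float = 0.3
    mean_depth: float = 30.0
    overdispersion: float = 0.02
    q0_baseline: float = 0.05
    shared_frequency: float = 0.6
    diff_freq_high: float = 0.9
    diff_freq_low: float = 0.1
    deletion_cn_choices: tuple[int, ...] = (0, 1)
    duplication_cn_choices: tuple[int, ...] = (3, 4)

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        for p, name in [
            (self.duplication_fraction, "duplication_fraction"),
            (self.q0_baseline, "q0_baseline"),
            (self.shared_frequency, "shared_frequency"),
            (self.diff_freq_high, "diff_freq_high"),
            (self.diff_freq_low, "diff_freq_low"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_shared_cnvs < 0 or self.n_group_specific_cnvs < 0:
            raise ValueError("CNV counts must be non-negative")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, g in self.individuals:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.individuals)

    def group_of(self, individual_id: str) -> str:
        for i, g in self.individuals:
            if i == individual_id:
                return g
        raise KeyError(individual_id)

    def validate_against(self, layout: GenomeLayout) -> None:
        lo, hi = self.cnv_length_range
        if lo > hi:
            raise ValueError("cnv_length_range min > max")
        if lo < 2 * layout.window_size:
            raise ValueError(
                f"cnv_length_range minimum {lo} must be >= 2 windows "
                f"({2 * layout.window_size} bp)"
            )


@dataclass(frozen=True)
class TruthCnv:
    """Ground-truth CNV of one individual (0-based, half-open)."""

    individual_id: str
    chrom: str
    start: int
    end: int
    true_cn: float
    differentiated: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")
        if self.true_cn < 0:
            raise ValueError(f"true_cn must be non-negative: {self}")


@dataclass
class DepthProfile:
    """Per-window read counts and zero-MAPQ fractions for one individual."""

    individual_id: str
    layout: GenomeLayout
    counts: dict[str, np.ndarray]
    q0_fraction: dict[str, np.ndarray]
    gc: dict[str, np.ndarray] | None = None  # per-window GC content, optional

    def __post_init__(self) -> None:
        for chrom in self.layout.names:
            n = self.layout.n_windows(chrom)
            if len(self.counts[chrom]) != n or len(self.q0_fraction[chrom]) != n:
                raise ValueError(f"track length mismatch on {chrom}")
            if (self.counts[chrom] < 0).any():
                raise ValueError(f"negative counts on {chrom}")
            q0 = self.q0_fraction[chrom]
            if ((q0 < 0) | (q0 > 1)).any():
                raise ValueError(f"q0 fraction outside [0, 1] on {chrom}")

    @property
    def total_windows(self) -> int:
        return self.layout.total_windows


# ---------------------------------------------------------------------------
# truth planting


def _snap_length(length: int, window_size: int) -> int:
    """Round a bp length to the nearest whole number of windows (>= 2)."""
    n_win = max(2, round(length / window_size))
    return n_win * window_size


def plant_truth(layout: GenomeLayout, design: PopulationDesign) -> list[TruthCnv]:
    """Plant shared and group-differentiated CNV loci and assign carriers.

    Loci are disjoint genome-wide and snapped to window boundaries, so truth
    intervals never overlap within an individual and the caller's one-window
    resolution can recover boundaries exactly.  Shared loci receive at least
    one carrier in every group; differentiated loci carry at
    ``diff_freq_high`` in one group and ``diff_freq_low`` in the others.
    """
    design.validate_against(layout)
    rng = np.random.default_rng([design.seed, 0])
    ws = layout.window_size
    n_loci = design.n_shared_cnvs + design.n_group_specific_cnvs
    if n_loci == 0:
        return []
    if not design.individuals:
        raise ValueError("design has no individuals")

    chrom_names = list(layout.names)
    chrom_wins = np.array([layout.n_windows(c) for c in chrom_names], dtype=float)
    chrom_p = chrom_wins / chrom_wins.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    lo, hi = design.cnv_length_range
    loci: list[tuple[str, int, int]] = []
    for _ in range(n_loci):
        placed = False
        for _attempt in range(2000):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
            length = _snap_length(int(rng.integers(lo, hi + 1)), ws)
            n_win = length // ws
            max_start_win = layout.n_windows(chrom) - n_win
            if max_start_win < 0:
                continue
            start = int(rng.integers(0, max_start_win + 1)) * ws
            end = start + length
            # keep one window of clearance so adjacent loci stay separable
            if all(end + ws <= s or start >= e + ws for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                loci.append((chrom, start, end))
                placed = True
                break
        if not placed:
            raise ValueError(
                "genome too small to host the requested CNV loci without overlap"
            )

    groups = design.groups
    by_group: dict[str, list[str]] = {g: [] for g in groups}
    for ind, g in design.individuals:
        by_group[g].append(ind)

    truth: list[TruthCnv] = []
    for i, (chrom, start, end) in enumerate(loci):
        is_dup = rng.random() < design.duplication_fraction
        menu = design.duplication_cn_choices if is_dup else design.deletion_cn_choices
        cn = float(menu[rng.integers(0, len(menu))])
        differentiated = i >= design.n_shared_cnvs
        carriers: list[str] = []
        if differentiated:
            high_group = groups[int(rng.integers(0, len(groups)))]
            for ind, g in design.individuals:
                p = design.diff_freq_high if g == high_group else design.diff_freq_low
                if rng.random() < p:
                    carriers.append(ind)
        else:
            for ind, _g in design.individuals:
                if rng.random() < design.shared_frequency:
                    carriers.append(ind)
            carrier_set = set(carriers)
            for g in groups:  # every group must witness a shared locus
                members = by_group[g]
                if members and not carrier_set & set(members):
                    pick = members[int(rng.integers(0, len(members)))]
                    carriers.append(pick)
        for ind in carriers:
            truth.append(TruthCnv(ind, chrom, start, end, cn, differentiated))
    return truth


# ---------------------------------------------------------------------------
# depth simulation


def _copy_number_track(
    layout: GenomeLayout, truth: list[TruthCnv], individual_id: str
) -> dict[str, np.ndarray]:
    ws = layout.window_size
    cn = {c: np.full(layout.n_windows(c), 2.0) for c in layout.names}
    for t in truth:
        if t.individual_id != individual_id:
            continue
        cn[t.chrom][t.start // ws : t.end // ws] = t.true_cn
    return cn


def simulate_depth(
    layout: GenomeLayout,
    truth: list[TruthCnv],
    individual_id: str,
    design: PopulationDesign,
    q0_inflate: list[tuple[str, int, int, float]] | None = None,
    gc_bias: tuple[float, int] | None = None,
) -> DepthProfile:
    """Draw one individual's windowed depth and q0 tracks.

    Counts are negative-binomial with mean ``mean_depth * cn / 2`` and
    variance ``mu + overdispersion * mu^2`` (Poisson when overdispersion is
    0).  q0 fractions are Beta-distributed around ``q0_baseline``;
    ``q0_inflate`` entries ``(chrom, start, end, level)`` raise the q0 mean
    inside designated regions to exercise the q0 filter downstream.
    ``gc_bias = (amplitude, period_windows)`` superimposes a sinusoidal
    coverage wave tied to a synthetic GC track, purely to exercise the
    caller's GC-bin median normalization; GC is flat by default.
    """
    if individual_id not in design.ids:
        raise KeyError(f"unknown individual {individual_id!r}")
    idx = design.ids.index(individual_id)
    rng = np.random.default_rng([design.seed, 1 + idx])
    ws = layout.window_size
    cn = _copy_number_track(layout, truth, individual_id)

    counts: dict[str, np.ndarray] = {}
    q0: dict[str, np.ndarray] = {}
    gc_tracks: dict[str, np.ndarray] | None = {} if gc_bias else None
    alpha = design.overdispersion
    for chrom in layout.names:
        mu = design.mean_depth * cn[chrom] / 2.0
        if gc_bias is not None:
            amplitude, period = gc_bias
            phase = 2.0 * np.pi * np.arange(len(mu)) / period
            gc_tracks[chrom] = 0.5 + 0.2 * np.sin(phase)
            mu = mu * (1.0 + amplitude * np.sin(phase))
        if alpha <= 0:
            c = rng.poisson(mu)
        else:
            k = 1.0 / alpha  # NB size; p = k / (k + mu)
            p = k / (k + mu)
            c = rng.negative_binomial(k, p)
        counts[chrom] = c.astype(np.int64)

        level = np.full(len(mu), design.q0_baseline)
        if q0_inflate:
            for qc, qs, qe, qv in q0_inflate:
                if qc == chrom:
                    level[qs // ws : qe // ws] = qv
        q = np.zeros_like(level)
        pos = level > 0
        conc = 50.0
        if pos.any():
            a = np.clip(level[pos] * conc, 1e-6, None)
            b = np.clip((1.0 - level[pos]) * conc, 1e-6, None)
            q[pos] = rng.beta(a, b)
        q0[chrom] = np.clip(q, 0.0, 1.0)

    return DepthProfile(individual_id, layout, counts, q0, gc_tracks)


def simulate_cohort(
    layout: GenomeLayout, design: PopulationDesign
) -> tuple[list[TruthCnv], dict[str, DepthProfile]]:
    """Plant truth and simulate every individual's depth profile."""
    truth = plant_truth(layout, design)
    profiles = {
        ind: simulate_depth(layout, truth, ind, design) for ind in design.ids
    }
    return truth, profiles


# ---------------------------------------------------------------------------
# text IO: bedGraph-like depth tracks, BED-like truth, YAML design config


def write_depth_tracks(profile: DepthProfile, counts_path, q0_path) -> None:
    """Write 4-column bedGraph-like count and q0 tracks (0-based half-open)."""
    ws = profile.layout.window_size
    for path, tracks, fmt in [
        (counts_path, profile.counts, "{}"),
        (q0_path, profile.q0_fraction, "{:.6g}"),
    ]:
        with open(path, "w") as fh:
            for chrom in profile.layout.names:
                vals = tracks[chrom]
                for i, v in enumerate(vals):
                    fh.write(
                        f"{chrom}\t{i * ws}\t{(i + 1) * ws}\t{fmt.format(v)}\n"
                    )


def read_depth_tracks(
    counts_path, q0_path, individual_id: str, layout: GenomeLayout | None = None
) -> DepthProfile:
    """Read bedGraph-like count + q0 tracks; infer the layout if not given."""
    cols = ["chrom", "start", "end", "value"]
    cdf = pd.read_csv(counts_path, sep="\t", names=cols, dtype={"chrom": str})
    qdf = pd.read_csv(q0_path, sep="\t", names=cols, dtype={"chrom": str})
    if layout is None:
        ws = int(cdf["end"].iloc[0] - cdf["start"].iloc[0])
        chroms = [
            (chrom, int(g["end"].max()))
            for chrom, g in cdf.groupby("chrom", sort=False)
        ]
        layout = GenomeLayout(tuple(chroms), ws)
    counts = {
        chrom: g.sort_values("start")["value"].to_numpy(dtype=np.int64)
        for chrom, g in cdf.groupby("chrom", sort=False)
    }
    q0 = {
        chrom: g.sort_values("start")["value"].to_numpy(dtype=float)
        for chrom, g in qdf.groupby("chrom", sort=False)
    }
    return DepthProfile(individual_id, layout, counts, q0)


_TRUTH_COLS = ["chrom", "start", "end", "individual", "true_cn", "differentiated"]


def write_truth(truth: list[TruthCnv], path) -> None:
    rows = [
        (t.chrom, t.start, t.end, t.individual_id, t.true_cn, int(t.differentiated))
        for t in truth
    ]
    pd.DataFrame(rows, columns=_TRUTH_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_truth(path) -> list[TruthCnv]:
    df = pd.read_csv(path, sep="\t", names=_TRUTH_COLS, dtype={"chrom": str})
    return [
        TruthCnv(
            r.individual, r.chrom, int(r.start), int(r.end), float(r.true_cn),
            bool(r.differentiated),
        )
        for r in df.itertuples()
    ]


def design_from_config(path) -> tuple[GenomeLayout, PopulationDesign]:
    """Load a layout + design from a YAML config; ``seed`` is mandatory."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ValueError("simulation config must set an explicit seed")
    layout = make_layout(cfg.pop("chromosomes"), cfg.pop("window_size", 100))
    cfg["individuals"] = tuple((str(i), str(g)) for i, g in cfg["individuals"])
    for key in ("cnv_length_range", "deletion_cn_choices", "duplication_cn_choices"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    known = set(PopulationDesign.__dataclass_fields__)
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return layout, PopulationDesign(**cfg)
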