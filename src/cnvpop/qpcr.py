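"""qPCR copy-number estimation (2 x 2^-ddCt) and concordance scoring.

Relative quantification differences the target-vs-reference-gene Ct between
a test sample and a diploid calibrator sample:

    dCt_test = Ct(target, test) - Ct(reference gene, test)
    dCt_cal  = Ct(target, calibrator) - Ct(reference gene, calibrator)
    ddCt     = dCt_test - dCt_cal
    CN       = 2 * 2^(-ddCt)

Triplicate Ct values are averaged on the Ct scale before differencing.
Concordance maps the qPCR CN to the same deleted/conserved/duplicated state
bounds used for CNVR classification and scores each target as confirmed when
the qPCR state agrees with the predicted region type in a majority of
assayed samples (strict and lenient variants available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cnvpop.cnvr import DELETED_BELOW, DUPLICATED_ABOVE

__all__ = [
    "QpcrMeasurement",
    "CopyNumberEstimate",
    "ConcordanceReport",
    "cn_from_ddct",
    "copy_number_from_ddct",
    "qpcr_state",
    "concordance",
    "read_ct_table",
    "build_measurements",
]


def _mean_ct(values) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.isnan(arr).any():
        raise ValueError("missing Ct values")
    if (arr <= 0).any():
        raise ValueError(f"Ct values must be positive, got {arr}")
    return float(arr.mean())


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for one (sample, target) against a calibrator."""

    sample_id: str
    target_id: str
    ct_target_test: tuple[float, ...]
    ct_reference_test: tuple[float, ...]
    ct_target_calibrator: tuple[float, ...]
    ct_reference_calibrator: tuple[float, ...]


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    target_id: str
    dct_test: float
    dct_calibrator: float
    ddct: float
    cn: float
    flags: tuple[str, ...] = ()


def cn_from_ddct(ddct: float) -> float:
    """CN = 2 * 2^(-ddCt); 0 -> 2 copies, 1 -> 1, -1 -> 4."""
    return 2.0 * 2.0 ** (-ddct)


def copy_number_from_ddct(
    m: QpcrMeasurement, max_replicate_sd: float | None = None
) -> CopyNumberEstimate:
    """Collapse triplicates to means, difference, and convert to copy number.

    A replicate standard deviation above ``max_replicate_sd`` (when set)
    flags the estimate rather than rejecting it.
    """
    flags: list[str] = []
    if max_replicate_sd is not None:
        for name, reps in [
            ("target_test", m.ct_target_test),
            ("reference_test", m.ct_reference_test),
            ("target_calibrator", m.ct_target_calibrator),
            ("reference_calibrator", m.ct_reference_calibrator),
        ]:
            arr = np.asarray(reps, dtype=float)
            if arr.size > 1 and arr.std(ddof=1) > max_replicate_sd:
                flags.append(f"high_sd:{name}")
    dct_test = _mean_ct(m.ct_target_test) - _mean_ct(m.ct_reference_test)
    dct_cal = _mean_ct(m.ct_target_calibrator) - _mean_ct(m.ct_reference_calibrator)
    ddct = dct_test - dct_cal
    return CopyNumberEstimate(
        m.sample_id, m.target_id, dct_test, dct_cal, ddct, cn_from_ddct(ddct),
        tuple(flags),
    )


def qpcr_state(
    cn: float,
    deleted_below: float = DELETED_BELOW,
    duplicated_above: float = DUPLICATED_ABOVE,
) -> str:
    if cn < deleted_below:
        return "deleted"
    if cn <= duplicated_above:
        return "conserved"
    return "duplicated"


def _agrees(predicted: str, cn: float, mode: str) -> bool:
    state = qpcr_state(cn)
    if predicted in ("deletion", "deleted"):
        if mode == "lenient":
            # tolerate heterozygous deletions: any CN below the conserved
            # upper bound supports a deletion prediction
            return cn < DUPLICATED_ABOVE
        return state == "deleted"
    if predicted in ("duplication", "duplicated"):
        return state == "duplicated"
    if predicted == "both":
        return state in ("deleted", "duplicated")
    return state == "conserved"


@dataclass(frozen=True)
class ConcordanceReport:
    table: pd.DataFrame  # per-target: n_samples, n_agreeing, confirmed
    n_confirmed: int
    n_total: int
    rate: float | None  # None when no targets could be scored
    unmatched: tuple[tuple[str, str], ...]
    mode: str


def concordance(
    predicted: list[tuple[str, str, str]],
    qpcr: list[tuple[str, str, float]],
    mode: str = "majority",
) -> ConcordanceReport:
    """Score predicted CNVR states against qPCR copy numbers per target.

    ``predicted`` holds ``(target_id, sample_id, state)`` and ``qpcr``
    holds ``(target_id, sample_id, cn)``.  A target is confirmed when the
    qPCR-derived state agrees with the prediction in a strict majority of
    its matched samples (``mode="majority"``), in every sample
    (``mode="strict"``), or under the heterozygous-deletion-tolerant rule
    (``mode="lenient"``, majority).  Pairs present on only one side are
    listed as unmatched and excluded.
    """
    if mode not in ("majority", "strict", "lenient"):
        raise ValueError(f"unknown concordance mode {mode!r}")
    pred_map = {(t, s): state for t, s, state in predicted}
    qpcr_map = {(t, s): cn for t, s, cn in qpcr}
    matched = sorted(set(pred_map) & set(qpcr_map))
    unmatched = tuple(sorted(set(pred_map) ^ set(qpcr_map)))

    per_target: dict[str, list[bool]] = {}
    for t, s in matched:
        per_target.setdefault(t, []).append(
            _agrees(pred_map[(t, s)], qpcr_map[(t, s)], mode)
        )
    rows = []
    n_confirmed = 0
    for t in sorted(per_target):
        agree = per_target[t]
        if mode == "strict":
            confirmed = all(agree)
        else:
            confirmed = sum(agree) > len(agree) / 2
        n_confirmed += confirmed
        rows.append((t, len(agree), sum(agree), confirmed))
    table = pd.DataFrame(rows, columns=["target", "n_samples", "n_agreeing", "confirmed"])
    n_total = len(per_target)
    rate = n_confirmed / n_total if n_total else None
    return ConcordanceReport(table, n_confirmed, n_total, rate, unmatched, mode)


# ---------------------------------------------------------------------------
# IO: long-format Ct table -> measurements


def read_ct_table(path) -> pd.DataFrame:
    """Read a TSV with columns sample, target, role, replicate, ct.

    ``role`` is ``target`` (the assayed CNVR amplicon) or ``reference``
    (the single-copy reference gene, e.g. DGAT2).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "target", "role", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = set(df["role"]) - {"target", "reference"}
    if bad:
        raise ValueError(f"unknown roles in Ct table: {sorted(bad)}")
    return df


def build_measurements(
    df: pd.DataFrame, calibrator_sample: str
) -> list[QpcrMeasurement]:
    """Assemble per-(sample, target) measurements against a calibrator sample."""
    samples = set(df["sample"])
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in Ct table")

    def reps(sample, target, role) -> tuple[float, ...]:
        sel = df[
            (df["sample"] == sample) & (df["target"] == target) & (df["role"] == role)
        ]["ct"]
        if sel.empty:
            raise ValueError(
                f"missing Ct values for sample={sample!r} target={target!r} role={role!r}"
            )
        return tuple(float(v) for v in sel)

    out: list[QpcrMeasurement] = []
    targets = sorted(set(df.loc[df["role"] == "target", "target"]))
    for sample in sorted(samples - {calibrator_sample}):
        for target in targets:
            has = not df[
                (df["sample"] == sample)
                & (df["target"] == target)
                & (df["role"] == "target")
            ].empty
            if not has:
                continue
            out.append(
                QpcrMeasurement(
                    sample_id=sample,
                    target_id=target,
                    ct_target_test=reps(sample, target, "target"),
                    ct_reference_test=reps(sample, target, "reference"),
                    ct_target_calibrator=reps(calibrator_sample, target, "target"),
                    ct_reference_calibrator=reps(calibrator_sample, target, "reference"),
                )
            )
    return out
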