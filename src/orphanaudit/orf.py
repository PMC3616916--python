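"""Sequence-quality metrics for single-pass transcript reads.

The quality audit asks whether unannotated reads are simply worse reads.
Per read it measures the longest open reading frame (a maximal stop-free
in-frame interval, reported together with whether an in-frame ATG occurs
inside it), read length, and GC content, and compares groups of reads with
Welch's unequal-variance t-test.

ORFs are defined stop-to-stop rather than ATG-to-stop because a missing
start codon is a separate quality signal: a read can carry a long coding
interval whose 5' end (and start codon) was not sequenced. By default only
the three forward frames are searched, matching directionally cloned,
5'-sequenced cDNA libraries; pass ``frames=SIX_FRAMES`` for both strands.

Coordinates are 0-based half-open on the read throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConsistencyError,
    DegenerateInputError,
    StatisticsError,
    UndefinedValueError,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
FORWARD_FRAMES = (1, 2, 3)
SIX_FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ESTRecord:
    """A transcript read: identifier, nucleotide sequence, optional library label."""

    id: str
    sequence: str
    source_label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DegenerateInputError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise DegenerateInputError(
                f"{self.id}: sequence contains non-ACGTN symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class OrfCall:
    """Longest stop-free in-frame interval found on a read.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    read (forward strand), ``end - start`` is a multiple of 3, and the
    interval contains no in-frame stop codon. ``has_start_codon`` is true
    iff an in-frame ATG occurs within the interval.
    """

    est_id: str
    frame: int
    start: int
    end: int
    orf_length_nt: int
    has_start_codon: bool


def _scan_frame(seq: str, offset: int) -> tuple[int, int]:
    """Longest stop-free codon run in one frame; earliest run wins ties.

    Returns 0-based half-open coordinates on ``seq`` trimmed to whole codons.
    A codon containing N is treated as neither stop nor start.
    """
    n = len(seq)
    best_start, best_end = offset, offset
    run_start = offset
    i = offset
    while i + 3 <= n:
        if seq[i : i + 3] in STOP_CODONS:
            if i - run_start > best_end - best_start:
                best_start, best_end = run_start, i
            run_start = i + 3
        i += 3
    if i - run_start > best_end - best_start:
        best_start, best_end = run_start, i
    return best_start, best_end


def _has_inframe_start(sub: str) -> bool:
    return any(sub[i : i + 3] == START_CODON for i in range(0, len(sub) - 2, 3))


def find_orf(record: ESTRecord, frames: Sequence[int] = FORWARD_FRAMES) -> OrfCall:
    """Longest maximal stop-free in-frame interval across the requested frames.

    Ties are broken by the order of ``frames`` (lower frame number first by
    default) and then by smaller start within a frame. For negative frames
    the scan runs on the reverse complement; reported coordinates are mapped
    back onto the forward read.
    """
    seq = record.sequence.upper()
    if len(seq) < 3:
        raise DegenerateInputError(
            f"{record.id}: sequence shorter than 3 nt ({len(seq)} nt)"
        )
    length = len(seq)
    rc = seq.translate(_COMPLEMENT)[::-1] if any(f < 0 for f in frames) else ""
    best: OrfCall | None = None
    for frame in frames:
        if frame > 0:
            s, e = _scan_frame(seq, frame - 1)
            sub = seq[s:e]
            start, end = s, e
        else:
            s, e = _scan_frame(rc, -frame - 1)
            sub = rc[s:e]
            start, end = length - e, length - s
        if best is None or (e - s if frame < 0 else end - start) > best.orf_length_nt:
            best = OrfCall(
                est_id=record.id,
                frame=frame,
                start=start,
                end=end,
                orf_length_nt=end - start,
                has_start_codon=_has_inframe_start(sub),
            )
    assert best is not None
    return best


def gc_content(record: ESTRecord) -> float:
    """GC percentage, 100*(G+C)/(A+C+G+T); N is excluded from the denominator."""
    seq = record.sequence.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise UndefinedValueError(f"{record.id}: GC content undefined (all-N sequence)")
    return 100.0 * gc / denom


def est_metrics(
    records: Iterable[ESTRecord], frames: Sequence[int] = FORWARD_FRAMES
) -> pd.DataFrame:
    """Per-read metric table: length, ORF call, GC percent."""
    rows = []
    for rec in records:
        orf = find_orf(rec, frames)
        rows.append(
            {
                "est_id": rec.id,
                "length_nt": len(rec.sequence),
                "orf_length_nt": orf.orf_length_nt,
                "frame": orf.frame,
                "has_start_codon": orf.has_start_codon,
                "gc_percent": gc_content(rec),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QualitySummary:
    group: str
    n: int
    mean_orf_length_nt: float
    mean_length_nt: float
    n_without_start: int
    mean_gc_percent: float


def summarize_metrics(
    metrics: pd.DataFrame, partition: Mapping[str, str]
) -> dict[str, QualitySummary]:
    """Group summaries from a per-read metric table (see :func:`est_metrics`)."""
    missing = sorted(set(metrics["est_id"]) - set(partition))
    if missing:
        raise ConsistencyError(
            f"{len(missing)} est ids missing from partition: {missing[:10]}"
        )
    labels = metrics["est_id"].map(partition)
    out: dict[str, QualitySummary] = {}
    for group, sub in metrics.groupby(labels, sort=True):
        out[str(group)] = QualitySummary(
            group=str(group),
            n=len(sub),
            mean_orf_length_nt=float(sub["orf_length_nt"].mean()),
            mean_length_nt=float(sub["length_nt"].mean()),
            n_without_start=int((~sub["has_start_codon"]).sum()),
            mean_gc_percent=float(sub["gc_percent"].mean()),
        )
    return out


def summarize_quality(
    records: Iterable[ESTRecord],
    partition: Mapping[str, str],
    frames: Sequence[int] = FORWARD_FRAMES,
) -> dict[str, QualitySummary]:
    """Compute per-read metrics and summarize them by partition label."""
    return summarize_metrics(est_metrics(records, frames), partition)


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("welch_t requires at least 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if math.isclose(a.mean(), b.mean()):
            # degenerate but well-defined: identical constant groups
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0,
                               float(a.mean()), float(b.mean()))
        raise StatisticsError("welch_t undefined: both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )
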