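"""Assembly-quality audit: redundancy accounting and the single-copy failure rate.

Two questions about an EST assembly are answered here. First, bookkeeping:
how many input reads collapsed into how many unique sequences (gene
discovery rate), and what the contig-size spectrum looks like. Second, the
under-assembly estimate: gene families that are single-copy in every
reference species should appear once in the focal assembly; when such a
family is represented by several focal sequences, those extra sequences are
taken to be fragments of one gene that failed to assemble. The failure rate
is the product of two proportions,

    failure_rate = (multi-copy families / families matched)
                 x (multi-copy families / sequences inside multi-copy families),

i.e. the fraction of families affected times the fraction of the inflated
sequences that correspond to real genes; applied to the unique-sequence
total it yields an adjusted (deflated) unique-gene count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, DegenerateInputError, StatisticsError

SINGLETON_LABEL = "SINGLETON"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class AssemblyComposition:
    """Read-to-contig composition: contig member counts plus singleton reads."""

    n_input_reads: int
    contigs: tuple[tuple[str, int], ...]
    n_singletons: int

    def __post_init__(self) -> None:
        for cid, k in self.contigs:
            if k < 2:
                raise ConsistencyError(f"contig {cid} has {k} members (< 2)")
        total = self.n_singletons + sum(k for _, k in self.contigs)
        if total != self.n_input_reads:
            raise ConsistencyError(
                f"composition does not balance: {self.n_singletons} singletons + "
                f"{sum(k for _, k in self.contigs)} contig members != "
                f"{self.n_input_reads} input reads"
            )

    @property
    def n_unique(self) -> int:
        return self.n_singletons + len(self.contigs)

    @classmethod
    def from_membership(cls, membership: pd.DataFrame) -> "AssemblyComposition":
        """Build from a (read_id, contig_id) table; ``SINGLETON`` marks unassembled reads."""
        counts = Counter(membership["contig_id"])
        n_singletons = counts.pop(SINGLETON_LABEL, 0)
        contigs = tuple(sorted((cid, k) for cid, k in counts.items()))
        return cls(
            n_input_reads=len(membership),
            contigs=contigs,
            n_singletons=n_singletons,
        )


def discovery_rate(n_input_reads: int, n_unique: int) -> float:
    """Unique sequences per input read (gene discovery rate)."""
    if n_input_reads <= 0:
        raise DegenerateInputError("n_input_reads must be positive")
    if not 0 < n_unique <= n_input_reads:
        raise DegenerateInputError(
            f"n_unique must be in (0, n_input_reads]; got {n_unique}/{n_input_reads}"
        )
    return n_unique / n_input_reads


@dataclass(frozen=True)
class ContigSpectrum:
    histogram: dict[int, int]
    frac_2_3: float


def contig_spectrum(assembly: AssemblyComposition) -> ContigSpectrum:
    """Histogram of contig member counts and the fraction with 2-3 members."""
    hist = Counter(k for _, k in assembly.contigs)
    total = sum(hist.values())
    frac = (hist.get(2, 0) + hist.get(3, 0)) / total if total else 0.0
    return ContigSpectrum(histogram=dict(sorted(hist.items())), frac_2_3=frac)


@dataclass(frozen=True)
class FailureEstimate:
    """Under-assembly estimate from a conserved single-copy copy-number table."""

    n_families_matched: int
    n_multicopy_families: int
    n_sequences_in_multicopy_families: int
    p_multicopy: float
    p_true_singletons: float
    failure_rate: float
    n_discounted: int | None = None
    adjusted_unique: int | None = None

    def with_adjustment(self, n_unique: int) -> "FailureEstimate":
        if n_unique <= 0:
            raise DegenerateInputError("n_unique must be positive")
        discounted = _round_half_away(n_unique * self.failure_rate)
        return replace(self, n_discounted=discounted, adjusted_unique=n_unique - discounted)


def failure_rate(table: pd.DataFrame) -> FailureEstimate:
    """Assembly-failure rate from a (family_id, n_focal_sequences) table.

    The table must be restricted to families single-copy in all reference
    species and matched by the focal assembly, with positive integer counts.
    """
    if table is None or len(table) == 0:
        raise StatisticsError("copy-number table is empty")
    counts = table["n_focal_sequences"].astype(int)
    if (counts < 1).any():
        raise ConsistencyError("copy counts must be positive integers")
    n_matched = len(table)
    multi = counts > 1
    n_multi = int(multi.sum())
    n_seq_multi = int(counts[multi].sum())
    p_multi = n_multi / n_matched
    p_true = n_multi / n_seq_multi if n_seq_multi else 0.0
    return FailureEstimate(
        n_families_matched=n_matched,
        n_multicopy_families=n_multi,
        n_sequences_in_multicopy_families=n_seq_multi,
        p_multicopy=p_multi,
        p_true_singletons=p_true,
        failure_rate=p_multi * p_true,
    )


def adjust_unique_count(n_unique: int, estimate: FailureEstimate) -> int:
    """Unique-sequence count deflated by the assembly-failure rate.

    The discount is rounded half-away-from-zero before subtraction, so
    adjusted + discounted = original exactly.
    """
    return int(estimate.with_adjustment(n_unique).adjusted_unique)


def assign_families(
    hits: pd.DataFrame, family_map: Mapping[str, str]
) -> pd.DataFrame:
    """Copy-number table from filtered homology hits and a subject->family map.

    Each query is assigned the family of its best hit (lowest e-value, then
    highest bit score, then lexicographically smallest subject id); queries
    whose best hit's subject has no family mapping, or with no hit at all,
    are omitted. Family copy count = number of distinct queries assigned.
    """
    if len(hits) == 0:
        return pd.DataFrame(columns=["family_id", "n_focal_sequences"])
    best = (
        hits.sort_values(
            ["query_id", "e_value", "bit_score", "subject_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .drop_duplicates("query_id", keep="first")
        .copy()
    )
    best["family_id"] = best["subject_id"].map(family_map)
    best = best.dropna(subset=["family_id"])
    table = (
        best.groupby("family_id")["query_id"]
        .nunique()
        .rename("n_focal_sequences")
        .reset_index()
        .sort_values("family_id", ignore_index=True)
    )
    return table
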