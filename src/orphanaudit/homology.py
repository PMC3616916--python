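"""Homology filtering, annotation partitioning, and the reference-quality discount.

A transcript is "annotated" against a reference dataset when it has at least
one homology hit passing the standard thresholds (e-value <= 1e-5 AND
aligned length >= 33 residues, both boundaries inclusive). This module
filters raw tabular hit files, partitions an explicit query universe into
matched/unmatched per dataset (with marginals, pairwise contingencies, and
the cross-dataset union), and summarizes e-value and taxonomic spectra.

It also implements the reference-completeness correction: when a reference
dataset fails to match even the reference species' own transcripts at rate
(1 - p_intra), that share of the focal non-matches is attributed to
reference fragmentation/incompleteness rather than true non-homology and
is discarded from the denominator:

    discarded  = n_nomatch * (1 - p_intra)
    corrected  = n_match / (n_total - discarded)

The corrected fraction is always >= the raw fraction, with equality only
for a perfect reference (p_intra = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DegenerateInputError, ParseError

OUTFMT6_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "aligned_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]

E_VALUE_MAX = 1e-5
MIN_ALIGNED_LENGTH = 33


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def read_outfmt6(path, dataset_id: str | None = None) -> pd.DataFrame:
    """Read a 12-column tabular hit file; extra columns are tolerated and ignored."""
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise ParseError(f"{path}: cannot parse tabular hits: {exc}") from exc
    if raw.shape[1] < 12:
        raise ParseError(f"{path}: expected >= 12 tab-separated columns, got {raw.shape[1]}")
    df = raw.iloc[:, :12].copy()
    df.columns = OUTFMT6_COLUMNS
    for col in OUTFMT6_COLUMNS[2:]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = converted
    if dataset_id is not None:
        df["dataset_id"] = dataset_id
    return df


def filter_hits(
    hits: pd.DataFrame,
    e_max: float = E_VALUE_MAX,
    min_len: int = MIN_ALIGNED_LENGTH,
) -> pd.DataFrame:
    """Keep rows with e_value <= e_max and aligned_length >= min_len (inclusive)."""
    keep = (hits["e_value"] <= e_max) & (hits["aligned_length"] >= min_len)
    return hits.loc[keep].reset_index(drop=True)


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per query: lowest e-value, then highest bit score, then subject id."""
    return (
        hits.sort_values(
            ["query_id", "e_value", "bit_score", "subject_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .drop_duplicates("query_id", keep="first")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class PartitionTable:
    """Per-query matched flags per dataset, over an explicit query universe."""

    flags: pd.DataFrame  # bool, index = query_id, columns = dataset_id

    @property
    def n_queries(self) -> int:
        return len(self.flags)

    @property
    def datasets(self) -> list[str]:
        return list(self.flags.columns)

    def marginals(self) -> pd.DataFrame:
        n = self.n_queries
        rows = []
        for ds in self.datasets:
            m = int(self.flags[ds].sum())
            rows.append(
                {
                    "dataset_id": ds,
                    "n_match": m,
                    "n_nomatch": n - m,
                    "match_fraction": m / n if n else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def contingency(self, d1: str, d2: str) -> pd.DataFrame:
        a, b = self.flags[d1], self.flags[d2]
        table = pd.DataFrame(
            {
                "match": [int((a & b).sum()), int((~a & b).sum())],
                "no_match": [int((a & ~b).sum()), int((~a & ~b).sum())],
            },
            index=pd.Index(["match", "no_match"], name=d1),
        )
        table.columns.name = d2
        return table

    def pairwise_contingencies(self) -> dict[tuple[str, str], pd.DataFrame]:
        return {
            (d1, d2): self.contingency(d1, d2)
            for d1, d2 in combinations(self.datasets, 2)
        }

    def union_count(self) -> int:
        """Queries matched in at least one dataset; each query counted once."""
        return int(self.flags.any(axis=1).sum())


def partition(
    query_ids: Iterable[str],
    hits: pd.DataFrame | Mapping[str, pd.DataFrame],
) -> PartitionTable:
    """Matched/unmatched flags per dataset over the full query universe.

    ``hits`` is either a single filtered table with a ``dataset_id`` column,
    or a mapping dataset_id -> filtered table. Unmatched queries still appear
    (all-False rows); a hit naming an unknown query raises.
    """
    universe = pd.Index(list(query_ids), name="query_id")
    if universe.has_duplicates:
        raise ConsistencyError("query universe contains duplicate ids")
    if isinstance(hits, Mapping):
        tables = dict(hits)
    else:
        if "dataset_id" not in hits.columns:
            raise ConsistencyError("hit table lacks a dataset_id column")
        tables = {ds: sub for ds, sub in hits.groupby("dataset_id", sort=True)}
    flags = pd.DataFrame(False, index=universe, columns=list(tables))
    for ds, table in tables.items():
        queries = pd.Index(table["query_id"].unique())
        unknown = queries.difference(universe)
        if len(unknown):
            raise ConsistencyError(
                f"dataset {ds!r}: hits reference unknown queries {sorted(unknown)[:10]}"
            )
        flags.loc[queries, ds] = True
    return PartitionTable(flags=flags)


@dataclass(frozen=True)
class EvalueSpectrum:
    frac_le_1e10: float
    frac_le_1e50: float
    histogram: pd.DataFrame  # columns: log10_bin, n_queries


def evalue_spectrum(hits: pd.DataFrame) -> EvalueSpectrum:
    """Best-e-value-per-query spectrum over annotated queries.

    Zero e-values are binned into the most significant histogram bin rather
    than failing the log transform.
    """
    if len(hits) == 0:
        raise DegenerateInputError("evalue_spectrum requires at least one hit")
    best = best_hits(hits)
    e = best["e_value"].to_numpy(dtype=float)
    n = len(e)
    frac10 = float((e <= 1e-10).sum()) / n
    frac50 = float((e <= 1e-50).sum()) / n
    floor = -200.0
    with np.errstate(divide="ignore"):
        log_e = np.where(e > 0, np.log10(np.maximum(e, 10.0**floor)), floor)
    bins = np.floor(np.clip(log_e, floor, 0.0)).astype(int)
    hist = (
        pd.Series(bins)
        .value_counts()
        .sort_index()
        .rename_axis("log10_bin")
        .rename("n_queries")
        .reset_index()
    )
    return EvalueSpectrum(frac_le_1e10=frac10, frac_le_1e50=frac50, histogram=hist)


def taxon_breakdown(
    hits: pd.DataFrame,
    taxon_map: Mapping[str, str],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Counts of best-hit subject taxa per query, optionally rolled up into groups.

    ``taxon_map`` maps subject ids to taxon labels; ``groups`` (optional)
    maps taxon labels to higher-level groups, supporting nested tallies
    such as bacterial-family counts inside a bacteria group.
    """
    best = best_hits(hits)
    unmapped = sorted(set(best["subject_id"]) - set(taxon_map))
    if unmapped:
        raise ConsistencyError(
            f"{len(unmapped)} best-hit subjects missing from taxon map: {unmapped[:10]}"
        )
    taxa = best["subject_id"].map(taxon_map)
    out = taxa.value_counts().rename_axis("taxon").rename("n_queries").reset_index()
    if groups is not None:
        out["group"] = out["taxon"].map(groups).fillna("other")
        out = out[["group", "taxon", "n_queries"]].sort_values(
            ["group", "taxon"], ignore_index=True
        )
    return out


def intraspecific_rate(
    self_hits: pd.DataFrame | int, n_reference_queries: int
) -> float:
    """Fraction of a reference's own transcripts with >= 1 surviving self-hit.

    Accepts either a filtered self-hit table (distinct queries are counted)
    or a pre-computed matched-query count.
    """
    if n_reference_queries <= 0:
        raise DegenerateInputError("n_reference_queries must be positive")
    if isinstance(self_hits, pd.DataFrame):
        n_matched = int(self_hits["query_id"].nunique())
    else:
        n_matched = int(self_hits)
    if not 0 <= n_matched <= n_reference_queries:
        raise ConsistencyError(
            f"matched count {n_matched} outside [0, {n_reference_queries}]"
        )
    return n_matched / n_reference_queries


@dataclass(frozen=True)
class CorrectionInput:
    """Marginals and intraspecific rate feeding the completeness correction."""

    n_total: int
    n_match: int
    n_nomatch: int
    p_intra: float

    def __post_init__(self) -> None:
        if self.n_match + self.n_nomatch != self.n_total:
            raise ConsistencyError(
                f"marginals do not sum: {self.n_match} + {self.n_nomatch} != {self.n_total}"
            )
        if not 0.0 <= self.p_intra <= 1.0:
            raise ConsistencyError(f"p_intra must be in [0, 1]; got {self.p_intra}")


@dataclass(frozen=True)
class CorrectedMatching:
    raw_fraction: float
    n_discarded: float
    corrected_fraction: float
    corrected_percent: int  # rounded to whole percent for report output


def corrected_matching(inp: CorrectionInput) -> CorrectedMatching:
    """Matching fraction after discarding reference-incompleteness non-matches."""
    discarded = inp.n_nomatch * (1.0 - inp.p_intra)
    denom = inp.n_total - discarded
    if denom <= 0:
        raise DegenerateInputError(
            "corrected matching undefined: all queries discarded "
            f"(n_total={inp.n_total}, discarded={discarded:.1f})"
        )
    corrected = inp.n_match / denom
    return CorrectedMatching(
        raw_fraction=inp.n_match / inp.n_total,
        n_discarded=discarded,
        corrected_fraction=corrected,
        corrected_percent=_round_half_away(100.0 * corrected),
    )
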