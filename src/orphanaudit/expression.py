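"""Expression calling against a random-probe empirical null.

Arrays carry thousands of "random" probes with no genomic target; their
per-condition intensity distribution is an empirical null for hybridization
background. For each condition the threshold is the q-quantile (default
0.995) of the random-probe intensities, so a single call has an empirical
per-test false-positive rate of 1 - q = 0.005. A target is "expressed" in a
condition when the median of its probes strictly exceeds that condition's
threshold, and "functional" when expressed in at least ``min_conditions``
conditions (default 2 of 12, the inversion of "no evidence of expression in
11 or 12 conditions"). Targets with a single probe use that probe's value
as the median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, StatisticsError

RANDOM_TARGET = "RANDOM"
MIN_NULL_PROBES = 200


def null_threshold(values: Sequence[float], q: float = 0.995) -> float:
    """Empirical q-quantile of null intensities (linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise StatisticsError("null_threshold: empty null set")
    if arr.size < MIN_NULL_PROBES:
        warnings.warn(
            f"only {arr.size} null values (< {MIN_NULL_PROBES}); "
            "quantile threshold will be noisy",
            stacklevel=2,
        )
    return float(np.quantile(arr, q))


@dataclass(frozen=True)
class ExpressionCalls:
    """Per-(target, condition) calls and per-target functional flags."""

    per_condition: pd.DataFrame  # target_id, condition_id, median_intensity, threshold, expressed
    per_target: pd.DataFrame  # target_id, n_conditions_expressed, functional
    thresholds: dict[str, float]
    q: float
    min_conditions: int

    @property
    def functional_targets(self) -> set[str]:
        mask = self.per_target["functional"]
        return set(self.per_target.loc[mask, "target_id"])


def call_expression(
    matrix: pd.DataFrame,
    q: float = 0.995,
    min_conditions: int = 2,
    targets: Iterable[str] | None = None,
) -> ExpressionCalls:
    """Call condition-dependent expression from a long-format probe matrix.

    ``matrix`` columns: probe_id, target_id (``RANDOM`` for null probes),
    condition_id, intensity. Thresholds come from the random probes of each
    condition; every condition must carry at least one. If ``targets`` is
    given, every listed target must have probes in the matrix.
    """
    required = {"probe_id", "target_id", "condition_id", "intensity"}
    missing_cols = required - set(matrix.columns)
    if missing_cols:
        raise ConsistencyError(f"probe matrix lacks columns {sorted(missing_cols)}")
    is_null = matrix["target_id"] == RANDOM_TARGET
    conditions = sorted(matrix["condition_id"].unique())
    thresholds: dict[str, float] = {}
    for cond in conditions:
        nulls = matrix.loc[is_null & (matrix["condition_id"] == cond), "intensity"]
        if nulls.empty:
            raise ConsistencyError(f"condition {cond!r} has no random probes")
        thresholds[cond] = null_threshold(nulls.to_numpy(), q)
    genes = matrix.loc[~is_null]
    if targets is not None:
        wanted = set(targets)
        present = set(genes["target_id"].unique())
        orphaned = sorted(wanted - present)
        if orphaned:
            raise ConsistencyError(
                f"{len(orphaned)} targets have zero probes: {orphaned[:10]}"
            )
        genes = genes[genes["target_id"].isin(wanted)]
    med = (
        genes.groupby(["target_id", "condition_id"], sort=True)["intensity"]
        .median()
        .rename("median_intensity")
        .reset_index()
    )
    med["threshold"] = med["condition_id"].map(thresholds)
    med["expressed"] = med["median_intensity"] > med["threshold"]  # strict
    per_target = (
        med.groupby("target_id", sort=True)["expressed"]
        .sum()
        .astype(int)
        .rename("n_conditions_expressed")
        .reset_index()
    )
    per_target["functional"] = per_target["n_conditions_expressed"] >= min_conditions
    return ExpressionCalls(
        per_condition=med,
        per_target=per_target,
        thresholds=thresholds,
        q=q,
        min_conditions=min_conditions,
    )


@dataclass(frozen=True)
class FunctionalSummary:
    """Counts of probed / retained (functional) / retained-with-annotation targets."""

    n_probed: int
    n_retained: int
    n_retained_annotated: int
    n_retained_unannotated: int

    def __post_init__(self) -> None:
        if self.n_retained_annotated + self.n_retained_unannotated != self.n_retained:
            raise ConsistencyError("retained annotated + unannotated != retained")

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_probed if self.n_probed else 0.0

    @property
    def annotated_of_retained(self) -> float:
        return self.n_retained_annotated / self.n_retained if self.n_retained else 0.0

    @property
    def unannotated_of_retained(self) -> float:
        return self.n_retained_unannotated / self.n_retained if self.n_retained else 0.0


def functional_summary(
    calls: ExpressionCalls, annotation: Mapping[str, bool]
) -> FunctionalSummary:
    """Tabulate functional targets by annotation status."""
    per_target = calls.per_target
    missing = sorted(set(per_target["target_id"]) - set(annotation))
    if missing:
        raise ConsistencyError(
            f"{len(missing)} probed targets missing annotation flags: {missing[:10]}"
        )
    retained = per_target[per_target["functional"]]
    n_ann = int(retained["target_id"].map(annotation).sum())
    return FunctionalSummary(
        n_probed=len(per_target),
        n_retained=len(retained),
        n_retained_annotated=n_ann,
        n_retained_unannotated=len(retained) - n_ann,
    )


def summary_from_counts(
    n_probed: int, n_retained: int, n_retained_annotated: int
) -> FunctionalSummary:
    """Build a summary directly from printed/count-table inputs."""
    return FunctionalSummary(
        n_probed=n_probed,
        n_retained=n_retained,
        n_retained_annotated=n_retained_annotated,
        n_retained_unannotated=n_retained - n_retained_annotated,
    )
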