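"""Gene-family exclusivity and its resampling null.

Given a family-by-species presence/absence matrix, a family is *exclusive*
to a focal species set when it is present in at least one focal species and
absent from every non-focal species. To judge whether a biologically
defined focal set (e.g. the blood-feeding arthropods) shares unusually many
exclusive families, the observed count is compared against the exclusive
counts of random same-size species combinations (default 30 draws of 5 of
the matrix's species), summarized by their mean and sample SD.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError

# combinations can repeat across draws by default (the sampling scheme is
# draws of k species without replacement *within* a draw); distinct=True
# forces all draws to be different combinations.


def read_family_matrix(path) -> pd.DataFrame:
    """Read a families-by-species TSV (0/1 or copy counts) as a boolean matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float) > 0


@dataclass(frozen=True)
class ExclusiveSet:
    """Families exclusive to a focal set, with the focal sharing spectrum.

    ``spectrum`` counts exclusive families by how many focal species carry
    them; its values sum to ``n_exclusive``.
    """

    focal: tuple[str, ...]
    families: tuple[str, ...]
    spectrum: dict[int, int]

    @property
    def n_exclusive(self) -> int:
        return len(self.families)


def exclusive_families(matrix: pd.DataFrame, focal: Iterable[str]) -> ExclusiveSet:
    """Families present in >= 1 focal species and in 0 non-focal species."""
    focal = tuple(focal)
    if not focal:
        raise ConfigurationError("focal set must be non-empty")
    unknown = sorted(set(focal) - set(matrix.columns))
    if unknown:
        raise ConsistencyError(f"unknown species in focal set: {unknown}")
    present = matrix.astype(bool)
    nonfocal = [s for s in matrix.columns if s not in set(focal)]
    in_focal = present[list(focal)].sum(axis=1)
    in_nonfocal = (
        present[nonfocal].any(axis=1)
        if nonfocal
        else pd.Series(False, index=matrix.index)
    )
    mask = (in_focal >= 1) & ~in_nonfocal
    fams = tuple(matrix.index[mask])
    spectrum = dict(sorted(Counter(int(k) for k in in_focal[mask]).items()))
    return ExclusiveSet(focal=focal, families=fams, spectrum=spectrum)


@dataclass(frozen=True)
class ResampleNull:
    mean: float
    sd: float
    counts: tuple[int, ...]
    combinations: tuple[tuple[str, ...], ...]

    @property
    def n_combinations(self) -> int:
        return len(self.counts)


def resample_null(
    matrix: pd.DataFrame,
    k: int = 5,
    n_combinations: int = 30,
    seed: int | None = None,
    distinct: bool = False,
    exclude: Sequence[str] | None = None,
) -> ResampleNull:
    """Exclusive-family counts for random k-species combinations.

    ``exclude`` (typically the observed focal set) removes one combination
    from the draw; with ``distinct=True`` every draw is a different
    combination (requires enough combinations to exist). Reproducible under
    ``seed``; sd is the sample (n-1) standard deviation.
    """
    species = list(matrix.columns)
    if k > len(species):
        raise ConfigurationError(f"k={k} exceeds n_species={len(species)}")
    if n_combinations < 2:
        raise ConfigurationError("n_combinations must be >= 2")
    excluded = tuple(sorted(exclude)) if exclude else None
    rng = np.random.default_rng(seed)
    combos: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    from math import comb

    available = comb(len(species), k) - (1 if excluded else 0)
    if distinct and n_combinations > available:
        raise ConfigurationError(
            f"cannot draw {n_combinations} distinct combinations; only {available} exist"
        )
    while len(combos) < n_combinations:
        pick = tuple(sorted(rng.choice(species, size=k, replace=False).tolist()))
        if excluded is not None and pick == excluded:
            continue
        if distinct and pick in seen:
            continue
        seen.add(pick)
        combos.append(pick)
    counts = tuple(exclusive_families(matrix, c).n_exclusive for c in combos)
    arr = np.asarray(counts, dtype=float)
    return ResampleNull(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        counts=counts,
        combinations=tuple(combos),
    )


def enumerate_null(matrix: pd.DataFrame, k: int) -> ResampleNull:
    """Exact enumeration over all k-species combinations (small matrices)."""
    combos = [tuple(c) for c in combinations(sorted(matrix.columns), k)]
    counts = tuple(exclusive_families(matrix, c).n_exclusive for c in combos)
    arr = np.asarray(counts, dtype=float)
    return ResampleNull(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        counts=counts,
        combinations=tuple(combos),
    )


@dataclass(frozen=True)
class NullComparison:
    observed: int
    null_mean: float
    null_sd: float
    z_score: float | None
    within_one_sd: bool | None


def compare_to_null(observed: int, null_mean: float, null_sd: float) -> NullComparison:
    """Standardize an observed exclusive count against the resampling null.

    When the null SD is zero the z-score is undefined (None) rather than
    infinite.
    """
    if null_sd == 0:
        return NullComparison(observed, null_mean, null_sd, None, None)
    z = (observed - null_mean) / null_sd
    return NullComparison(observed, null_mean, null_sd, z, abs(z) <= 1.0)
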