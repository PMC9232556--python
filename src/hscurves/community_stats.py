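"""Community-matrix statistics: Bray-Curtis, ANOSIM, Shannon diversity, EPT.

The ANOSIM implementation is rank-based (Clarke's R) with average ranks for
ties.  The permutation p-value uses the (b + 1) / (m + 1) estimator, which
never returns 0 and matches the convention under which 999 permutations can
yield p = 0.002 at b = 1.  For small designs an exact mode enumerates every
distinct assignment of group labels instead of sampling permutations.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import SampleRecord, TraitRecord

__all__ = [
    "EPT_ORDERS",
    "AnosimResult",
    "community_matrix",
    "log_density_transform",
    "bray_curtis",
    "anosim",
    "shannon",
    "ept_count",
]

#: Pollution-sensitive insect orders making up the EPT index.
EPT_ORDERS = frozenset({"Ephemeroptera", "Plecoptera", "Trichoptera"})


@dataclass(frozen=True)
class AnosimResult:
    """Outcome of an ANOSIM test.

    ``R`` lies in [-1, 1]: values near 1 mean between-group dissimilarities
    dominate, near 0 an even spread of ranks, below 0 more dissimilarity
    within groups than between them.
    """

    R: float
    p: float
    n_permutations: int
    grouping: tuple[str, ...]
    seed: int | None = None
    method: str = "permutation"

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.grouping:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def as_dict(self) -> dict:
        return {
            "R": self.R,
            "p": self.p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "method": self.method,
            "group_sizes": self.group_sizes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True))


def community_matrix(
    samples: Iterable[SampleRecord], taxa: Sequence[str] | None = None
) -> pd.DataFrame:
    """Samples-by-taxa abundance matrix with explicit zeros for absences."""
    samples = list(samples)
    if taxa is None:
        names: set[str] = set()
        for s in samples:
            names.update(s.counts)
        taxa = sorted(names)
    index = [s.sample_id for s in samples]
    data = np.zeros((len(samples), len(taxa)))
    col = {t: j for j, t in enumerate(taxa)}
    for i, s in enumerate(samples):
        for taxon, count in s.counts.items():
            if taxon in col:
                data[i, col[taxon]] = count
    return pd.DataFrame(data, index=index, columns=list(taxa))


def log_density_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ln(1 + x), the usual variance-stabilising transform."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundances cannot be log-transformed")
    return pd.DataFrame(np.log1p(values), index=matrix.index, columns=matrix.columns)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample rows.

    d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).  A pair of all-zero
    samples is undefined by the formula and is set to 0 with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=-1)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=-1)
    zero = den == 0
    if zero[~np.eye(n, dtype=bool)].any():
        warnings.warn(
            "pair(s) of all-zero samples: Bray-Curtis undefined, set to 0",
            stacklevel=2,
        )
    d = np.divide(num, den, out=np.zeros_like(num), where=~zero)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _distinct_assignments(codes: np.ndarray):
    """Yield every distinct arrangement of the label multiset ``codes``."""
    values, counts = np.unique(codes, return_counts=True)
    n = len(codes)
    out = np.empty(n, dtype=codes.dtype)

    def rec(avail: tuple[int, ...], vi: int):
        if vi == len(values) - 1:
            for pos in avail:
                out[pos] = values[-1]
            yield out.copy()
            return
        for chosen in itertools.combinations(avail, int(counts[vi])):
            chosen_set = set(chosen)
            for pos in chosen:
                out[pos] = values[vi]
            rest = tuple(p for p in avail if p not in chosen_set)
            yield from rec(rest, vi + 1)

    yield from rec(tuple(range(n)), 0)


def anosim(
    dissimilarity: pd.DataFrame | np.ndarray,
    grouping: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> AnosimResult:
    """Analysis of similarities on a pairwise dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M / 2) with
    M = n(n-1)/2 pairwise dissimilarities ranked jointly (average ranks on
    ties); R = 1 exactly when every between-group dissimilarity exceeds every
    within-group one.  ``exact=True`` replaces Monte-Carlo label permutation
    with exhaustive enumeration of all distinct label assignments, giving the
    exact permutation p-value (observed assignment included in the tally).
    """
    D = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray([str(g) for g in grouping])
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError(f"dissimilarity shape {D.shape} does not match {n} labels")
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if counts.min() < 2:
        small = values[counts < 2].tolist()
        raise ValueError(f"every group needs at least 2 samples; too small: {small}")

    iu = np.triu_indices(n, k=1)
    condensed = D[iu]
    if np.allclose(condensed, condensed[0]):
        warnings.warn(
            "constant dissimilarity matrix: ANOSIM R is 0 by construction",
            stacklevel=2,
        )
    ranks = rankdata(condensed)  # average ranks for ties
    denom = condensed.size / 2.0
    codes = np.searchsorted(values, labels)

    def r_stat(code_rows: np.ndarray) -> np.ndarray:
        same = code_rows[:, iu[0]] == code_rows[:, iu[1]]
        r_within = (ranks * same).sum(axis=1) / same.sum(axis=1)
        r_between = (ranks * ~same).sum(axis=1) / (~same).sum(axis=1)
        return (r_between - r_within) / denom

    r_obs = float(r_stat(codes[None, :])[0])
    tol = 1e-12
    if exact:
        perms = np.array(list(_distinct_assignments(codes)))
        r_perm = r_stat(perms)
        p = float(np.count_nonzero(r_perm >= r_obs - tol) / len(perms))
        n_reported = len(perms)
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
        r_perm = r_stat(perms)
        exceed = int(np.count_nonzero(r_perm >= r_obs - tol))
        p = (exceed + 1) / (n_permutations + 1)
        n_reported = n_permutations
        method = "permutation"
    return AnosimResult(
        R=r_obs,
        p=p,
        n_permutations=n_reported,
        grouping=tuple(labels.tolist()),
        seed=seed,
        method=method,
    )


def shannon(counts: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon-Wiener diversity H = -sum p_i ln p_i over taxa present.

    Invariant under rescaling all counts by a positive constant.  Raises on
    an all-zero input; callers that need H = 0 for empty microhabitats (the
    K coefficient does) handle that case themselves.
    """
    if isinstance(counts, Mapping):
        values = np.asarray(list(counts.values()), dtype=float)
    else:
        values = np.asarray(list(counts), dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


def ept_count(
    sample: SampleRecord,
    traits: Iterable[TraitRecord] | Mapping[str, str],
) -> int:
    """Number of Ephemeroptera, Plecoptera and Trichoptera individuals.

    ``traits`` may be a list of trait records or a taxon -> order mapping.
    """
    if isinstance(traits, Mapping):
        orders = dict(traits)
    else:
        orders = {t.taxon: t.order for t in traits}
    missing = sorted(t for t in sample.counts if t not in orders)
    if missing:
        raise ValueError(f"taxa without an order assignment: {missing}")
    return sum(
        count for taxon, count in sample.counts.items()
        if orders[taxon] in EPT_ORDERS
    )
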