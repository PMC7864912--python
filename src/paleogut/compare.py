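"""Compositional comparison: Bray-Curtis, PCoA, PERMANOVA, rank-sum tests.

Implements the group-comparison layer: Bray-Curtis dissimilarities between
abundance profiles, classical metric scaling (principal coordinates),
distance-based one-way PERMANOVA with a seeded permutation null for the
pseudo-F ratio, the Wilcoxon rank-sum test between two sample groups, and
the reads-per-million normalisation for damage-selected read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .profiles import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermTestResult",
    "bray_curtis",
    "pcoa",
    "permanova",
    "wilcoxon_ranksum",
    "pmds_reads_per_million",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.nanmin(self.data) < 0:
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray
    has_negative_eigenvalues: bool = False


@dataclass(frozen=True)
class PermTestResult:
    pseudo_F: float
    p: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        floor = 1.0 / (self.n_perm + 1)
        if not (floor - 1e-12 <= self.p <= 1.0 + 1e-12):
            raise ValueError("permutation p-value outside attainable range")


def bray_curtis(table: AbundanceTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample rows:
    d(i,j) = sum|x_i - x_j| / sum(x_i + x_j) over taxa, in [0, 1]."""
    counts = table.counts if isinstance(table, AbundanceTable) else table
    ids = [str(s) for s in counts.index]
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(counts.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(ids=ids, data=d)


def pcoa(dm: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers -0.5*D^2, eigendecomposes, and scales eigenvectors by
    the square root of their eigenvalues. Axes with non-positive eigenvalues
    are dropped (no Cailliez/Lingoes correction); negative eigenvalues are
    still reported and flagged, since they signal a non-Euclidean distance.
    """
    n = dm.n
    d2 = dm.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-12
    positive = evals > tol
    n_axes = int(positive.sum())
    if k is not None:
        n_axes = min(n_axes, k)
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    pos_sum = evals[positive].sum()
    prop = evals[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=dm.ids, columns=[f"PC{i+1}" for i in range(n_axes)]
        ),
        eigenvalues=evals,
        proportion_explained=prop,
        has_negative_eigenvalues=bool((evals < -tol).any()),
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way distance-based pseudo-F from squared distances.

    SS_total = sum_{i<j} d2_ij / N; SS_within sums the analogous per-group
    terms; F = (SS_between/(a-1)) / (SS_within/(N-a)).
    """
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within <= 0:
        return np.inf
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermTestResult:
    """Permutation test of group separation via the pseudo-F ratio.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm), so the smallest
    attainable p is 1/(n_perm + 1).
    """
    if len(groups) != dm.n:
        raise ValueError("groups length must match the distance matrix")
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    if len(labels) >= dm.n:
        raise ValueError("need at least one group with >1 sample")
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, codes, len(labels))
    rng = np.random.Generator(np.random.PCG64(seed))
    n_ge = 0
    for _ in range(n_perm):
        f_perm = _pseudo_f(d2, rng.permutation(codes), len(labels))
        if f_perm >= f_obs:
            n_ge += 1
    return PermTestResult(
        pseudo_F=float(f_obs), p=(1 + n_ge) / (1 + n_perm), n_perm=n_perm, seed=seed
    )


def wilcoxon_ranksum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) between two independent groups.

    Uses the exact null distribution when both groups are small (n <= 12)
    and untied, the normal approximation with continuity correction
    otherwise. Returns (U statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def pmds_reads_per_million(n_pmds5: int, n_total: int) -> float:
    """Damage-selected reads per million sequenced reads: 1e6 * n5 / n."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_pmds5 < 0:
        raise ValueError("n_pmds5 must be >= 0")
    return 1e6 * n_pmds5 / n_total
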