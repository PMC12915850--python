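"""Diversity metrics, dissimilarities, ordination and PERMANOVA.

All statistics are implemented directly from their defining formulas so
that each can be checked against independent oracles; the PERMANOVA uses
the partitioning of the summed squared dissimilarities with free label
permutation and the add-one p-value convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with sample labels."""

    sample_ids: list[str]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match sample_ids")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("asymmetric distance matrix")
        if d.min() < -1e-12 or d.max() > 1.0 + 1e-9:
            raise ValueError("dissimilarities outside [0, 1]")
        self.matrix = d

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def shannon(abundances: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats), with 0 ln 0 = 0."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundance")
    total = a.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = a / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: sum |x_i - y_i| / sum (x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundance")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors all zero")
    return float(np.abs(x - y).sum() / denom)


def jaccard(
    x: Sequence[float], y: Sequence[float], presence_threshold: float = 0.0
) -> float:
    """Jaccard dissimilarity 1 - |A & B| / |A | B| on presence sets.

    Presence means abundance strictly above ``presence_threshold``
    (default 0, appropriate after QC zeroing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    a = x > presence_threshold
    b = y > presence_threshold
    union = (a | b).sum()
    if union == 0:
        raise ValueError("both presence sets empty")
    return float(1.0 - (a & b).sum() / union)


def distance_matrix(
    values: np.ndarray,
    sample_ids: Sequence[str],
    metric: str = "bray_curtis",
    presence_threshold: float = 0.0,
) -> DistanceMatrix:
    """All pairwise dissimilarities of a samples x taxa matrix."""
    X = np.asarray(values, dtype=float)
    n = X.shape[0]
    d = np.zeros((n, n))
    if metric == "bray_curtis":
        # vectorized: |x-y| summed via broadcasting in manageable blocks
        for i in range(n):
            diff = np.abs(X[i + 1 :] - X[i]).sum(axis=1)
            tot = (X[i + 1 :] + X[i]).sum(axis=1)
            with np.errstate(invalid="ignore"):
                row = np.where(tot > 0, diff / tot, 0.0)
            d[i, i + 1 :] = row
            d[i + 1 :, i] = row
    elif metric == "jaccard":
        P = X > presence_threshold
        inter = P.astype(float) @ P.T
        counts = P.sum(axis=1)
        union = counts[:, None] + counts[None, :] - inter
        with np.errstate(invalid="ignore"):
            d = np.where(union > 0, 1.0 - inter / union, 0.0)
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(sample_ids), d, metric)


def pcoa(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Classical scaling (principal coordinates analysis).

    Double-centers -D^2/2, eigendecomposes, and returns coordinates for
    the positive eigenvalues along with ALL eigenvalues in decreasing
    order (negative ones are reported, not dropped — they flag
    non-Euclidean structure in the dissimilarity).
    """
    n = d.n
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    D2 = d.matrix ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > 1e-12 * max(evals.max(), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])[None, :]
    return coords, evals


def _permanova_stats(
    d2: np.ndarray, group_codes: np.ndarray, n_groups: int
) -> tuple[float, float, float]:
    """(R^2, pseudo-F, SS_total) from squared dissimilarities."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)  # sum over i<j of d^2 / N
    ss_within = 0.0
    for g in range(n_groups):
        mask = group_codes == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    return r2, f, ss_total


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    strata: Optional[Sequence[str]] = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    Partitions the sum of squared dissimilarities into between- and
    within-group components; significance by free permutation of the
    group labels (optionally within strata), p with the add-one
    convention so 0 is never reported.
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise ValueError("groups length does not match distance matrix")
    uniq, codes = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    d2 = d.matrix ** 2
    r2, f_obs, _ = _permanova_stats(d2, codes, len(uniq))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ge = 0
    idx = np.arange(d.n)
    strata_arr = None if strata is None else np.asarray(strata)
    for _ in range(n_permutations):
        if strata_arr is None:
            perm = rng.permutation(idx)
        else:
            perm = idx.copy()
            for s in np.unique(strata_arr):
                m = np.where(strata_arr == s)[0]
                perm[m] = m[rng.permutation(len(m))]
        _, f_perm, _ = _permanova_stats(d2, codes[perm], len(uniq))
        if f_perm >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return PermanovaResult(float(r2), float(f_obs), float(p), n_permutations)


def within_group_dissimilarity_test(
    d: DistanceMatrix, groups: Sequence[str]
) -> dict:
    """Compare within-group pairwise dissimilarities between two groups.

    Collects all within-group pairwise dissimilarities per group and
    applies a two-sided Wilcoxon rank-sum test — an operationalization
    of "community heterogeneity differs between groups".
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    sets = {}
    for g in uniq:
        m = np.where(groups == g)[0]
        if len(m) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        iu = np.triu_indices(len(m), k=1)
        sets[str(g)] = d.matrix[np.ix_(m, m)][iu]
    a, b = (sets[str(u)] for u in uniq)
    if np.ptp(np.concatenate([a, b])) == 0:
        p = 1.0
        stat = 0.0
    else:
        stat, p = stats.ranksums(a, b)
    return {
        "groups": [str(u) for u in uniq],
        "dissimilarities": sets,
        "median_difference": float(np.median(a) - np.median(b)),
        "statistic": float(stat),
        "p_value": float(p),
    }
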