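"""Community-ecology statistics: theta_YC dissimilarity, diversity indices,
permutation AMOVA and group-comparison utilities.

theta_YC (Yue & Clayton) between compositions p and q:

    d(p, q) = 1 - sum(p*q) / (sum(p^2) + sum(q^2) - sum(p*q))

AMOVA partitions the pairwise squared-distance sum of squares among vs
within groups (Excoffier's partition) and assesses the F-ratio by label
permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def inverse_simpson(counts_row) -> float:
    """1 / sum(p_i^2) for the relative abundances of a sample."""
    row = np.asarray(counts_row, dtype=float)
    total = row.sum()
    if row.size == 0 or total <= 0:
        raise ValueError("inverse Simpson undefined for an empty sample")
    p = row / total
    return float(1.0 / np.sum(p**2))


def observed_richness(counts_row) -> int:
    """Number of OTUs with count > 0."""
    return int(np.count_nonzero(np.asarray(counts_row) > 0))


def theta_yc(p, q) -> float:
    """Yue-Clayton dissimilarity between two compositions (each sums to 1)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("compositions must share the OTU index")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("compositions must be nonnegative")
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("compositions must sum to 1 (within 1e-9)")
    cross = float(np.dot(p, q))
    denom = float(np.dot(p, p) + np.dot(q, q)) - cross
    return 1.0 - cross / denom


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    metric_name: str = "thetayc"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(self.d)).max() > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def theta_yc_matrix(counts: pd.DataFrame, metric_name: str = "thetayc") -> DistanceMatrix:
    """All pairwise theta_YC distances between the rows of a count table."""
    mat = counts.to_numpy(dtype=float)
    totals = mat.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("every sample needs positive total count")
    rel = mat / totals
    gram = rel @ rel.T
    sq = np.diag(gram)
    denom = sq[:, None] + sq[None, :] - gram
    d = 1.0 - gram / denom
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(counts.index), d=d, metric_name=metric_name)


def _within_ss(d2: np.ndarray, membership: np.ndarray, sizes: np.ndarray) -> float:
    """Sum over groups of (sum of within-group squared distances)/(2*n_g)."""
    ss = 0.0
    for g, n_g in enumerate(sizes):
        mask = membership == g
        ss += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss


def amova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation AMOVA on a distance matrix.

    Returns ``(F, p)`` with ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = pd.Series(list(groups), index=dm.ids)
    codes, uniques = pd.factorize(labels)
    k = len(uniques)
    if k < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 samples")
    n = len(codes)
    d2 = dm.d**2

    ss_total = d2.sum() / (2.0 * n)
    ss_within = _within_ss(d2, codes, sizes)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    f_obs = (ss_among / df_among) / (ss_within / df_within)

    rng = np.random.default_rng(seed)
    # batch the permutations: per-group sums via indicator matmuls
    perms = np.empty((n_perm, n), dtype=np.int64)
    for b in range(n_perm):
        perms[b] = rng.permutation(codes)
    within = np.zeros(n_perm)
    for g in range(k):
        ind = (perms == g).astype(float)  # n_perm x n
        within += np.einsum("bi,bi->b", ind @ d2, ind) / (2.0 * sizes[g])
    among = ss_total - within
    f_perm = (among / df_among) / (within / df_within)
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)
    return float(f_obs), float(p)


def diversity_t_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test (Student's t)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs n >= 2")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            warnings.warn("zero pooled variance; identical arms -> p = 1")
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means")
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def nmds_embed(dm: DistanceMatrix, k: int = 2, seed: int = 0, n_init: int = 4):
    """Nonmetric MDS ordination (plumbing; visualization support only).

    Returns ``(coords, stress)`` where ``stress`` is Kruskal stress-1.
    """
    from sklearn.manifold import MDS

    mds = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        random_state=seed,
        n_init=n_init,
        normalized_stress=True,
    )
    coords = mds.fit_transform(dm.d)
    return coords, float(mds.stress_)
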