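"""Mahalanobis-metric clustering of per-SNP selectivity profiles.

Each SNP's selectivity across the ten characteristics is summarized by a
t-statistic vector t_c = (beta_with - beta_without) / sqrt(se_with^2 +
se_without^2).  Because the characteristics overlap within individuals,
the vector entries are correlated; the covariance is estimated from a
panel of SNPs with no migraine association, and the Mahalanobis metric
d(x, y) = sqrt((x-y)' Sigma^-1 (x-y)) whitens that correlation before
agglomerative clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .constants import CHARACTERISTICS

__all__ = [
    "TStatVector",
    "NullCovariance",
    "build_tstat_vector",
    "tstat_vectors_from_effects",
    "estimate_null_covariance",
    "mahalanobis_distance",
    "pairwise_mahalanobis",
    "hierarchical_cluster",
    "ClusterResult",
]


@dataclass(frozen=True)
class TStatVector:
    snp_id: str
    t: np.ndarray  # length-10, ordered as CHARACTERISTICS

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.shape != (len(CHARACTERISTICS),):
            raise ValueError(
                f"selectivity vector must have length {len(CHARACTERISTICS)}"
            )
        if not np.isfinite(t).all():
            raise ValueError(f"{self.snp_id}: non-finite selectivity entries")
        object.__setattr__(self, "t", t)


@dataclass(frozen=True)
class NullCovariance:
    sigma: np.ndarray
    n_null_snps: int


def build_tstat_vector(snp_id: str, effects: pd.DataFrame) -> TStatVector:
    """Selectivity vector from a with/without effects table for one SNP.

    ``effects`` needs columns characteristic, stratum, beta, se covering
    all ten characteristics in both strata.
    """
    t = np.empty(len(CHARACTERISTICS))
    for c, name in enumerate(CHARACTERISTICS):
        sub = effects[effects["characteristic"] == name]
        w = sub[sub["stratum"] == "with"]
        o = sub[sub["stratum"] == "without"]
        if len(w) != 1 or len(o) != 1:
            raise ValueError(f"{snp_id}: missing with/without pair for {name!r}")
        bw, sw = float(w["beta"].iloc[0]), float(w["se"].iloc[0])
        bo, so = float(o["beta"].iloc[0]), float(o["se"].iloc[0])
        if not (sw > 0 and so > 0):
            raise ValueError(f"{snp_id}: non-positive SE for {name!r}")
        t[c] = (bw - bo) / np.sqrt(sw**2 + so**2)
    return TStatVector(snp_id=snp_id, t=t)


def tstat_vectors_from_effects(effects: pd.DataFrame) -> list[TStatVector]:
    return [
        build_tstat_vector(snp_id, grp)
        for snp_id, grp in effects.groupby("snp_id", sort=False)
    ]


def estimate_null_covariance(
    null_vectors: list[TStatVector] | np.ndarray, min_snps: int = 30
) -> NullCovariance:
    """Sample covariance of selectivity vectors over a null-SNP panel."""
    if isinstance(null_vectors, np.ndarray):
        mat = np.asarray(null_vectors, dtype=float)
    else:
        mat = np.stack([v.t for v in null_vectors])
    if mat.shape[0] < min_snps:
        raise ValueError(
            f"need at least {min_snps} null SNPs to estimate the covariance, "
            f"got {mat.shape[0]}"
        )
    sigma = np.cov(mat, rowvar=False)
    if np.allclose(sigma, 0.0):
        warnings.warn("degenerate null panel: covariance is the zero matrix")
    return NullCovariance(sigma=sigma, n_null_snps=mat.shape[0])


def _inverse(sigma: np.ndarray) -> np.ndarray:
    # pseudo-inverse fallback for singular covariance
    try:
        return np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance: using Moore-Penrose pseudo-inverse")
        return np.linalg.pinv(sigma)


def mahalanobis_distance(
    x: TStatVector | np.ndarray,
    y: TStatVector | np.ndarray,
    cov: NullCovariance | np.ndarray,
) -> float:
    xv = x.t if isinstance(x, TStatVector) else np.asarray(x, dtype=float)
    yv = y.t if isinstance(y, TStatVector) else np.asarray(y, dtype=float)
    sigma = cov.sigma if isinstance(cov, NullCovariance) else np.asarray(cov)
    if xv.shape != yv.shape or sigma.shape != (xv.size, xv.size):
        raise ValueError("dimension mismatch between vectors and covariance")
    d = xv - yv
    q = float(d @ _inverse(sigma) @ d)
    return float(np.sqrt(max(q, 0.0)))


def pairwise_mahalanobis(
    vectors: list[TStatVector], cov: NullCovariance
) -> pd.DataFrame:
    """Symmetric SNP x SNP Mahalanobis distance matrix."""
    ids = [v.snp_id for v in vectors]
    mat = np.stack([v.t for v in vectors])
    vi = _inverse(cov.sigma)
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = mat[i] - mat[j]
            dist[i, j] = dist[j, i] = np.sqrt(max(float(d @ vi @ d), 0.0))
    return pd.DataFrame(dist, index=ids, columns=ids)


@dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    newick: str


def hierarchical_cluster(
    dist: pd.DataFrame, method: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering of a precomputed distance matrix.

    Complete linkage by default ('single'/'average' also accepted); the
    leaf order sorts report rows, and the merge tree is exported as a
    Newick string with merge-height differences as branch lengths.
    """
    labels = list(dist.index)
    mat = dist.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("distance matrix contains non-finite entries")
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) == 1:
        return ClusterResult(
            linkage=np.empty((0, 4)),
            labels=labels,
            leaf_order=labels,
            newick=f"{labels[0]};",
        )
    condensed = squareform(mat, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        linkage=Z, labels=labels, leaf_order=order, newick=_to_newick(Z, labels)
    )


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"
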