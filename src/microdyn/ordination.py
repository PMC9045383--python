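"""PCA of community profiles and MANOVA-style group separation.

Samples' OTU fractional-abundance profiles are reduced by PCA
(mean-centered, unscaled); group separation (by subject, gender or phase)
is then assessed on the leading principal components via Mahalanobis
distances between group means under the pooled within-group covariance,
an overall one-way MANOVA (Wilks' lambda with Rao's F approximation),
pairwise Hotelling's T-squared tests (Bonferroni-adjusted), and a
single-linkage dendrogram over the group-mean distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform


@dataclass
class PcaModel:
    loadings: np.ndarray            # components x features
    scores: pd.DataFrame            # samples x components
    explained_variance_ratio: np.ndarray


@dataclass
class GroupSeparation:
    labels: list[str]
    mahalanobis: pd.DataFrame       # group x group distances between means
    statistic_name: str
    statistic: float                # Wilks' lambda
    F: float
    df: tuple[float, float]
    p: float
    pairwise_p: dict[tuple[str, str], float]
    pairwise_p_adjusted: dict[tuple[str, str], float]
    merges: list[tuple[str, str, float]]   # single-linkage merge list
    n_pcs_used: int


def pca(abundances: pd.DataFrame, n_components: int) -> PcaModel:
    """Column-mean-centered PCA via SVD; components ordered by variance."""
    X = abundances.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    bound = min(n - 1, m)
    if n_components > bound:
        raise ValueError(f"n_components must be <= min(samples-1, features) = {bound}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention: largest-magnitude loading positive
    for k in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2 / (n - 1)
    total_var = Xc.var(axis=0, ddof=1).sum()
    ratio = var / total_var if total_var > 0 else np.zeros_like(var)
    scores = U * s
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PcaModel(
        loadings=Vt[:n_components],
        scores=pd.DataFrame(scores[:, :n_components], index=abundances.index,
                            columns=cols),
        explained_variance_ratio=ratio[:n_components],
    )


def _wilks_rao_f(lam: float, p: int, k: int, N: int) -> tuple[float, tuple[float, float], float]:
    """Rao's F approximation for Wilks' lambda (p dims, k groups, N samples)."""
    q = k - 1
    num = p * p * q * q - 4
    den = p * p + q * q - 5
    t = np.sqrt(num / den) if den > 0 and num > 0 else 1.0
    df1 = p * q
    df2 = ((N - k) - (p - q + 1) / 2.0) * t - (p * q - 2) / 2.0
    if df2 <= 0 or lam <= 0:
        return np.inf, (df1, max(df2, 1e-9)), 0.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return float(F), (float(df1), float(df2)), pval


def group_separation(
    scores: pd.DataFrame, labels: pd.Series | list, n_pcs: int = 25
) -> GroupSeparation:
    """Separation statistics between labelled groups of PC scores.

    ``n_pcs`` is capped at ``min(n_pcs, available PCs, N - k - 1)`` to keep
    the pooled covariance invertible; the covariance additionally carries a
    tiny ridge (1e-8 x trace/dim).
    """
    labels = pd.Series(labels, index=scores.index).astype(str)
    groups = sorted(labels.unique())
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with < 2 samples: {small}")
    N = len(scores)
    p = min(n_pcs, scores.shape[1], N - k - 1)
    if p < 1:
        raise ValueError("not enough samples for even one PC dimension")
    X = scores.to_numpy(dtype=float)[:, :p]

    means = {}
    W = np.zeros((p, p))
    for g in groups:
        sel = X[(labels == g).to_numpy()]
        means[g] = sel.mean(axis=0)
        dev = sel - means[g]
        W += dev.T @ dev
    pooled = W / (N - k)
    pooled = pooled + np.eye(p) * (1e-8 * np.trace(pooled) / p)
    try:
        pooled_inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance singular even after regularization; use fewer PCs"
        ) from exc

    dist = pd.DataFrame(0.0, index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        d = means[a] - means[b]
        dist.loc[a, b] = dist.loc[b, a] = float(np.sqrt(d @ pooled_inv @ d))

    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    for g in groups:
        d = (means[g] - grand)[:, None]
        B += sizes[g] * (d @ d.T)
    lam = float(np.linalg.det(W) / np.linalg.det(W + B))
    F, df, pval = _wilks_rao_f(lam, p, k, N)

    pairs = list(combinations(groups, 2))
    pairwise, adjusted = {}, {}
    for a, b in pairs:
        pairwise[(a, b)] = _hotelling_t2_p(
            X[(labels == a).to_numpy()], X[(labels == b).to_numpy()]
        )
        adjusted[(a, b)] = min(pairwise[(a, b)] * len(pairs), 1.0)

    merges = _single_linkage(dist)

    return GroupSeparation(
        labels=groups,
        mahalanobis=dist,
        statistic_name="wilks_lambda",
        statistic=lam,
        F=F,
        df=df,
        p=pval,
        pairwise_p=pairwise,
        pairwise_p_adjusted=adjusted,
        merges=merges,
        n_pcs_used=p,
    )


def _hotelling_t2_p(A: np.ndarray, B: np.ndarray) -> float:
    """Two-sample Hotelling's T-squared p-value (F distribution)."""
    na, nb = len(A), len(B)
    p = A.shape[1]
    diff = A.mean(axis=0) - B.mean(axis=0)
    Sa = np.cov(A, rowvar=False, ddof=1)
    Sb = np.cov(B, rowvar=False, ddof=1)
    Sp = ((na - 1) * Sa + (nb - 1) * Sb) / (na + nb - 2)
    Sp = np.atleast_2d(Sp)
    Sp = Sp + np.eye(p) * (1e-8 * np.trace(Sp) / p)
    t2 = (na * nb) / (na + nb) * float(diff @ np.linalg.inv(Sp) @ diff)
    df2 = na + nb - 1 - p
    if df2 <= 0:
        return 1.0
    F = t2 * df2 / ((na + nb - 2) * p)
    return float(stats.f.sf(F, p, df2))


def _single_linkage(dist: pd.DataFrame) -> list[tuple[str, str, float]]:
    """Single-linkage merge list over a symmetric distance matrix."""
    groups = list(dist.index)
    if len(groups) < 2:
        return []
    Z = linkage(squareform(dist.to_numpy(), checks=False), method="single")
    clusters: dict[int, list[str]] = {i: [g] for i, g in enumerate(groups)}
    merges = []
    nxt = len(groups)
    for a_i, b_i, height, _cnt in Z:
        a, b = clusters[int(a_i)], clusters[int(b_i)]
        merges.append(("+".join(sorted(a)), "+".join(sorted(b)), float(height)))
        clusters[nxt] = sorted(a + b)
        nxt += 1
    return merges
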