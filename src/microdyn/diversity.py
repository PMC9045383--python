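"""Alpha diversity, weighted UniFrac beta diversity and grouped distance tests.

The convergence question — does a shared living environment make
individuals' communities more alike? — is answered by comparing
between-subject weighted UniFrac distances across experimental phases
with a Kruskal-Wallis rank sum test and Bonferroni-adjusted pairwise
comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .io import OtuTable

logger = logging.getLogger(__name__)


@dataclass
class GroupTestResult:
    grouping: str
    H: float
    df: int
    p: float
    pairwise_p: dict[tuple[str, str], float]
    pairwise_p_adjusted: dict[tuple[str, str], float]


def alpha_diversity(table: OtuTable, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity: Shannon (natural log) or observed OTUs."""
    if metric not in {"shannon", "observed_otus"}:
        raise ValueError(f"unknown metric {metric!r}")
    counts = table.counts
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-total sample")
    if metric == "observed_otus":
        return (counts > 0).sum(axis=0).astype(float).rename("observed_otus")
    frac = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(frac > 0, frac * np.log(frac), 0.0)
    return pd.Series(-plogp.sum(axis=0), index=counts.columns, name="shannon")


# ---------------------------------------------------------------------------
# weighted UniFrac

def _branch_profile(tree: TreeNode, fractions: pd.DataFrame):
    """Branch lengths and per-branch descending mass for each sample.

    ``fractions`` is leaves x samples. Returns ``(lengths, masses)`` with
    one row per non-root branch; ``masses[b, s]`` is the fraction of
    sample ``s`` descending through branch ``b`` (postorder accumulation).
    """
    leaf_names = {t.name for t in tree.tips()}
    extra = [i for i in fractions.index if i not in leaf_names]
    if extra:
        raise ValueError(f"composition ids missing from tree: {extra}")
    n_samples = fractions.shape[1]
    lookup = {i: fractions.loc[i].to_numpy(dtype=float) for i in fractions.index}
    lengths, masses = [], []
    acc: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = lookup.get(node.name, np.zeros(n_samples))
        else:
            vec = np.zeros(n_samples)
            for child in node.children:
                vec = vec + acc.pop(id(child))
        acc[id(node)] = vec
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            masses.append(vec)
    return np.asarray(lengths), np.asarray(masses)


def weighted_unifrac(
    sample_p, sample_q, tree: TreeNode, normalized: bool = True
) -> float:
    """Weighted UniFrac distance between two compositions on a tree.

    Raw distance: ``sum_b len_b * |P_b - Q_b|`` over all non-root
    branches, where ``P_b`` is the fraction of sample P descending through
    branch ``b``. The normalized variant divides by
    ``sum_b len_b * (P_b + Q_b)`` and is bounded in [0, 1].
    """
    p = pd.Series(sample_p, dtype=float)
    q = pd.Series(sample_q, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("compositions must each sum to 1")
    frac = pd.DataFrame({"p": p, "q": q}).fillna(0.0)
    lengths, masses = _branch_profile(tree, frac)
    diff = float(np.sum(lengths * np.abs(masses[:, 0] - masses[:, 1])))
    if not normalized:
        return diff
    denom = float(np.sum(lengths * (masses[:, 0] + masses[:, 1])))
    return diff / denom if denom > 0 else 0.0


def unifrac_matrix(
    table: OtuTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """All-pairs weighted UniFrac over the table's samples (single tree pass)."""
    fractions = table.fractions()
    lengths, masses = _branch_profile(tree, fractions)
    n = fractions.shape[1]
    out = np.zeros((n, n))
    denom_parts = lengths[:, None] * masses
    for i, j in combinations(range(n), 2):
        diff = float(np.sum(lengths * np.abs(masses[:, i] - masses[:, j])))
        if normalized:
            denom = float(np.sum(denom_parts[:, i] + denom_parts[:, j]))
            diff = diff / denom if denom > 0 else 0.0
        out[i, j] = out[j, i] = diff
    return DistanceMatrix(out, ids=list(fractions.columns))


# ---------------------------------------------------------------------------
# grouped distances

def between_subject_distances(
    dm: DistanceMatrix, metadata: pd.DataFrame, stratify_by: str = "phase"
) -> dict[str, list[float]]:
    """Between-subject distances at matched time points, stratified.

    ``stratify_by`` is a metadata column (``phase`` or ``time_point``).
    Distances are always taken between distinct subjects sampled at the
    same time point; a phase stratum pools its time points' pairs. Strata
    with fewer than 2 subjects yield an empty list with a warning.
    """
    if stratify_by not in metadata.columns:
        raise ValueError(f"unknown metadata column {stratify_by!r}")
    ids = [i for i in dm.ids if i in metadata.index]
    result: dict[str, list[float]] = {}
    for stratum, rows in metadata.loc[ids].groupby(stratify_by, sort=True):
        if rows["subject"].nunique() < 2:
            logger.warning("stratum %r has < 2 subjects; empty distance list", stratum)
            result[str(stratum)] = []
            continue
        vals = [
            float(dm[a, b])
            for _, tp_rows in rows.groupby("time_point")
            for a, b in combinations(tp_rows.index, 2)
            if tp_rows.loc[a, "subject"] != tp_rows.loc[b, "subject"]
        ]
        result[str(stratum)] = vals
    return result


def convergence_test(
    dm: DistanceMatrix, metadata: pd.DataFrame
) -> tuple[GroupTestResult, dict[str, float]]:
    """Phase-grouped test of between-subject community convergence.

    Pooling every between-subject pair into the Kruskal-Wallis test
    pseudo-replicates heavily (each sample sits in several pairs and each
    subject pair recurs at every time point), which inflates the test far
    beyond its nominal level. Instead, each time point is summarized by
    its mean between-subject distance — conditionally independent across
    time points — and those per-time-point means are grouped by phase.
    Returns the test result and the per-phase medians of the summaries.
    """
    by_tp = between_subject_distances(dm, metadata, "time_point")
    tp_phase = metadata.groupby("time_point")["phase"].first()
    groups: dict[str, list[float]] = {}
    for tp, vals in by_tp.items():
        if not vals:
            continue
        phase = str(tp_phase.loc[type(tp_phase.index[0])(tp)])
        groups.setdefault(phase, []).append(float(np.mean(vals)))
    kw = kruskal_wallis(groups, grouping="phase")
    medians = {k: float(np.median(v)) for k, v in groups.items()}
    return kw, medians


def kruskal_wallis(groups: dict[str, list[float]], grouping: str = "") -> GroupTestResult:
    """Kruskal-Wallis rank sum test with tie correction, plus pairwise
    two-group tests Bonferroni-adjusted across all pairs."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name in names:
        if len(groups[name]) == 0:
            raise ValueError(f"group {name!r} is empty")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*arrays)
    pairs = list(combinations(names, 2))
    pairwise, adjusted = {}, {}
    for a, b in pairs:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            pp = 1.0
        else:
            _, pp = stats.kruskal(xa, xb)
        pairwise[(a, b)] = float(pp)
        adjusted[(a, b)] = float(min(pp * len(pairs), 1.0))
    return GroupTestResult(
        grouping=grouping,
        H=float(H),
        df=len(names) - 1,
        p=float(p),
        pairwise_p=pairwise,
        pairwise_p_adjusted=adjusted,
    )
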