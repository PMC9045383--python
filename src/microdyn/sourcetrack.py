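"""Expectation-maximization microbial source tracking.

Each sink community (a saliva sample) is modelled as a multinomial
mixture over known source communities (air samples) plus one latent
"unknown" source: the sink's taxon distribution is
``sum_k alpha_k beta_k + alpha_u beta_u``. Source distributions
``beta_k`` are fixed at the smoothed source relative abundances.

Estimating the unknown distribution ``beta_u`` jointly and without
constraint is degenerate: ``alpha_u = 1`` with ``beta_u`` equal to the
empirical sink composition is always the global likelihood optimum, so a
fully flexible unknown slowly absorbs the known sources. The estimator
therefore proceeds in two stages, both deterministic:

1. fit the mixing proportions by EM with the unknown held at the uniform
   distribution, and form the sink's *excess* composition — the observed
   taxon fractions minus the fitted known-source mixture, thresholded at
   one standard deviation of multinomial sampling noise;
2. fix ``beta_u`` at that normalized excess (uniform if there is none)
   and re-fit the proportions by EM, which is then a well-posed convex
   mixture fit.

Each stage is a proper EM whose observed-data log-likelihood is
nondecreasing at every iteration (asserted at run time); the reported
trace is that of the final stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable, TaxonomyMap, aggregate_to_rank

logger = logging.getLogger(__name__)


@dataclass
class SourceEstimate:
    sink_id: str
    source_names: list[str]         # known sources then "unknown"
    proportions: np.ndarray         # alpha_k, sums to 1
    log_likelihood: list[float]
    iterations: int
    converged: bool


def _em_proportions(
    x: np.ndarray, B: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, list[float], int, bool]:
    """EM for mixing proportions with all component distributions fixed.

    Starts from uniform proportions; stops when ``max |delta alpha| < tol``.
    """
    n_comp = B.shape[0]
    alpha = np.full(n_comp, 1.0 / n_comp)
    total = x.sum()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = np.maximum(alpha @ B, 1e-300)
        ll = float(np.sum(x * np.log(mix)))
        if trace:
            # EM guarantee; tiny negative drift only from float rounding
            assert ll >= trace[-1] - 1e-8 * max(1.0, abs(trace[-1])), (
                "log-likelihood decreased during EM"
            )
        trace.append(ll)
        resp = (alpha[:, None] * B) / mix[None, :]
        new_alpha = (resp * x[None, :]).sum(axis=1) / total
        delta = np.max(np.abs(new_alpha - alpha))
        alpha = new_alpha
        if delta < tol:
            converged = True
            break
    return alpha, trace, it, converged


def em_source_track(
    sink,
    sources,
    source_names: list[str] | None = None,
    sink_id: str = "",
    max_iter: int = 1000,
    tol: float = 1e-6,
    pseudocount: float = 1.0,
    residual_z: float = 1.0,
) -> SourceEstimate:
    """Estimate mixing proportions of ``sink`` over ``sources`` + unknown.

    ``sink`` is a count vector; ``sources`` an (n_sources, n_taxa) count
    array aligned to the same taxa. ``residual_z`` is the noise threshold
    (in multinomial standard deviations) applied when extracting the
    unknown community from the stage-1 residual.
    """
    x = np.asarray(sink, dtype=float)
    S = np.atleast_2d(np.asarray(sources, dtype=float))
    if S.shape[1] != x.shape[0]:
        raise ValueError(
            f"taxa mismatch: sink has {x.shape[0]}, sources have {S.shape[1]}"
        )
    if x.sum() <= 0:
        raise ValueError("sink has zero total count")
    if (S.sum(axis=1) <= 0).any():
        raise ValueError("a source has zero total count")
    n_src, n_taxa = S.shape
    names = list(source_names) if source_names else [f"source{k+1}" for k in range(n_src)]
    if len(names) != n_src:
        raise ValueError("source_names length mismatch")
    names = names + ["unknown"]

    beta = (S + pseudocount) / (S + pseudocount).sum(axis=1, keepdims=True)
    uniform = np.full(n_taxa, 1.0 / n_taxa)
    total = x.sum()
    p = x / total

    # stage 1: uniform unknown; extract the noise-thresholded excess
    alpha1, _, it1, _ = _em_proportions(
        x, np.vstack([beta, uniform]), max_iter, tol
    )
    fitted = alpha1[:-1] @ beta
    residual = np.maximum(p - fitted - residual_z * np.sqrt(fitted / total), 0.0)
    if residual.sum() > 1e-9:
        beta_u = residual / residual.sum()
    else:
        beta_u = uniform

    # stage 2: unknown fixed at the excess community; convex refit
    alpha, trace, it2, converged = _em_proportions(
        x, np.vstack([beta, beta_u]), max_iter, tol
    )
    if not converged:
        logger.warning(
            "EM did not converge in %d iterations (sink %r)", max_iter, sink_id
        )
    return SourceEstimate(
        sink_id=sink_id,
        source_names=names,
        proportions=alpha,
        log_likelihood=trace,
        iterations=it1 + it2,
        converged=converged,
    )


def attribute_cohort(
    counts: pd.DataFrame,
    source_ids: list[str],
    sink_ids: list[str],
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[list[SourceEstimate], pd.Series]:
    """Per-sink source attribution over a shared count table.

    ``counts`` is taxa x samples; ``source_ids`` and ``sink_ids`` must be
    disjoint column sets. Returns the per-sink estimates and the mean
    proportion per source (plus unknown) over all sinks.
    """
    overlap = set(source_ids) & set(sink_ids)
    if overlap:
        raise ValueError(f"source and sink ids overlap: {sorted(overlap)}")
    missing = [s for s in list(source_ids) + list(sink_ids) if s not in counts.columns]
    if missing:
        raise ValueError(f"ids not in table: {missing}")
    S = counts[source_ids].to_numpy(dtype=float).T
    estimates = []
    for sink in sink_ids:
        est = em_source_track(
            counts[sink].to_numpy(dtype=float),
            S,
            source_names=list(source_ids),
            sink_id=sink,
            max_iter=max_iter,
            tol=tol,
        )
        estimates.append(est)
    props = np.stack([e.proportions for e in estimates])
    mean = pd.Series(props.mean(axis=0), index=estimates[0].source_names,
                     name="mean_proportion")
    return estimates, mean


def shared_taxa(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    group_a: list[str],
    group_b: list[str],
    rank: str = "genus",
) -> set[str]:
    """Taxa at ``rank`` detected (count > 0) in at least one sample of
    both groups — the Venn-overlap set between e.g. air and saliva."""
    if not group_a or not group_b:
        raise ValueError("both sample groups must be nonempty")
    agg = aggregate_to_rank(table, taxonomy, rank)
    present_a = agg.counts[group_a].sum(axis=1) > 0
    present_b = agg.counts[group_b].sum(axis=1) > 0
    shared = set(agg.counts.index[present_a & present_b])
    shared.discard("unclassified")
    return shared
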