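"""Reference-community normalization for longitudinal compositional data.

Per-sample fractional abundances are compositional: a bloom of a single
taxon at one time point deflates every other taxon's fraction at that time
point even though their absolute loads did not change, creating spurious
anti-correlations along the series. The remedy implemented here rescales
each time point toward a reference community built from the *other* time
points with a similar community structure:

(i)   each time point is normalized so fractional abundances sum to 1;
(ii)  highly abundant OTUs are selected, by descending median fractional
      abundance, until they account for 90% of the median time-point reads;
(iii) for each focal time point, every other time point gets weight
      ``(1 - j)^2`` with ``j`` the Jensen-Shannon distance (base-2 logs,
      hence in [0, 1]) between the two abundant-OTU subcompositions; the
      reference value of each abundant OTU is the weighted median of its
      fractions over the other time points, and the focal time point is
      multiplied by the median reference/observed ratio over abundant OTUs
      present at that time point.

A constant series is a fixed point of the procedure (all scale factors 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .io import OtuTable

_SUM_TOL = 1e-9


@dataclass
class NormalizedSeries:
    """One subject's reference-normalized time x OTU abundance series."""

    subject: str
    abundances: pd.DataFrame        # time points x OTUs, post step (iii)
    abundant_otus: list[str]
    scale_factors: pd.Series        # per time point, step (iii) multiplier
    reference: pd.DataFrame         # time points x abundant OTUs


def fractional_normalize(table: OtuTable, subject: str) -> pd.DataFrame:
    """Step (i): per-time-point fractional abundances for one subject.

    Returns a time x OTU DataFrame (rows indexed by time point, ordered)
    whose rows sum to 1.
    """
    meta = table.samples_for(subject)
    if len(meta) < 2:
        raise ValueError(f"subject {subject!r} has fewer than 2 time points")
    counts = table.counts[meta.index].T.astype(float)
    totals = counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)}")
    frac = counts.div(totals, axis=0)
    frac.index = pd.Index(meta["time_point"], name="time_point")
    return frac


def select_abundant_otus(fractions: pd.DataFrame, threshold: float = 0.90) -> list[str]:
    """Step (ii): smallest prefix of OTUs (by descending median fraction)
    whose medians cumulatively reach ``threshold`` of the summed medians."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if fractions.empty:
        raise ValueError("empty abundance table")
    medians = fractions.median(axis=0).sort_values(ascending=False, kind="stable")
    total = medians.sum()
    if total <= 0:
        raise ValueError("all median abundances are zero")
    cum = medians.cumsum() / total
    # index of the first OTU at which the cumulative share reaches threshold
    k = int(np.searchsorted(cum.to_numpy(), threshold - _SUM_TOL)) + 1
    selected = medians.iloc[:k]
    if threshold == 1.0:
        selected = medians[medians > 0]
    return list(selected.index)


def jsd(p, q) -> float:
    """Jensen-Shannon distance (sqrt of the divergence, base-2 logs).

    Bounded in [0, 1]; 0 iff the compositions are identical.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-d arrays of equal length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("compositions must be nonnegative")
    if abs(p.sum() - 1.0) > _SUM_TOL or abs(q.sum() - 1.0) > _SUM_TOL:
        raise ValueError("compositions must each sum to 1")
    d = float(jensenshannon(p, q, base=2))
    # guard scipy's sqrt of tiny negative rounding
    return min(max(d, 0.0), 1.0) if np.isfinite(d) else 0.0


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape or values.ndim != 1 or len(values) == 0:
        raise ValueError("values and weights must be equal-length 1-d arrays")
    if (weights < 0).any():
        raise ValueError("weights must be >= 0")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(values[order][min(idx, len(values) - 1)])


def reference_normalize(
    fractions: pd.DataFrame, abundant: list[str]
) -> NormalizedSeries:
    """Step (iii): rescale each time point toward its JSD-weighted reference.

    For the focal time point ``t``, every other time point ``u`` receives
    weight ``(1 - jsd(t, u))^2`` computed on the renormalized abundant-OTU
    subcompositions; the reference value of each abundant OTU is the
    weighted median of its fractions over ``u != t``; and all OTU fractions
    at ``t`` are multiplied by the median reference/observed ratio over
    abundant OTUs with nonzero observed fraction at ``t``.
    """
    if len(fractions) < 3:
        raise ValueError("reference normalization needs at least 3 time points")
    missing = [o for o in abundant if o not in fractions.columns]
    if missing:
        raise ValueError(f"abundant OTUs not in table: {missing}")
    if not abundant:
        raise ValueError("abundant OTU set is empty")

    sub = fractions[abundant].to_numpy(dtype=float)
    row_sums = sub.sum(axis=1)
    if (row_sums <= 0).any():
        bad = fractions.index[row_sums <= 0].tolist()
        raise ValueError(f"all abundant OTUs zero at time points {bad}")
    comp = sub / row_sums[:, None]

    T = len(fractions)
    scale = np.ones(T)
    reference = np.zeros_like(sub)
    for t in range(T):
        others = [u for u in range(T) if u != t]
        w = np.array([(1.0 - jsd(comp[t], comp[u])) ** 2 for u in others])
        if w.sum() <= 0:
            # every other time point is maximally dissimilar; fall back to
            # equal weights so the reference stays defined
            w = np.ones(len(others))
        ref_t = np.array(
            [weighted_median(sub[others, k], w) for k in range(len(abundant))]
        )
        reference[t] = ref_t
        observed = sub[t]
        nz = observed > 0
        if not nz.any():
            raise ValueError(f"all abundant OTUs zero at time point {fractions.index[t]}")
        ratios = ref_t[nz] / observed[nz]
        scale[t] = float(np.median(ratios))

    normalized = fractions.mul(pd.Series(scale, index=fractions.index), axis=0)
    subject = getattr(fractions, "subject", "")
    return NormalizedSeries(
        subject=subject,
        abundances=normalized,
        abundant_otus=list(abundant),
        scale_factors=pd.Series(scale, index=fractions.index, name="scale_factor"),
        reference=pd.DataFrame(reference, index=fractions.index, columns=abundant),
    )


def normalize_subject(
    table: OtuTable, subject: str, threshold: float = 0.90
) -> NormalizedSeries:
    """Full three-step normalization for one subject."""
    frac = fractional_normalize(table, subject)
    abundant = select_abundant_otus(frac, threshold=threshold)
    result = reference_normalize(frac, abundant)
    result.subject = subject
    return result
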