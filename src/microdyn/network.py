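"""Genus-cytokine co-occurrence networks inside the enclosure.

For one subject's inside-phase samples: genera are filtered to mean
relative abundance above a threshold (default 1%), every pair among
{genera} U {cytokines} is rank-correlated (Spearman), and edges with
``|rho|`` at or above the threshold (default 0.5) are kept. Raw p-values
come from the t-approximation on n-2 df; Benjamini-Hochberg q-values are
attached across all tested pairs, and an edge is flagged significant when
its raw p <= 0.05 (the q-value is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CytokineTable, OtuTable, TaxonomyMap, aggregate_to_rank


@dataclass
class CoNetwork:
    subject: str
    nodes: pd.DataFrame   # index: node id; columns: kind, mean_level
    edges: pd.DataFrame   # node_a, node_b, rho, p, q, sign, significant
    rho_threshold: float


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation on average ranks with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def build_network(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    cytokines: CytokineTable,
    subject: str,
    abundance_threshold: float = 0.01,
    rho_threshold: float = 0.5,
) -> CoNetwork:
    """Co-occurrence network for one subject's inside-enclosure samples."""
    meta = table.samples_for(subject)
    inside = meta[meta["environment"] == "inside"]
    samples = [s for s in inside.index if s in cytokines.values.index]
    if len(samples) < 4:
        raise ValueError(
            f"subject {subject!r} has fewer than 4 inside-phase samples with cytokines"
        )
    genus_table = aggregate_to_rank(table, taxonomy, "genus")
    frac = genus_table.fractions()[samples]
    frac = frac.drop(index="unclassified", errors="ignore")
    mean_abund = frac.mean(axis=1)
    genera = mean_abund[mean_abund > abundance_threshold].index.tolist()
    if not genera:
        raise ValueError(
            f"no genus exceeds mean relative abundance {abundance_threshold}"
        )
    cyto = cytokines.values.loc[samples]

    series: dict[str, np.ndarray] = {g: frac.loc[g].to_numpy() for g in genera}
    series.update({c: cyto[c].to_numpy() for c in cyto.columns})
    kinds = {g: "genus" for g in genera}
    kinds.update({c: "cytokine" for c in cyto.columns})

    rows = []
    for a, b in combinations(series, 2):
        if np.ptp(series[a]) == 0 or np.ptp(series[b]) == 0:
            continue
        rho, p = spearman(series[a], series[b])
        rows.append({"node_a": a, "node_b": b, "rho": rho, "p": p})
    all_pairs = pd.DataFrame(rows)
    all_pairs["q"] = fdr_adjust(all_pairs["p"].to_numpy())
    edges = all_pairs[all_pairs["rho"].abs() >= rho_threshold].copy()
    edges["sign"] = np.sign(edges["rho"]).astype(int)
    edges["significant"] = edges["p"] <= 0.05
    edges = edges.reset_index(drop=True)

    nodes = pd.DataFrame(
        {
            "kind": pd.Series(kinds),
            "mean_level": pd.Series(
                {n: float(np.mean(series[n])) for n in series}
            ),
        }
    )
    nodes.index.name = "node"
    return CoNetwork(
        subject=subject, nodes=nodes, edges=edges, rho_threshold=rho_threshold
    )
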