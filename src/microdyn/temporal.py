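"""Stationarity and trend assessment for short ecological time series.

Two complementary checks mirror the study design: the sample
autocorrelation function (ACF) probes whether a series behaves like a
stationary stochastic process (ACF depending only on the lag, staying
inside the white-noise band), and the Mann-Kendall test asks whether a
monotone trend is present over a contiguous window, without assuming any
distributional form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.tsa.stattools import acf as _sm_acf

from .io import OtuTable


@dataclass
class AcfResult:
    series_id: str
    lags: np.ndarray
    acf: np.ndarray               # autocorrelation at lags 0..max_lag
    bound: float                  # two-sided white-noise band +-z_{0.975}/sqrt(n)
    n_significant_lags: int       # lags 1..max_lag outside the band
    stationary_verdict: bool


@dataclass
class TrendResult:
    series_id: str
    S: int
    varS: float
    Z: float
    p: float
    direction: str                # increasing / decreasing / none


def acf(series, max_lag: int, series_id: str = "") -> AcfResult:
    """Sample ACF with the biased (denominator-n) estimator.

    The white-noise significance band is ``+-1.96/sqrt(n)``; the series is
    called stationary when at most 5% of lags 1..max_lag fall outside it.
    """
    x = np.asarray(series, dtype=float)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    n = len(x)
    if n < max_lag + 2:
        raise ValueError(f"series length {n} too short for max_lag={max_lag}")
    if np.ptp(x) == 0:
        raise ValueError("constant series has undefined autocorrelation")
    vals = _sm_acf(x, nlags=max_lag, adjusted=False, fft=False)
    bound = float(norm.ppf(0.975) / np.sqrt(n))
    n_sig = int(np.sum(np.abs(vals[1:]) > bound))
    verdict = n_sig <= 0.05 * max_lag
    return AcfResult(
        series_id=series_id,
        lags=np.arange(max_lag + 1),
        acf=vals,
        bound=bound,
        n_significant_lags=n_sig,
        stationary_verdict=bool(verdict),
    )


def mann_kendall(series, series_id: str = "") -> TrendResult:
    """Mann-Kendall trend test with tie correction and continuity correction.

    ``S = sum_{i<j} sign(x_j - x_i)``;
    ``var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18`` over tie groups
    of size ``t``; ``Z = (S -+ 1)/sqrt(var(S))`` with the sign-matched
    continuity correction; two-sided normal p-value. The direction is the
    sign of S (none when S = 0).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Mann-Kendall test needs at least 4 observations")
    diff_signs = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff_signs, k=1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))
    varS = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if varS <= 0:
        Z = 0.0
    elif S > 0:
        Z = (S - 1) / np.sqrt(varS)
    elif S < 0:
        Z = (S + 1) / np.sqrt(varS)
    else:
        Z = 0.0
    p = float(2.0 * norm.sf(abs(Z)))
    direction = "increasing" if S > 0 else "decreasing" if S < 0 else "none"
    return TrendResult(series_id=series_id, S=S, varS=float(varS), Z=float(Z),
                       p=min(p, 1.0), direction=direction)


def select_core_otus(table: OtuTable, subject: str) -> list[str]:
    """OTUs present (count > 0) at strictly more than half of the
    subject's time points."""
    meta = table.samples_for(subject)
    if len(meta) < 2:
        raise ValueError(f"subject {subject!r} has fewer than 2 time points")
    counts = table.counts[meta.index]
    present = (counts > 0).sum(axis=1)
    core = present[present > len(meta) / 2.0]
    return list(core.index)


def horizon_transform(series):
    """Mean-center a series and band it by its mean absolute deviation.

    Returns ``(centered, band_width, band_index, sign)`` where the band
    index of each point is ``ceil(|centered| / band_width)`` (0 at the
    mean) and the sign marks above/below the mean — the data transform
    behind horizon graphs of abundance variation.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("series must have at least 2 points")
    centered = x - x.mean()
    width = float(np.abs(centered).mean())
    if width == 0:
        raise ValueError("constant series has zero mean absolute deviation")
    band_index = np.ceil(np.abs(centered) / width - 1e-12).astype(int)
    return centered, width, band_index, np.sign(centered).astype(int)


def trend_table(
    abundances: pd.DataFrame, window: tuple | None = None
) -> pd.DataFrame:
    """Mann-Kendall results for every column of a time x series table.

    ``window`` restricts to the contiguous run of time points (inclusive
    endpoints on the index) — e.g. the outside-to-inside span.
    """
    data = abundances
    if window is not None:
        lo, hi = window
        data = data.loc[(data.index >= lo) & (data.index <= hi)]
    rows = []
    for col in data.columns:
        res = mann_kendall(data[col].to_numpy(), series_id=str(col))
        rows.append(
            {"series": res.series_id, "S": res.S, "varS": res.varS,
             "Z": res.Z, "p": res.p, "direction": res.direction}
        )
    return pd.DataFrame(rows).set_index("series")
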