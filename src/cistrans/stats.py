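"""Shared statistical primitives used across the pipeline.

Thin, well-specified wrappers around scipy/statsmodels routines plus the
resampling machinery (add-one empirical p-values) that several modules share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EmpiricalTestResult",
    "bh_adjust",
    "hypergeom_upper",
    "pearson_with_p",
    "pearson_columns",
    "bootstrap_set_statistic",
]


@dataclass
class EmpiricalTestResult:
    """Observed statistic, its resampled null, and the add-one empirical p.

    p_empirical = (1 + #{null >= observed}) / (1 + n_resamples) for an
    upper-tail test, which can never be exactly zero.
    """

    observed_stat: float
    null_stats: np.ndarray
    n_resamples: int
    p_empirical: float
    seed: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_empirical <= 1.0):
            raise ValueError("empirical p must lie in (0, 1]")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper(k: int, n_universe: int, n_successes: int, n_draws: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in ``n_draws`` draws without replacement from a
    universe of ``n_universe`` items containing ``n_successes`` successes.
    """
    if n_successes > n_universe or n_draws > n_universe:
        raise ValueError("successes and draws must not exceed the universe size")
    return float(sps.hypergeom.sf(k - 1, n_universe, n_successes, n_draws))


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided t-distribution p-value."""
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def pearson_columns(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r (and two-sided p) of a vector against every column of a matrix.

    Vectorized equivalent of looping scipy.stats.pearsonr over columns.
    Columns with zero variance yield NaN.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = x.shape[0]
    if Y.shape[0] != n:
        raise ValueError("x and Y must share the sample dimension")
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return r, p


def bootstrap_set_statistic(
    values: np.ndarray,
    set_size: int,
    observed: float,
    n_resamples: int,
    seed: int,
    chunk: int = 2_000_000,
) -> EmpiricalTestResult:
    """Upper-tail empirical p for a mean statistic of a gene set.

    The null is built by random sampling *with replacement* of ``set_size``
    values from ``values`` (the full universe), ``n_resamples`` times; the
    null statistic is the mean of each resample. Resamples are drawn in
    chunks to bound memory.
    """
    values = np.asarray(values, dtype=float)
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_resamples, dtype=float)
    rows_per_chunk = max(1, chunk // set_size)
    done = 0
    while done < n_resamples:
        m = min(rows_per_chunk, n_resamples - done)
        idx = rng.integers(0, values.size, size=(m, set_size))
        nulls[done : done + m] = values[idx].mean(axis=1)
        done += m
    b = int(np.sum(nulls >= observed))
    p = (1.0 + b) / (1.0 + n_resamples)
    return EmpiricalTestResult(
        observed_stat=float(observed),
        null_stats=nulls,
        n_resamples=n_resamples,
        p_empirical=p,
        seed=seed,
    )
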