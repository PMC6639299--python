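"""Unsupervised patient clustering and group comparison.

Patients are clustered into two groups by rank-2 non-negative matrix
factorization (NMF) of the min-max-scaled patient x feature matrix, using
multiplicative Frobenius updates with random restarts.  Cluster/stage
association uses Pearson's chi-squared test; survival differences between
groups use Kaplan-Meier curves and the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

_EPS = 1e-12


@dataclass
class NMFClustering:
    W: np.ndarray
    H: np.ndarray
    rank: int
    assignments: pd.Series          # patient_id -> {1, 2}
    reconstruction_error: float
    error_history: list
    seed: int


@dataclass
class KMCurve:
    times: np.ndarray               # event/censoring time grid
    survival: np.ndarray            # product-limit estimates
    at_risk: np.ndarray
    censor_times: np.ndarray


def minmax_scale_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature min-max scaling to [0, 1]; constant features map to 0."""
    lo = matrix.min(axis=0)
    span = matrix.max(axis=0) - lo
    span = span.replace(0, 1.0)
    return (matrix - lo) / span


def _mu_nmf(v: np.ndarray, rank: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list]:
    """Multiplicative-update NMF for the Frobenius objective.

    The Frobenius error is tracked each iteration; the update rule makes it
    non-increasing, which callers may assert against ``history``.
    """
    n, m = v.shape
    scale = np.sqrt(v.mean() / rank + _EPS)
    w = scale * rng.random((n, rank)) + _EPS
    h = scale * rng.random((rank, m)) + _EPS
    history = [float(np.linalg.norm(v - w @ h))]
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + _EPS)
        w *= (v @ h.T) / (w @ h @ h.T + _EPS)
        err = float(np.linalg.norm(v - w @ h))
        history.append(err)
        prev = history[-2]
        if prev > 0 and (prev - err) / prev < tol:
            break
    return w, h, history


def nmf_cluster(matrix: pd.DataFrame, rank: int = 2, seed: int = 0,
                n_restarts: int = 20, max_iter: int = 500,
                tol: float = 1e-6) -> NMFClustering:
    """Best-of-restarts NMF with hard assignment by dominant basis column.

    ``matrix`` must already be elementwise nonnegative (use
    :func:`minmax_scale_features`); rows of all zeros are rejected because
    their assignment would be arbitrary.
    """
    v = matrix.to_numpy(dtype=float)
    if np.any(v < 0):
        raise ValueError("NMF input must be elementwise nonnegative")
    if np.any(v.sum(axis=1) == 0):
        raise ValueError("NMF input contains all-zero rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        w, h, history = _mu_nmf(v, rank, rng, max_iter, tol)
        if best is None or history[-1] < best[2][-1]:
            best = (w, h, history)
    w, h, history = best
    # fix component scale so argmax comparisons are meaningful
    norms = np.linalg.norm(h, axis=1) + _EPS
    w = w * norms
    h = h / norms[:, None]
    labels = np.argmax(w, axis=1) + 1
    assignments = pd.Series(labels, index=matrix.index, name="cluster")
    return NMFClustering(W=w, H=h, rank=rank, assignments=assignments,
                         reconstruction_error=history[-1],
                         error_history=history, seed=seed)


def chi_squared_association(assignments, labels) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) on the contingency
    table of cluster assignment vs a categorical label."""
    table = pd.crosstab(pd.Series(list(assignments)),
                        pd.Series(list(labels)))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 nonempty categories on each side")
    stat, p, dof, expected = stats.chi2_contingency(table.to_numpy(),
                                                    correction=False)
    if np.any(expected == 0):
        raise ValueError("zero expected count; merge sparse categories")
    return float(stat), int(dof), float(p)


def kaplan_meier(times, events) -> KMCurve:
    """Product-limit survival estimate for one group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk,
                   censor_times=np.sort(times[events == 0]))


def log_rank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank chi-squared statistic (1 df) and p-value."""
    events_a = np.asarray(events_a, int)
    events_b = np.asarray(events_b, int)
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    res = logrank_test(times_a, times_b, event_observed_A=events_a,
                       event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)
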