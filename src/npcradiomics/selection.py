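"""Primary feature selection.

Two screens run in sequence on the training cohort:

1. contour reproducibility -- features must achieve an intraclass
   correlation ICC(2,1) strictly above a threshold (default 0.8) between the
   two raters' extractions on the dual-contoured subset;
2. redundancy -- greedy pairwise-correlation elimination (the caret
   ``findCorrelation`` algorithm) with an absolute-correlation cutoff
   (default 0.5) on the survivors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ICCResult:
    feature_name: str
    icc2: float
    n_subjects: int
    n_raters: int = 2


@dataclass
class SelectionReport:
    kept_features: list = field(default_factory=list)
    dropped_by_icc: list = field(default_factory=list)
    dropped_by_correlation: list = field(default_factory=list)
    icc_threshold: float = 0.8
    corr_cutoff: float = 0.5
    icc_values: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(asdict(self), indent=2))
        return Path(path)


def icc2(ratings: np.ndarray, feature_name: str = "") -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)) with the
    subject mean squares MS_R, rater mean squares MS_C and residual MS_E of
    the two-way ANOVA.  All-identical ratings give ICC = 1 by convention.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("ratings must be an (n_subjects, 2) matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be finite")
    grand = x.mean()
    if np.allclose(x, grand):
        return ICCResult(feature_name, 1.0, n, k)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_cols = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0:
        return ICCResult(feature_name, 1.0 if ms_r == ms_e else 0.0, n, k)
    return ICCResult(feature_name, float((ms_r - ms_e) / denom), n, k)


def filter_by_icc(training_features: pd.DataFrame,
                  rater2_features: pd.DataFrame,
                  threshold: float = 0.8) -> SelectionReport:
    """Keep features with ICC(2,1) strictly above ``threshold``.

    ICC is computed on the patients present in both matrices (the
    dual-contoured subset).
    """
    common = training_features.index.intersection(rater2_features.index)
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 dual-contoured subjects, got {len(common)}")
    report = SelectionReport(icc_threshold=threshold)
    for name in training_features.columns:
        if name not in rater2_features.columns:
            raise ValueError(f"rater-2 matrix lacks feature {name!r}")
        ratings = np.column_stack([
            training_features.loc[common, name].to_numpy(float),
            rater2_features.loc[common, name].to_numpy(float),
        ])
        result = icc2(ratings, name)
        report.icc_values[name] = result.icc2
        if result.icc2 > threshold:
            report.kept_features.append(name)
        else:
            report.dropped_by_icc.append(name)
    return report


def find_correlation(corr: np.ndarray | pd.DataFrame,
                     cutoff: float = 0.5) -> list[int]:
    """Greedy elimination of highly correlated features (caret-style).

    Repeatedly take the remaining pair with the largest absolute correlation
    above ``cutoff`` and remove whichever member has the larger mean absolute
    correlation with all other remaining features; at ties the lower index is
    removed.  Returns the removed indices in removal order.
    """
    c = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    a = np.abs(c.copy())
    np.fill_diagonal(a, 0.0)
    active = list(range(c.shape[0]))
    removed: list[int] = []
    while len(active) > 1:
        sub = a[np.ix_(active, active)]
        flat = int(np.argmax(sub))
        i_loc, j_loc = divmod(flat, len(active))
        if sub[i_loc, j_loc] <= cutoff:
            break
        means = sub.sum(axis=1) / (len(active) - 1)
        if means[i_loc] > means[j_loc]:
            drop_loc = i_loc
        elif means[j_loc] > means[i_loc]:
            drop_loc = j_loc
        else:
            drop_loc = min(i_loc, j_loc)
        removed.append(active.pop(drop_loc))
    return removed


def primary_selection(feature_matrix: pd.DataFrame,
                      rater2_matrix: pd.DataFrame,
                      icc_threshold: float = 0.8,
                      corr_cutoff: float = 0.5) -> SelectionReport:
    """ICC screen, then Pearson-correlation redundancy screen.

    The correlation screen uses training-cohort values only (the rows of
    ``feature_matrix``).  Constant surviving columns are assigned zero
    correlation with everything so they are never eliminated here.
    """
    report = filter_by_icc(feature_matrix, rater2_matrix, icc_threshold)
    report.corr_cutoff = corr_cutoff
    survivors = report.kept_features
    if survivors:
        sub = feature_matrix[survivors]
        corr = sub.corr(method="pearson").fillna(0.0)
        np.fill_diagonal(corr.values, 1.0)
        removed = find_correlation(corr, corr_cutoff)
        dropped = [survivors[i] for i in removed]
        report.dropped_by_correlation = dropped
        report.kept_features = [f for f in survivors if f not in dropped]
    if not report.kept_features:
        raise ValueError(
            f"primary selection kept zero features; report: {asdict(report)}")
    return report
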