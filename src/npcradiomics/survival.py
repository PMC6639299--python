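"""Prognostic modelling: LASSO-Cox signatures, validation and stratification.

For each endpoint three model families are fitted on the training cohort --
radiomics-only, clinical-only (T stage, N stage, age, sex) and combined.
The L1 penalty weight lambda is chosen by cross-validated partial-likelihood
deviance with the one-standard-error rule (lambda.1se); model discrimination
is summarised by Harrell's concordance index with a bootstrap confidence
interval; risk groups are formed at the training-median risk score.

The penalized path is solved by the glmnet-style coordinate-descent solver
of scikit-survival (Breslow tie handling); cross-validation deviance follows
Verweij & Van Houwelingen: for a model fitted without fold k, the fold's
deviance is -2 [pl(all data) - pl(data without fold k)] evaluated at the
fitted coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

CLINICAL_COVARIATES = ["t_stage", "n_stage", "age", "sex"]
_STAGE_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CoxSignature:
    """A fitted sparse Cox model with frozen training standardization."""

    endpoint: str
    coefficients: dict                  # nonzero only, on standardized scale
    chosen_lambda: float
    lambda_path: np.ndarray
    means: dict                         # training mean per entered covariate
    sds: dict                           # training SD per entered covariate
    entered_covariates: list = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.coefficients) == 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda_path"] = [float(v) for v in self.lambda_path]
        return d


@dataclass
class CIndexResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_comparable_pairs: int


@dataclass
class RiskStratification:
    threshold: float
    group: pd.Series                    # patient_id -> {"high", "low"}


@dataclass
class LambdaSelection:
    lambda_1se: float
    lambda_min: float
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    n_folds_used: int


@dataclass
class NomogramTable:
    """Linear points mapping: the covariate with the widest linear-predictor
    span gets 0-100 points; total points map affinely to the risk score."""

    rows: pd.DataFrame                  # per covariate: coef, lo, hi, points span
    slope: float                        # risk = slope * total_points + intercept
    intercept: float

    def total_points(self, covariates: dict) -> float:
        pts = 0.0
        for _, row in self.rows.iterrows():
            contrib = row["coef_std"] * ((covariates[row["covariate"]]
                                          - row["mean"]) / row["sd"])
            pts += (contrib - row["min_contribution"]) / self.slope_unit * 100
        return pts

    @property
    def slope_unit(self) -> float:
        return float(self.rows["span"].max())

    def risk_from_points(self, total_points: float) -> float:
        return self.slope * total_points + self.intercept


# ---------------------------------------------------------------------------
# Standardization and the partial likelihood
# ---------------------------------------------------------------------------

def standardize(train: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score using training statistics; constant columns get SD 1."""
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=0).replace(0, 1.0)
    return (train - means) / sds, means, sds


def apply_standardization(x: pd.DataFrame, means: pd.Series,
                          sds: pd.Series) -> pd.DataFrame:
    return (x[means.index] - means) / sds


def _loglik_path(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                 betas: np.ndarray) -> np.ndarray:
    """Breslow partial log-likelihood at each column of ``betas`` (p, L)."""
    eta = x @ betas                                   # (n, L)
    order = np.argsort(time, kind="stable")
    t, e, eta_o = time[order], event[order], eta[order]
    # cumulative sum of exp(eta) over the risk set {j : t_j >= t_i}
    rev = np.cumsum(np.exp(eta_o)[::-1], axis=0)[::-1]
    ll = np.zeros(betas.shape[1])
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].astype(bool)
        if d.any():
            ll += eta_o[i:j][d].sum(axis=0) - d.sum() * np.log(rev[i])
        i = j
    return ll


def cox_partial_loglik(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                       beta: np.ndarray) -> float:
    """Breslow partial log-likelihood at coefficients ``beta``."""
    return float(_loglik_path(np.asarray(x, float), np.asarray(time, float),
                              np.asarray(event, int),
                              np.asarray(beta, float)[:, None])[0])


# ---------------------------------------------------------------------------
# Penalized path and lambda selection
# ---------------------------------------------------------------------------

@dataclass
class CoxPath:
    lambdas: np.ndarray                 # decreasing
    coefs: np.ndarray                   # (n_features, n_lambdas)
    feature_names: list

    def n_nonzero(self) -> np.ndarray:
        return (self.coefs != 0).sum(axis=0)


def _check_survival_inputs(x: pd.DataFrame, time: np.ndarray,
                           event: np.ndarray) -> None:
    if event.sum() == 0:
        raise ValueError("no events in survival data")
    if not np.all(np.isfinite(x.to_numpy(float))):
        raise ValueError("non-finite covariates")


def fit_lasso_cox(x: pd.DataFrame, time, event,
                  lambda_grid: Sequence[float] | None = None,
                  n_lambdas: int = 50) -> CoxPath:
    """L1-penalized Cox coefficient path (covariates assumed standardized).

    With ``lambda_grid=None`` the grid is log-spaced downward from the
    smallest lambda at which every coefficient is exactly zero.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    _check_survival_inputs(x, time, event)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    kwargs = dict(l1_ratio=1.0, tol=1e-9, max_iter=100000)
    if lambda_grid is None:
        model = CoxnetSurvivalAnalysis(n_alphas=n_lambdas,
                                       alpha_min_ratio=0.01, **kwargs)
    else:
        grid = np.sort(np.asarray(lambda_grid, float))[::-1]
        model = CoxnetSurvivalAnalysis(alphas=grid, **kwargs)
    model.fit(x.to_numpy(float), y)
    return CoxPath(lambdas=np.asarray(model.alphas_),
                   coefs=np.asarray(model.coef_),
                   feature_names=list(x.columns))


def coefficients_at(x: pd.DataFrame, time, event, lam: float) -> pd.Series:
    """Refit the penalized model at one lambda; returns all coefficients."""
    path = fit_lasso_cox(x, time, event, lambda_grid=[lam])
    return pd.Series(path.coefs[:, 0], index=path.feature_names)


def select_lambda(x: pd.DataFrame, time, event,
                  folds: str | int = "loocv", seed: int = 0,
                  lambda_grid: Sequence[float] | None = None,
                  ) -> LambdaSelection:
    """Cross-validated deviance curve and the lambda.1se rule.

    ``folds`` is ``"loocv"`` or an integer k (stratified on event status).
    lambda.1se is the largest lambda whose mean CV deviance is within one
    standard error of the minimum mean deviance.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    _check_survival_inputs(x, time, event)
    if lambda_grid is None:
        lambda_grid = fit_lasso_cox(x, time, event).lambdas
    grid = np.sort(np.asarray(lambda_grid, float))[::-1]
    xa = x.to_numpy(float)
    n = len(time)

    if folds == "loocv":
        fold_indices = [np.array([i]) for i in range(n)]
    else:
        k = int(folds)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_indices = [test for _, test in skf.split(xa, event)]

    ll_full_cache: dict[int, float] = {}
    fold_devs = []
    for test_idx in fold_indices:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if event[train_mask].sum() == 0:
            warnings.warn("skipping CV fold with no training events")
            continue
        try:
            path = fit_lasso_cox(x.iloc[train_mask], time[train_mask],
                                 event[train_mask], lambda_grid=grid)
        except (ValueError, ArithmeticError) as exc:
            warnings.warn(f"skipping CV fold: {exc}")
            continue
        # coxnet may return fewer lambdas than requested; map each grid
        # lambda to the nearest fitted one (the path is continuous)
        col = np.array([int(np.argmin(np.abs(np.log(path.lambdas) -
                                             np.log(lam))))
                        for lam in grid])
        betas = path.coefs[:, col]
        ll_all = _loglik_path(xa, time, event, betas)
        ll_train = _loglik_path(xa[train_mask], time[train_mask],
                                event[train_mask], betas)
        fold_devs.append(-2.0 * (ll_all - ll_train))
    if not fold_devs:
        raise ValueError("all CV folds were skipped")
    dev = np.vstack(fold_devs)
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(dev.shape[0]) \
        if dev.shape[0] > 1 else np.zeros(len(grid))
    i_min = int(np.argmin(mean))
    threshold = mean[i_min] + se[i_min]
    # grid is decreasing, so the first qualifying index is the largest lambda
    i_1se = int(np.argmax(mean <= threshold))
    return LambdaSelection(lambda_1se=float(grid[i_1se]),
                           lambda_min=float(grid[i_min]),
                           lambdas=grid, mean_deviance=mean,
                           se_deviance=se, n_folds_used=dev.shape[0])


def build_signature(x_train: pd.DataFrame, time, event, endpoint: str,
                    folds: str | int = "loocv", seed: int = 0,
                    ) -> CoxSignature:
    """Standardize, fit the path, pick lambda.1se, keep nonzero covariates."""
    z, means, sds = standardize(x_train)
    sel = select_lambda(z, time, event, folds=folds, seed=seed)
    coefs = coefficients_at(z, time, event, sel.lambda_1se)
    nonzero = coefs[coefs != 0]
    return CoxSignature(endpoint=endpoint,
                        coefficients=nonzero.to_dict(),
                        chosen_lambda=sel.lambda_1se,
                        lambda_path=sel.lambdas,
                        means=means.to_dict(), sds=sds.to_dict(),
                        entered_covariates=list(x_train.columns))


# ---------------------------------------------------------------------------
# Scoring, concordance and stratification
# ---------------------------------------------------------------------------

def risk_score(signature: CoxSignature, covariates: pd.DataFrame) -> pd.Series:
    """Cox linear predictor on training-standardized covariates.

    Higher score means higher hazard.  A patient at the training means of
    every signature covariate scores exactly 0.
    """
    scores = np.zeros(len(covariates))
    for name, beta in signature.coefficients.items():
        if name not in covariates.columns:
            raise KeyError(f"missing covariate {name!r}")
        z = ((covariates[name].to_numpy(float) - signature.means[name])
             / signature.sds[name])
        scores += beta * z
    return pd.Series(scores, index=covariates.index, name="risk_score")


def concordance_index(scores, time, event, n_bootstrap: int = 2000,
                      seed: int = 0) -> CIndexResult:
    """Harrell's C with a percentile bootstrap confidence interval.

    Comparable pairs follow the usual censoring rules; score ties are
    credited 0.5.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int).astype(bool)
    c, conc, disc, tied_risk, _ = concordance_index_censored(
        event, time, scores)
    n_pairs = int(conc + disc + tied_risk)
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    rng = np.random.default_rng(seed)
    n = len(scores)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if event[idx].sum() == 0:
            continue
        cb = concordance_index_censored(event[idx], time[idx], scores[idx])
        if cb[1] + cb[2] + cb[3] > 0:
            boots.append(cb[0])
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = c
    return CIndexResult(estimate=float(c), ci_low=float(min(lo, c)),
                        ci_high=float(max(hi, c)),
                        n_comparable_pairs=n_pairs)


def cross_validate_model(x: pd.DataFrame, time, event, k: int = 10,
                         seed: int = 0,
                         fit_fn: Callable | None = None) -> pd.DataFrame:
    """Out-of-sample C-index per fold (folds stratified by event status).

    ``fit_fn(x_train, time, event) -> score_fn`` builds a risk scorer on the
    training part; the default builds a lambda.1se LASSO-Cox signature with
    an inner 5-fold CV.  Folds without comparable pairs are reported as NaN.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if fit_fn is None:
        def fit_fn(xt, tt, et):
            sig = build_signature(xt, tt, et, endpoint="cv", folds=5,
                                  seed=seed)
            if sig.is_empty:
                return lambda xv: pd.Series(0.0, index=xv.index)
            return lambda xv: risk_score(sig, xv)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(x, event)):
        scorer = fit_fn(x.iloc[train_idx], time[train_idx], event[train_idx])
        scores = np.asarray(scorer(x.iloc[test_idx]), float)
        e, t = event[test_idx].astype(bool), time[test_idx]
        if e.sum() == 0:
            c = np.nan
        else:
            cb = concordance_index_censored(e, t, scores)
            c = cb[0] if cb[1] + cb[2] + cb[3] > 0 else np.nan
        rows.append({"fold": fold, "c_index": c,
                     "n_test": len(test_idx), "n_events": int(e.sum())})
    df = pd.DataFrame(rows)
    df.attrs["mean"] = float(np.nanmean(df["c_index"]))
    df.attrs["sd"] = float(np.nanstd(df["c_index"]))
    return df


def stratify(training_scores: pd.Series,
             cohort_scores: pd.Series) -> RiskStratification:
    """High/low risk split at the training-median score (strict >)."""
    if len(training_scores) == 0:
        raise ValueError("training scores are empty")
    if np.ptp(np.asarray(training_scores, float)) == 0:
        raise ValueError("degenerate training scores (all equal)")
    threshold = float(np.median(training_scores))
    group = pd.Series(np.where(cohort_scores > threshold, "high", "low"),
                      index=cohort_scores.index, name="risk_group")
    return RiskStratification(threshold=threshold, group=group)


def nomogram_points(signature: CoxSignature,
                    covariate_ranges: dict) -> NomogramTable:
    """Points table: widest-span covariate maps to 0-100 points."""
    if signature.is_empty:
        raise ValueError("cannot build a nomogram from an empty signature")
    rows = []
    for name, beta in signature.coefficients.items():
        lo, hi = covariate_ranges[name]
        sd = signature.sds[name]
        mean = signature.means[name]
        c_lo = beta * (lo - mean) / sd
        c_hi = beta * (hi - mean) / sd
        rows.append({"covariate": name, "coef_std": beta, "lo": lo, "hi": hi,
                     "mean": mean, "sd": sd,
                     "min_contribution": min(c_lo, c_hi),
                     "span": abs(c_hi - c_lo)})
    table = pd.DataFrame(rows)
    max_span = float(table["span"].max())
    if max_span == 0:
        raise ValueError("all covariate ranges have zero span")
    table["points_at_lo"] = (table.apply(
        lambda r: (r["coef_std"] * (r["lo"] - r["mean"]) / r["sd"]
                   - r["min_contribution"]), axis=1) / max_span * 100)
    table["points_at_hi"] = (table.apply(
        lambda r: (r["coef_std"] * (r["hi"] - r["mean"]) / r["sd"]
                   - r["min_contribution"]), axis=1) / max_span * 100)
    slope = max_span / 100.0
    intercept = float(table["min_contribution"].sum())
    return NomogramTable(rows=table, slope=slope, intercept=intercept)


# ---------------------------------------------------------------------------
# Cohort comparison and the model table
# ---------------------------------------------------------------------------

def encode_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Ordinal/binary encoding of clinical covariates for modelling."""
    out = pd.DataFrame(index=df.index)
    out["t_stage"] = df["t_stage"].astype(float)
    out["n_stage"] = df["n_stage"].astype(float)
    out["age"] = df["age"].astype(float)
    out["sex"] = (df["sex"] == "male").astype(float)
    return out


def compare_cohorts(train: pd.DataFrame,
                    valid: pd.DataFrame) -> pd.DataFrame:
    """Per-feature training vs validation comparison.

    Ordinal/continuous features (age, stages) use the two-sided
    Mann-Whitney U test (U reported for the training sample); sex uses the
    chi-squared test.  Features constant in both cohorts get p = 1.
    """
    rows = []
    ordinals = {"age": lambda d: d["age"].astype(float),
                "t_stage": lambda d: d["t_stage"].astype(float),
                "n_stage": lambda d: d["n_stage"].astype(float),
                "overall_stage": lambda d: d["overall_stage"].map(
                    _STAGE_ORDINAL).astype(float)}
    for name, getter in ordinals.items():
        a, b = getter(train), getter(valid)
        if a.nunique() <= 1 and b.nunique() <= 1 and set(a) == set(b):
            rows.append({"feature": name, "test": "mann-whitney",
                         "statistic": np.nan, "p": 1.0})
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"feature": name, "test": "mann-whitney",
                     "statistic": float(u), "p": float(p)})
    sexes = pd.crosstab(
        pd.Series(["train"] * len(train) + ["valid"] * len(valid)),
        pd.concat([train["sex"], valid["sex"]]).to_numpy())
    if sexes.shape[1] < 2:
        rows.append({"feature": "sex", "test": "chi-squared",
                     "statistic": np.nan, "p": 1.0})
    else:
        s, p, _, _ = stats.chi2_contingency(sexes.to_numpy(),
                                            correction=False)
        rows.append({"feature": "sex", "test": "chi-squared",
                     "statistic": float(s), "p": float(p)})
    return pd.DataFrame(rows)


def run_prognostic_models(feature_train: pd.DataFrame,
                          feature_valid: pd.DataFrame,
                          clinical_train: pd.DataFrame,
                          clinical_valid: pd.DataFrame,
                          survival_frames: dict,
                          kept_features: list,
                          endpoints: Sequence[str] = ("DFS", "OS", "DMFS",
                                                      "LRFS"),
                          folds: str | int = "loocv", seed: int = 0,
                          n_bootstrap: int = 500,
                          ) -> tuple[pd.DataFrame, dict]:
    """Fit radiomics / clinical / combined models for every endpoint.

    Returns the C-index table (one row per endpoint x family, training and
    validation columns) plus the fitted signatures.  A family whose
    lambda.1se model is empty is reported as unavailable (NaN cells).
    """
    clin_tr = encode_clinical(clinical_train)
    clin_va = encode_clinical(clinical_valid)
    designs = {
        "radiomics": (feature_train[kept_features],
                      feature_valid[kept_features]),
        "clinical": (clin_tr, clin_va),
        "combined": (pd.concat([feature_train[kept_features], clin_tr],
                               axis=1),
                     pd.concat([feature_valid[kept_features], clin_va],
                               axis=1)),
    }
    rows = []
    signatures: dict = {}
    for endpoint in endpoints:
        if endpoint not in survival_frames:
            raise ValueError(f"endpoint {endpoint!r} absent from survival data")
        surv = survival_frames[endpoint]
        for family, (x_tr, x_va) in designs.items():
            tr = surv.loc[x_tr.index]
            va = surv.loc[x_va.index]
            sig = build_signature(x_tr, tr["time"].to_numpy(),
                                  tr["event"].to_numpy(), endpoint,
                                  folds=folds, seed=seed)
            signatures[(endpoint, family)] = sig
            row = {"endpoint": endpoint, "family": family,
                   "n_selected": len(sig.coefficients),
                   "available": not sig.is_empty}
            if sig.is_empty:
                for col in ("train_cindex", "train_ci_low", "train_ci_high",
                            "valid_cindex", "valid_ci_low", "valid_ci_high"):
                    row[col] = np.nan
            else:
                for label, x_c, s_c in (("train", x_tr, tr),
                                        ("valid", x_va, va)):
                    res = concordance_index(risk_score(sig, x_c),
                                            s_c["time"], s_c["event"],
                                            n_bootstrap=n_bootstrap,
                                            seed=seed)
                    row[f"{label}_cindex"] = res.estimate
                    row[f"{label}_ci_low"] = res.ci_low
                    row[f"{label}_ci_high"] = res.ci_high
            rows.append(row)
    return pd.DataFrame(rows), signatures
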