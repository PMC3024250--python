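"""Survival analysis for categorized fractal-dimension biomarkers.

Kaplan-Meier estimation, logrank comparison, Cox proportional-hazards
regression (Efron tie handling by default), a log(-log S) proportionality
check, ROC-AUC of Cox-predicted event probabilities at a horizon,
predicted-mean single imputation of missing covariates, and split-sample
cross-validation whose shrinkage coefficient is the difference between
training and validation AUCs.

Estimation is delegated to lifelines (Kaplan-Meier, logrank, Cox partial
likelihood) and scikit-learn (imputation regressions, rank-based AUC); this
module owns the study-specific contracts around them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import ContractError, InsufficientDataError, UndefinedEstimateError

logger = logging.getLogger(__name__)

#: model terms in report order; 'category' expands to intermediate/high
#: dummies against the low reference
FULL_MODEL = (
    "category",
    "age_group",
    "size_group",
    "grade",
    "node_status",
    "er_status",
    "her2_status",
)

_OUTCOME_COLS = {"dss": "dss_event", "os": "os_event"}


@dataclass
class KMCurve:
    """Product-limit survival estimate with a queried horizon value."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    horizon: float
    horizon_estimate: float


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``coefficients`` are log hazard ratios for the non-reference levels; the
    reference level of every categorical covariate has hazard ratio 1 by
    construction and is not listed.
    """

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci95: pd.DataFrame  # columns lower, upper (hazard-ratio scale)
    p_values: pd.Series
    outcome: str
    covariates: tuple[str, ...]
    design_columns: tuple[str, ...]
    _fitter: CoxPHFitter = field(repr=False, default=None)

    def predict_event_probability(self, df: pd.DataFrame, horizon: float) -> np.ndarray:
        """1 - S(horizon | covariates) under this fit's coefficients."""
        design = build_design(df, self.covariates)
        surv = self._fitter.predict_survival_function(
            design[list(self.design_columns)], times=[horizon]
        )
        return 1.0 - surv.iloc[0].to_numpy()


@dataclass
class CVReport:
    """Split-sample cross-validation summary."""

    auc_training: float
    auc_validation: float
    shrinkage: float
    split_seed: int
    n_training: int
    n_validation: int
    generalizable: bool


def km_estimate(
    times: Sequence[float], events: Sequence[int], horizon: float = 10.0
) -> KMCurve:
    """Kaplan-Meier product-limit estimator with S carried to the horizon."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    if times.size == 0:
        raise ContractError("km_estimate requires at least one subject")
    if times.shape != events.shape:
        raise ContractError("times and events must have equal length")
    if np.any(times < 0) or not np.isin(events, (0, 1)).all():
        raise ContractError("times must be >= 0 and events binary")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        times=surv.index.to_numpy(),
        survival=surv.to_numpy(),
        at_risk=table["at_risk"].to_numpy(),
        n_events=table["observed"].to_numpy(),
        horizon=float(horizon),
        horizon_estimate=float(kmf.predict(horizon)),
    )


def logrank(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> tuple[float, float]:
    """Unweighted k-group logrank test (chi-square, k-1 df)."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ContractError("logrank requires at least 2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def build_design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Expand model terms to a numeric design matrix.

    'category' becomes two dummies (category_intermediate, category_high)
    with 'low' as the reference; binary covariates pass through as 0/1.
    """
    cols = {}
    for name in covariates:
        if name == "category":
            cat = df["category"].astype(str)
            cols["category_intermediate"] = (cat == "intermediate").astype(float)
            cols["category_high"] = (cat == "high").astype(float)
        else:
            cols[name] = df[name].astype(float)
    return pd.DataFrame(cols, index=df.index)


def cox_fit(
    df: pd.DataFrame,
    outcome: str = "dss",
    covariates: Sequence[str] = ("category",),
    ties: str = "efron",
) -> CoxFit:
    """Maximum partial-likelihood Cox regression with Wald inference.

    ``outcome`` selects disease-specific ('dss') or overall ('os') survival.
    Efron tie handling is the default; 'breslow' is available for
    comparability with older software.
    """
    if outcome not in _OUTCOME_COLS:
        raise ContractError("outcome must be 'dss' or 'os'")
    if ties != "efron":
        raise NotImplementedError(
            "only Efron tie handling is provided by the partial-likelihood backend"
        )
    event_col = _OUTCOME_COLS[outcome]
    design = build_design(df, covariates)
    if design.isna().any().any():
        raise ContractError(
            "design matrix contains missing values; impute covariates first"
        )
    data = design.copy()
    data["duration"] = df["followup_years"].astype(float)
    data["event"] = df[event_col].astype(int)
    if data["event"].sum() < 1:
        raise InsufficientDataError("no events; Cox model cannot be fit")
    fitter = CoxPHFitter()
    try:
        fitter.fit(
            data,
            duration_col="duration",
            event_col="event",
            show_progress=False,
        )
    except Exception as exc:
        raise UndefinedEstimateError(f"Cox fit failed to converge: {exc}") from exc
    summary = fitter.summary
    ci = pd.DataFrame(
        {
            "lower": np.exp(summary["coef lower 95%"]),
            "upper": np.exp(summary["coef upper 95%"]),
        }
    )
    return CoxFit(
        coefficients=summary["coef"],
        hazard_ratios=np.exp(summary["coef"]),
        ci95=ci,
        p_values=summary["p"],
        outcome=outcome,
        covariates=tuple(covariates),
        design_columns=tuple(design.columns),
        _fitter=fitter,
    )


def check_proportionality(
    df: pd.DataFrame, covariate: str, outcome: str = "dss"
) -> tuple[dict[str, pd.DataFrame], str]:
    """Log-minus-log survival curves per stratum with a crossing heuristic.

    Strata whose curves run parallel on the log(-log S) vs log t plot are
    consistent with proportional hazards. To keep Kaplan-Meier step noise
    from masquerading as a crossing, the pairwise curve difference is
    standardized by its Greenwood variance; the flag is 'suspect' when, after
    the first decile of event times, some pair of strata separates
    significantly (|z| > 2) in BOTH directions over follow-up - i.e. the
    curves demonstrably cross - and 'ok' otherwise.
    """
    event_col = _OUTCOME_COLS[outcome]
    strata = df[covariate].dropna().unique()
    if len(strata) < 2:
        raise ContractError("proportionality check needs >= 2 strata")
    curves: dict[str, pd.DataFrame] = {}
    event_times = df.loc[df[event_col] == 1, "followup_years"].to_numpy()
    if event_times.size == 0:
        raise InsufficientDataError("no events in the data")
    grid = np.unique(event_times)
    t_min = float(np.quantile(event_times, 0.10))
    loglog: dict[str, np.ndarray] = {}
    varlog: dict[str, np.ndarray] = {}
    t_reliable: dict[str, float] = {}
    for level in sorted(strata, key=str):
        sub = df[df[covariate] == level]
        if sub[event_col].sum() == 0:
            logger.warning("stratum %s=%r has no events; omitted", covariate, level)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["followup_years"], sub[event_col])
        s = kmf.predict(grid).to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.log(-np.log(np.clip(s, 1e-12, 1.0 - 1e-12)))
        # Greenwood variance of the cumulative hazard, delta-method to log
        table = kmf.event_table
        with np.errstate(divide="ignore", invalid="ignore"):
            increments = table["observed"] / (
                table["at_risk"] * (table["at_risk"] - table["observed"])
            )
        var_cumhaz = increments.replace(np.inf, np.nan).fillna(0.0).cumsum()
        var_at_grid = (
            var_cumhaz.reindex(
                var_cumhaz.index.union(grid)
            ).ffill().fillna(0.0).reindex(grid).to_numpy(dtype=float)
        )
        cumhaz = -np.log(np.clip(s, 1e-12, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            varlog[str(level)] = var_at_grid / np.maximum(cumhaz, 1e-12) ** 2
        curves[str(level)] = pd.DataFrame(
            {"time": grid, "survival": s, "log_minus_log": y}
        )
        loglog[str(level)] = y
        # last time the stratum still has a meaningful risk set; beyond it
        # the curve is a flat extrapolation and must not enter the comparison
        at_risk = table["at_risk"].to_numpy(dtype=float)
        reliable = table.index.to_numpy(dtype=float)[at_risk >= 5]
        t_reliable[str(level)] = float(reliable.max()) if reliable.size else 0.0
    if len(loglog) < 2:
        raise InsufficientDataError("fewer than 2 strata with events")
    flag = "ok"
    keys = list(loglog)
    after = grid > t_min
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            diff = loglog[keys[i]] - loglog[keys[j]]
            se = np.sqrt(varlog[keys[i]] + varlog[keys[j]])
            with np.errstate(divide="ignore", invalid="ignore"):
                z = diff / se
            window = after & (grid <= min(t_reliable[keys[i]], t_reliable[keys[j]]))
            z = z[window & np.isfinite(z)]
            signif = np.sign(z[np.abs(z) > 2.0])
            if signif.size and signif.min() < 0 < signif.max():
                flag = "suspect"
    return curves, flag


def _mann_whitney_auc(y: np.ndarray, score: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic; tied scores count 1/2."""
    from scipy.stats import rankdata

    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedEstimateError("AUC undefined: outcomes are all one class")
    ranks = rankdata(score)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(
    fit: CoxFit, df: pd.DataFrame, outcome: Optional[str] = None, horizon: float = 10.0
) -> float:
    """AUC of Cox-predicted event probability against observed outcome.

    The score is 1 - S(horizon | covariates) from the fit; the comparative
    standard is the observed event indicator (subjects censored without the
    event count as non-events).
    """
    outcome = outcome or fit.outcome
    y = df[_OUTCOME_COLS[outcome]].astype(int).to_numpy()
    score = fit.predict_event_probability(df, horizon)
    return _mann_whitney_auc(y, score)


def impute_predicted_mean(
    df: pd.DataFrame, variables: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Predicted-mean single imputation of missing covariates.

    For each target variable a regression on the fully observed covariates is
    fit to complete cases (logistic for binary targets, with the predicted
    probability mapped to the nearer category; linear otherwise). Returns the
    completed table and per-variable imputed counts.
    """
    from sklearn.linear_model import LinearRegression, LogisticRegression

    df = df.copy()
    candidate_predictors = [
        c
        for c in df.columns
        if c not in variables
        and df[c].notna().all()
        and pd.api.types.is_numeric_dtype(df[c])
        and c not in ("dss_event", "os_event", "followup_years")
    ]
    log: dict[str, int] = {}
    for var in variables:
        missing = df[var].isna()
        log[var] = int(missing.sum())
        if not missing.any():
            continue
        if missing.all():
            raise InsufficientDataError(f"variable {var!r} is 100% missing")
        complete = df.loc[~missing]
        observed = complete[var].astype(float)
        is_binary = set(np.unique(observed)) <= {0.0, 1.0}
        if candidate_predictors:
            X_fit = complete[candidate_predictors].to_numpy(dtype=float)
            X_mis = df.loc[missing, candidate_predictors].to_numpy(dtype=float)
            if is_binary and observed.nunique() > 1:
                model = LogisticRegression(max_iter=1000)
                model.fit(X_fit, observed.astype(int))
                pred = model.predict_proba(X_mis)[:, 1]
            else:
                model = LinearRegression()
                model.fit(X_fit, observed)
                pred = model.predict(X_mis)
        else:
            pred = np.full(int(missing.sum()), observed.mean())
        if is_binary:
            pred = (pred >= 0.5).astype(float)
        df.loc[missing, var] = pred
    return df, log


def _cv_from_sets(
    train: pd.DataFrame,
    valid: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    horizon: float,
    seed: int,
    ties: str = "efron",
) -> tuple[CVReport, CoxFit, Optional[CoxFit]]:
    fit_train = cox_fit(train, outcome, covariates, ties=ties)
    auc_train = roc_auc(fit_train, train, outcome, horizon)
    auc_valid = roc_auc(fit_train, valid, outcome, horizon)
    shrinkage = auc_train - auc_valid
    generalizable = abs(shrinkage) < 0.10
    final = None
    if generalizable:
        combined = pd.concat([train, valid], ignore_index=True)
        final = cox_fit(combined, outcome, covariates, ties=ties)
    report = CVReport(
        auc_training=float(auc_train),
        auc_validation=float(auc_valid),
        shrinkage=float(shrinkage),
        split_seed=int(seed),
        n_training=len(train),
        n_validation=len(valid),
        generalizable=generalizable,
    )
    return report, fit_train, final


def split_sample_cv(
    df: pd.DataFrame,
    outcome: str = "dss",
    covariates: Sequence[str] = ("category",),
    split_fraction: float = 0.5,
    seed: int = 0,
    horizon: float = 10.0,
    ties: str = "efron",
    validation: Optional[pd.DataFrame] = None,
) -> tuple[CVReport, CoxFit, Optional[CoxFit]]:
    """Split-sample cross-validation with a shrinkage coefficient.

    The sample is split at random into a training set of round(n * fraction)
    subjects and a validation set of the rest; coefficients estimated in
    training are applied unchanged to the validation covariates. Shrinkage is
    exactly auc_training - auc_validation; |shrinkage| < 0.10 marks the model
    generalizable, in which case a final fit on the combined data is also
    returned. Passing ``validation`` explicitly skips the split (e.g. a copy
    of the training data gives shrinkage 0).
    """
    if validation is not None:
        return _cv_from_sets(df, validation, outcome, covariates, horizon, seed, ties)
    if not 0.0 < split_fraction < 1.0:
        raise ContractError("split_fraction must lie in (0, 1)")
    n = len(df)
    if n < 20:
        raise InsufficientDataError("need n >= 20 for split-sample cross-validation")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * split_fraction))
    train = df.iloc[order[:n_train]].reset_index(drop=True)
    valid = df.iloc[order[n_train:]].reset_index(drop=True)
    try:
        return _cv_from_sets(train, valid, outcome, covariates, horizon, seed, ties)
    except (InsufficientDataError, UndefinedEstimateError) as exc:
        raise UndefinedEstimateError(
            f"split-sample fit failed ({exc}); consider fewer covariates"
        ) from exc
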