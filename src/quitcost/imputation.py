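"""Missing-data machinery.

Four layers, mirroring how trial analyses usually handle missingness:

1. a deterministic outcome rule — missing smoking-cessation indicators count
   as not abstinent, so abstinence denominators are the randomized arm sizes;
2. baseline mean imputation — missing baseline covariates are assumed
   unrelated to treatment and replaced by the full-sample mean (mode for
   categorical);
3. multiple imputation by chained equations (MICE) for follow-up variables,
   assuming missing at random: continuous variables by predictive mean
   matching (PMM, Bayesian draw of the regression then donor draw among the
   k nearest observed predicted means), binary variables by Bayesian
   logistic regression with data augmentation against perfect prediction;
   chains run separately by randomized arm with site as a stratification
   covariate; estimates are pooled across completed datasets by Rubin's
   rules with the Barnard-Rubin small-sample degrees of freedom;
4. pattern-mixture MNAR adjustments — imputed (never observed) cost and
   6-month utility cells are scaled by sensitivity factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ABSTINENCE_COLUMNS", "DEFAULT_IMPUTED_VARIABLES",
    "ImputationPlan", "ImputedSet", "PooledEstimate",
    "abstinence_missing_rule", "mean_impute_baseline", "mice_pmm",
    "choose_m", "rubin_pool", "mnar_adjust",
]

ABSTINENCE_COLUMNS = ["abstinent_co", "abstinent_sr", "pp7_1m", "pp7_3m", "pp7_6m"]

#: Follow-up analysis variables imputed by default, with their method tags.
DEFAULT_IMPUTED_VARIABLES: dict[str, str] = {
    "cost_cessation": "pmm",
    "cost_primary": "pmm",
    "cost_secondary": "pmm",
    "spend_nrt_ecig": "pmm",
    "utility_6m": "pmm",
    "vas_6m": "pmm",
}

#: Complete baseline predictors entering every chained equation.
DEFAULT_PREDICTORS = [
    "age", "female", "ftcd", "other_smokers", "attend_injury",
    "cost_baseline", "spend_ecig_baseline", "utility_baseline", "vas_baseline",
]


def abstinence_missing_rule(
    dataset: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Set every missing abstinence indicator to not-abstinent (0).

    Observed values are unchanged.  This is applied before any statistical
    imputation, so cessation outcomes are never model-imputed and rates use
    the full randomized denominators.
    """
    out = dataset.copy()
    for col in columns or ABSTINENCE_COLUMNS:
        if col in out.columns:
            out[col] = out[col].fillna(0.0)
    return out


def mean_impute_baseline(
    dataset: pd.DataFrame, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Replace missing baseline values by the full-sample mean (mode for
    non-numeric columns).  Follow-up variables are untouched."""
    out = dataset.copy()
    cols = covariates if covariates is not None else [
        "age", "female", "ftcd", "other_smokers", "deprivation", "attend_injury",
        "cost_baseline", "spend_ecig_baseline", "utility_baseline", "vas_baseline",
    ]
    for col in cols:
        if col not in out.columns or not out[col].isna().any():
            continue
        observed = out[col].dropna()
        if observed.empty:
            raise ValueError(f"baseline variable {col!r} has no observed values")
        if pd.api.types.is_numeric_dtype(out[col]):
            out[col] = out[col].fillna(observed.mean())
        else:
            out[col] = out[col].fillna(observed.mode().iloc[0])
    return out


@dataclass
class ImputationPlan:
    """Settings for one chained-equation run.

    ``variables`` maps each follow-up variable to its method tag
    (``pmm`` or ``logistic``); the order is the visit sequence within a
    cycle.  ``pmm_donors`` is the donor-pool size (nearest neighbours on
    predicted mean).  ``by_group`` runs a separate chain per randomized arm;
    ``stratify_by_site`` enters site indicator variables into every
    equation.
    """

    m: int = 45
    pmm_donors: int = 10
    by_group: bool = True
    stratify_by_site: bool = True
    variables: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_IMPUTED_VARIABLES))
    predictors: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    n_cycles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("number of imputations m must be >= 1")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        bad = {v for v in self.variables.values()} - {"pmm", "logistic"}
        if bad:
            raise ValueError(f"unknown imputation method tags: {sorted(bad)}")


@dataclass
class ImputedSet:
    """``m`` completed datasets plus the plan, seed and missingness record.

    ``missing_mask`` marks, per cell of the original data, which values were
    imputed — needed by the MNAR pattern-mixture adjustments, which must
    only ever touch imputed cells.
    """

    datasets: list[pd.DataFrame]
    plan: ImputationPlan
    missing_mask: pd.DataFrame
    diagnostics: dict[str, float]

    @property
    def m(self) -> int:
        return len(self.datasets)

    def write(self, directory) -> None:
        """Persist as ``imp_<i>.csv`` files plus a JSON manifest."""
        import dataclasses as _dc
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets, start=1):
            df.to_csv(d / f"imp_{i}.csv", index=False)
        manifest = {
            "m": self.m,
            "plan": _dc.asdict(self.plan),
            "diagnostics": self.diagnostics,
            "files": [f"imp_{i}.csv" for i in range(1, self.m + 1)],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _design(df: pd.DataFrame, predictors: list[str], site_dummies: bool) -> np.ndarray:
    cols = [np.ones(len(df))]
    for p in predictors:
        cols.append(df[p].to_numpy(dtype=float))
    if site_dummies and "site" in df.columns:
        sites = np.sort(df["site"].unique())
        for s in sites[1:]:
            cols.append((df["site"] == s).to_numpy(dtype=float))
    X = np.column_stack(cols)
    # drop constant (beyond intercept) and collinear columns for stability
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) > 0:
            keep.append(j)
    return X[:, keep]


def _bayes_ols_draw(rng, X, y):
    """Posterior draw (beta*, and beta_hat) under the standard noninformative
    normal linear model; ridge-stabilized if X is near-singular."""
    n, p = X.shape
    XtX = X.T @ X
    XtX_reg = XtX + 1e-8 * np.eye(p) * max(1.0, np.trace(XtX) / p)
    beta_hat = np.linalg.solve(XtX_reg, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2_star = sigma2_hat * dof / rng.chisquare(dof)
    cov = sigma2_star * np.linalg.inv(XtX_reg)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return beta_hat, beta_star


def _pmm_impute(rng, X_obs, y_obs, X_mis, k):
    beta_hat, beta_star = _bayes_ols_draw(rng, X_obs, y_obs)
    eta_obs = X_obs @ beta_hat
    eta_mis = X_mis @ beta_star
    k = min(k, len(y_obs))
    out = np.empty(len(eta_mis))
    order = np.argsort(eta_obs)
    eta_sorted = eta_obs[order]
    y_sorted = y_obs[order]
    for i, e in enumerate(eta_mis):
        j = np.searchsorted(eta_sorted, e)
        lo = max(0, j - k)
        hi = min(len(eta_sorted), j + k)
        window = np.arange(lo, hi)
        nearest = window[np.argsort(np.abs(eta_sorted[window] - e))[:k]]
        out[i] = y_sorted[nearest[rng.integers(k)]]
    return out


def _logistic_impute(rng, X_obs, y_obs, X_mis):
    import statsmodels.api as sm

    X_fit, y_fit, w = X_obs, y_obs, None
    for attempt in (0, 1):
        try:
            model = sm.GLM(y_fit, X_fit, family=sm.families.Binomial(),
                           freq_weights=w)
            res = model.fit(maxiter=100)
            if not np.all(np.isfinite(res.params)) or not np.all(
                    np.isfinite(res.cov_params())):
                raise ValueError("non-finite logistic fit")
            break
        except Exception:
            if attempt == 1:
                raise RuntimeError(
                    "logistic imputation model failed even after augmentation "
                    "for perfect prediction")
            # augment: half-weight pseudo-observations at both outcomes
            # anchored at the mean design row, against separation
            x_bar = X_obs.mean(axis=0, keepdims=True)
            X_fit = np.vstack([X_obs, x_bar, x_bar])
            y_fit = np.concatenate([y_obs, [0.0, 1.0]])
            w = np.concatenate([np.ones(len(y_obs)), [0.5, 0.5]])
    beta_star = rng.multivariate_normal(
        res.params, res.cov_params(), method="cholesky")
    p = 1.0 / (1.0 + np.exp(-(X_mis @ beta_star)))
    return rng.binomial(1, p).astype(float)


def _run_chain(rng, group: pd.DataFrame, plan: ImputationPlan) -> pd.DataFrame:
    """One completed copy of one arm's data (a single imputation)."""
    work = group.copy()
    to_impute = {v: m for v, m in plan.variables.items()
                 if v in work.columns and work[v].isna().any()}
    masks = {v: work[v].isna().to_numpy() for v in to_impute}
    # initial fill: random draws from each variable's observed pool
    for v in to_impute:
        obs = work.loc[~masks[v], v].to_numpy(dtype=float)
        if obs.size == 0:
            raise ValueError(f"variable {v!r} has no observed values in group")
        work.loc[masks[v], v] = rng.choice(obs, size=masks[v].sum())

    for _ in range(plan.n_cycles):
        for v, method in to_impute.items():
            mask = masks[v]
            others = [u for u in plan.variables if u in work.columns and u != v]
            predictors = plan.predictors + others
            predictors = [p for p in predictors if p in work.columns]
            X = _design(work, predictors, plan.stratify_by_site)
            y = work[v].to_numpy(dtype=float)
            y_obs = group.loc[~mask, v].to_numpy(dtype=float)
            if np.ptp(y_obs) == 0:  # constant observed values: nothing to model
                work.loc[mask, v] = y_obs[0]
                continue
            if method == "pmm":
                work.loc[mask, v] = _pmm_impute(
                    rng, X[~mask], y[~mask], X[mask], plan.pmm_donors)
            else:
                work.loc[mask, v] = _logistic_impute(rng, X[~mask], y[~mask], X[mask])
    return work


def mice_pmm(dataset: pd.DataFrame, plan: ImputationPlan) -> ImputedSet:
    """Multiple imputation by chained equations with PMM.

    Returns ``plan.m`` completed datasets.  Chains run separately per
    randomized arm when ``plan.by_group``; within each chain the listed
    variables are visited in order for ``plan.n_cycles`` cycles, each
    equation regressing on all other listed variables, the baseline
    predictors and (optionally) site indicators.  Deterministic under
    ``plan.seed``.
    """
    analysis_cols = [v for v in plan.variables if v in dataset.columns]
    missing_mask = dataset[analysis_cols].isna()
    diagnostics = {v: float(missing_mask[v].mean()) for v in analysis_cols}

    rng = np.random.default_rng(plan.seed)
    completed: list[pd.DataFrame] = []
    groups = (
        [g for _, g in dataset.groupby("arm", sort=True)]
        if plan.by_group and "arm" in dataset.columns else [dataset]
    )
    for _ in range(plan.m):
        parts = [_run_chain(rng, g, plan) for g in groups]
        filled = pd.concat(parts).loc[dataset.index]
        completed.append(filled)
    return ImputedSet(datasets=completed, plan=plan,
                      missing_mask=missing_mask, diagnostics=diagnostics)


def choose_m(missing_fractions) -> int:
    """Number of imputations: the highest percentage of missing data,
    rounded up, floored at one."""
    fractions = list(missing_fractions)
    if not fractions:
        raise ValueError("missing_fractions must be non-empty")
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("missing fractions must lie in [0, 1]")
    return max(1, math.ceil(100.0 * max(fractions)))


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    df: float

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def rubin_pool(point_estimates, variances, alpha: float = 0.05,
               df_complete: float | None = None) -> PooledEstimate:
    """Pool estimates across imputations by Rubin's rules.

    Total variance = mean within-imputation variance + (1 + 1/m) x
    between-imputation variance.  The CI uses a t reference with
    Barnard-Rubin degrees of freedom when ``df_complete`` (the complete-data
    df) is given, else the classic large-sample Rubin df.
    """
    q = np.asarray(list(point_estimates), dtype=float)
    u = np.asarray(list(variances), dtype=float)
    if q.shape != u.shape:
        raise ValueError("point_estimates and variances must have equal length")
    m = len(q)
    if m < 1:
        raise ValueError("need at least one estimate")
    qbar = float(q.mean())
    ubar = float(u.mean())
    if m == 1:
        t_var = ubar
        df = df_complete if df_complete is not None else np.inf
    else:
        b = float(q.var(ddof=1))
        t_var = ubar + (1.0 + 1.0 / m) * b
        if t_var == 0.0 or b == 0.0:
            df = df_complete if df_complete is not None else np.inf
        else:
            lam = (1.0 + 1.0 / m) * b / t_var
            df_old = (m - 1) / lam ** 2
            if df_complete is None:
                df = df_old
            else:
                df_obs = ((df_complete + 1.0) / (df_complete + 3.0)
                          * df_complete * (1.0 - lam))
                df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(
        1 - alpha / 2)
    half = tcrit * math.sqrt(t_var)
    return PooledEstimate(estimate=qbar, variance=t_var,
                          ci_low=qbar - half, ci_high=qbar + half, df=float(df))


DEFAULT_MNAR_COST_COLUMNS = ["cost_cessation", "cost_primary", "cost_secondary"]


def mnar_adjust(imp: ImputedSet, cost_factor: float = 1.0,
                utility_factor: float = 1.0,
                cost_columns: list[str] | None = None,
                utility_column: str = "utility_6m") -> ImputedSet:
    """Pattern-mixture MNAR adjustment.

    Multiplies only *imputed* cost cells by ``cost_factor`` and only
    *imputed* 6-month utility cells by ``utility_factor``; observed cells
    are untouched (bit-identical).  Returns a new :class:`ImputedSet`
    sharing the plan and mask.
    """
    if cost_factor <= 0 or utility_factor <= 0:
        raise ValueError("MNAR adjustment factors must be positive")
    cost_columns = cost_columns if cost_columns is not None else DEFAULT_MNAR_COST_COLUMNS
    adjusted = []
    for df in imp.datasets:
        new = df.copy()
        for col in cost_columns:
            if col in imp.missing_mask.columns:
                mask = imp.missing_mask[col]
                new.loc[mask, col] = new.loc[mask, col] * cost_factor
        if utility_column in imp.missing_mask.columns:
            mask = imp.missing_mask[utility_column]
            new.loc[mask, utility_column] = (
                new.loc[mask, utility_column] * utility_factor)
        adjusted.append(new)
    return ImputedSet(datasets=adjusted, plan=imp.plan,
                      missing_mask=imp.missing_mask, diagnostics=imp.diagnostics)
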