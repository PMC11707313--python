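"""Trial-period cost-utility analysis.

Abstinence statistics on intention-to-treat denominators, cost-per-abstainer
arithmetic, regression-adjusted incremental costs and QALYs on multiply
imputed data, the ICER with cost-effectiveness-plane dominance handling, and
bootstrap-with-imputation uncertainty summarized as percentile confidence
intervals, a cost-effectiveness plane cloud and cost-effectiveness
acceptability curves (CEAC).

Model choices follow common health-economics practice: costs (strictly
positive once the treatment cost is included) are modelled by a gamma GLM
with log link, falling back to an identity-link gaussian fit if the gamma
model fails to converge (the fallback is logged); QALYs by a linear model,
with a site random intercept attempted first and fixed site effects as the
fallback.  Incremental means from the nonlinear cost model are recycled
predictions (average marginal effect of arm), so both deltas are on the
natural scale required for ICER arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .imputation import (ImputationPlan, ImputedSet, PooledEstimate,
                         abstinence_missing_rule, mice_pmm, rubin_pool)
from .qaly import UtilityProfile, qaly_auc

logger = logging.getLogger(__name__)

__all__ = [
    "AbstinenceSummary", "IncrementalEstimates", "IncrementalResult", "ICERResult",
    "abstinence_stats", "followup_chi2", "cost_per_abstainer",
    "incremental_cost_per_additional_abstainer", "adjusted_incrementals",
    "icer", "bootstrap_mi", "ceac", "cep", "complete_cases",
    "add_total_cost_and_qalys", "round_pound", "DEFAULT_THRESHOLDS",
]

#: Willingness-to-pay grid (GBP per QALY): £0-£50,000 in £500 steps,
#: spanning the usual £20,000-£30,000 decision range.
DEFAULT_THRESHOLDS = np.arange(0, 50_001, 500)

COST_COVARIATES = ["age", "female", "attend_injury", "ftcd", "other_smokers",
                   "cost_baseline"]
QALY_COVARIATES = ["age", "attend_injury", "ftcd", "other_smokers",
                   "utility_baseline"]


def round_pound(x: float) -> int:
    """Round to the nearest pound, halves away from zero (presentation rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# --------------------------------------------------------------------------
# abstinence statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AbstinenceSummary:
    """Per-arm abstinence on randomized denominators with relative risk."""

    outcome: str
    n_control: int
    n_intervention: int
    abstainers_control: int
    abstainers_intervention: int
    rr: float | None
    rr_ci: tuple[float, float] | None

    @property
    def rate_control(self) -> float:
        return self.abstainers_control / self.n_control

    @property
    def rate_intervention(self) -> float:
        return self.abstainers_intervention / self.n_intervention

    def se(self, arm: str) -> float:
        p = self.rate_control if arm == "control" else self.rate_intervention
        n = self.n_control if arm == "control" else self.n_intervention
        return math.sqrt(p * (1 - p) / n)


def abstinence_stats(dataset: pd.DataFrame, outcome: str = "abstinent_co",
                     alpha: float = 0.05) -> AbstinenceSummary:
    """Abstinence rates, binomial SEs and relative risk with log-scale CI.

    Missing indicators are resolved to not-abstinent first, so denominators
    are the randomized arm sizes.
    """
    if outcome not in dataset.columns:
        raise KeyError(f"outcome column {outcome!r} not in dataset")
    df = abstinence_missing_rule(dataset, [outcome])
    counts = {}
    for arm in ("control", "intervention"):
        sub = df[df["arm"] == arm]
        counts[arm] = (int(sub[outcome].sum()), len(sub))
    a_c, n_c = counts["control"]
    a_i, n_i = counts["intervention"]
    if a_c == 0:
        rr, ci = None, None  # undefined: zero control numerator
    else:
        rr = (a_i / n_i) / (a_c / n_c)
        if a_i == 0:
            ci = None
        else:
            se_log = math.sqrt(1 / a_i - 1 / n_i + 1 / a_c - 1 / n_c)
            z = stats.norm.ppf(1 - alpha / 2)
            ci = (rr * math.exp(-z * se_log), rr * math.exp(z * se_log))
    return AbstinenceSummary(outcome=outcome, n_control=n_c, n_intervention=n_i,
                             abstainers_control=a_c, abstainers_intervention=a_i,
                             rr=rr, rr_ci=ci)


def followup_chi2(followed_by_arm: dict[str, tuple[int, int]]) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) for a difference in
    follow-up proportions.  ``followed_by_arm`` maps arm -> (followed, total).
    """
    table = []
    for arm, (followed, total) in followed_by_arm.items():
        if not 0 < followed < total:
            raise ValueError(f"degenerate follow-up counts for arm {arm!r}")
        table.append([followed, total - followed])
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue)


def cost_per_abstainer(mean_cost_per_participant: float, n: int,
                       abstainers: int) -> float:
    """Arm cessation cost per abstainer: mean cost x n / abstainers."""
    if abstainers <= 0:
        raise ZeroDivisionError("cost per abstainer undefined with zero abstainers")
    return mean_cost_per_participant * n / abstainers


def incremental_cost_per_additional_abstainer(
        cost_control: float, cost_intervention: float,
        rate_control: float, rate_intervention: float) -> float:
    """(cost_int - cost_ctrl) / (rate_int - rate_ctrl); negative values mean
    the costlier arm is the less effective one (dominance direction)."""
    d_rate = rate_intervention - rate_control
    if d_rate == 0:
        raise ZeroDivisionError("zero abstinence-rate difference")
    return (cost_intervention - cost_control) / d_rate


# --------------------------------------------------------------------------
# ICER and the cost-effectiveness plane
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ICERResult:
    """Δcost/ΔQALY with its cost-effectiveness-plane quadrant.

    ``tag`` is one of ``icer`` (NE: costlier, more effective),
    ``dominant_intervention`` (SE: cheaper, more effective — no ratio),
    ``dominated`` (NW: costlier, less effective — no ratio),
    ``sw_ratio`` (cheaper, less effective: ratio reported, interpretation
    reversed), ``undefined`` (ΔQALY = 0) or ``zero_delta``.
    """

    delta_cost: float
    delta_qaly: float
    tag: str
    value: float | None

    def __str__(self) -> str:
        if self.tag == "icer":
            return f"£{self.value:,.0f} per QALY gained"
        if self.tag == "sw_ratio":
            return f"£{self.value:,.0f} per QALY forgone (southwest quadrant)"
        return self.tag.replace("_", " ")


def icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    """Classify the (Δcost, ΔQALY) pair and form the ratio where defined."""
    if delta_cost == 0 and delta_qaly == 0:
        return ICERResult(delta_cost, delta_qaly, "zero_delta", None)
    if delta_qaly == 0:
        return ICERResult(delta_cost, delta_qaly, "undefined", None)
    if delta_qaly > 0:
        if delta_cost >= 0:
            return ICERResult(delta_cost, delta_qaly, "icer",
                              delta_cost / delta_qaly)
        return ICERResult(delta_cost, delta_qaly, "dominant_intervention", None)
    if delta_cost >= 0:
        return ICERResult(delta_cost, delta_qaly, "dominated", None)
    return ICERResult(delta_cost, delta_qaly, "sw_ratio", delta_cost / delta_qaly)


# --------------------------------------------------------------------------
# adjusted incremental estimation
# --------------------------------------------------------------------------

def add_total_cost_and_qalys(df: pd.DataFrame,
                             horizon_years: float = 0.5) -> pd.DataFrame:
    """Derive the payer-perspective total cost and trial QALYs per row.

    Total cost = treatment + cessation support + primary care + secondary
    care (own NRT/e-cigarette spending excluded); QALYs by trapezoidal area
    under the two utility measurements.
    """
    out = df.copy()
    out["total_cost"] = (out["cost_treatment"] + out["cost_cessation"]
                         + out["cost_primary"] + out["cost_secondary"])
    out["qalys"] = [
        qaly_auc(UtilityProfile(b, s, horizon_years)) if not (
            pd.isna(b) or pd.isna(s)) else np.nan
        for b, s in zip(out["utility_baseline"], out["utility_6m"])
    ]
    return out


def _design_matrix(df: pd.DataFrame, covariates: list[str],
                   site_dummies: bool) -> np.ndarray:
    cols = [np.ones(len(df)), (df["arm"] == "intervention").to_numpy(float)]
    for c in covariates:
        cols.append(df[c].to_numpy(float))
    if site_dummies and "site" in df.columns:
        for s in np.sort(df["site"].unique())[1:]:
            cols.append((df["site"] == s).to_numpy(float))
    X = np.column_stack(cols)
    keep = [j for j in range(X.shape[1]) if j < 2 or np.ptp(X[:, j]) > 0]
    return X[:, keep]


def _gamma_ame(df: pd.DataFrame, covariates: list[str],
               site_effects: bool = True) -> tuple[float, float]:
    """Average marginal effect of arm on cost from a gamma/log GLM, with
    delta-method variance; identity-link gaussian fallback on failure."""
    X = _design_matrix(df, covariates, site_dummies=site_effects)
    y = df["total_cost"].to_numpy(float)
    try:
        if (y <= 0).any():
            raise ValueError("non-positive costs: gamma family inapplicable")
        res = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit(
            maxiter=200)
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite gamma fit")
        beta, V = res.params, np.asarray(res.cov_params())
        X1, X0 = X.copy(), X.copy()
        X1[:, 1], X0[:, 1] = 1.0, 0.0
        mu1, mu0 = np.exp(X1 @ beta), np.exp(X0 @ beta)
        ame = float(np.mean(mu1 - mu0))
        grad = (mu1[:, None] * X1 - mu0[:, None] * X0).mean(axis=0)
        var = float(grad @ V @ grad)
        return ame, var
    except Exception as exc:  # pragma: no cover - data dependent
        logger.warning("gamma cost model failed (%s); "
                       "falling back to identity-link gaussian", exc)
        res = sm.OLS(y, X).fit()
        return float(res.params[1]), float(np.asarray(res.cov_params())[1, 1])


def _qaly_effect(df: pd.DataFrame, covariates: list[str],
                 random_intercept: bool = True,
                 site_effects: bool = True) -> tuple[float, float]:
    """Arm effect on QALYs: site random intercept when estimable, fixed
    site effects as the logged fallback."""
    import warnings

    y = df["qalys"].to_numpy(float)
    if random_intercept:
        try:
            X = _design_matrix(df, covariates, site_dummies=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, X, groups=df["site"].to_numpy()).fit(reml=True)
            if not res.converged or not np.isfinite(res.bse_fe[1]):
                raise ValueError("mixed model did not converge")
            return float(res.fe_params[1]), float(res.bse_fe[1] ** 2)
        except Exception as exc:
            logger.warning("site random intercept not estimable (%s); "
                           "using fixed site effects", exc)
    X = _design_matrix(df, covariates, site_dummies=site_effects)
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(np.asarray(res.cov_params())[1, 1])


@dataclass(frozen=True)
class IncrementalEstimates:
    """Rubin-pooled adjusted incremental cost and QALYs."""

    delta_cost: PooledEstimate
    delta_qaly: PooledEstimate

    def icer(self) -> ICERResult:
        return icer(self.delta_cost.estimate, self.delta_qaly.estimate)


def adjusted_incrementals(
    imp: ImputedSet | list[pd.DataFrame],
    cost_covariates: list[str] | None = None,
    qaly_covariates: list[str] | None = None,
    max_dropped_fraction: float = 0.2,
    qaly_random_intercept: bool = True,
    site_effects: bool = True,
) -> IncrementalEstimates:
    """Adjusted Δcost and ΔQALY, Rubin-pooled over imputed datasets.

    Per dataset, the cost model is a gamma/log GLM in arm + the cost
    covariates + site, summarized as the average marginal effect of arm;
    the QALY model is linear in arm + the QALY covariates with a site
    intercept.  Datasets where a model errors out are dropped with a
    warning; more than ``max_dropped_fraction`` dropped is a hard error.
    """
    datasets = imp.datasets if isinstance(imp, ImputedSet) else list(imp)
    cost_covariates = cost_covariates if cost_covariates is not None else COST_COVARIATES
    qaly_covariates = qaly_covariates if qaly_covariates is not None else QALY_COVARIATES
    cost_q, cost_u, qaly_q, qaly_u = [], [], [], []
    n_rows = None
    for i, df in enumerate(datasets):
        work = add_total_cost_and_qalys(df)
        n_rows = len(work)
        try:
            dc, vc = _gamma_ame(work, [c for c in cost_covariates
                                       if c in work.columns],
                                site_effects=site_effects)
            dq, vq = _qaly_effect(work, [c for c in qaly_covariates
                                         if c in work.columns],
                                  random_intercept=qaly_random_intercept,
                                  site_effects=site_effects)
        except Exception as exc:
            logger.warning("imputed dataset %d dropped: %s", i, exc)
            continue
        cost_q.append(dc)
        cost_u.append(vc)
        qaly_q.append(dq)
        qaly_u.append(vq)
    if not cost_q or (len(datasets) - len(cost_q)) / len(datasets) > max_dropped_fraction:
        raise RuntimeError("too many imputed datasets failed model fitting")
    df_com = (n_rows - 2 - len(cost_covariates)) if n_rows else None
    return IncrementalEstimates(
        delta_cost=rubin_pool(cost_q, cost_u, df_complete=df_com),
        delta_qaly=rubin_pool(qaly_q, qaly_u, df_complete=df_com),
    )


def complete_cases(dataset: pd.DataFrame) -> pd.DataFrame:
    """Participants with complete costs, utilities and 6-month smoking
    status — the complete-case sensitivity subset."""
    needed = ["cost_treatment", "cost_cessation", "cost_primary",
              "cost_secondary", "utility_baseline", "utility_6m",
              "cost_baseline", "abstinent_co"]
    return dataset.dropna(subset=[c for c in needed if c in dataset.columns])


# --------------------------------------------------------------------------
# bootstrap + imputation uncertainty
# --------------------------------------------------------------------------

@dataclass
class IncrementalResult:
    """Complete uncertainty bundle for one incremental comparison."""

    delta_cost: float
    delta_qaly: float
    delta_cost_ci: tuple[float, float]
    delta_qaly_ci: tuple[float, float]
    icer: ICERResult
    draws: np.ndarray  # (B, 2): Δcost, ΔQALY
    ceac: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_cost_ci": list(self.delta_cost_ci),
            "delta_qaly_ci": list(self.delta_qaly_ci),
            "icer_tag": self.icer.tag,
            "icer_value": self.icer.value,
            "ceac": {str(k): v for k, v in self.ceac.items()},
        }


def bootstrap_mi(dataset: pd.DataFrame, plan: ImputationPlan, B: int,
                 seed: int, resample: bool = True,
                 cost_covariates: list[str] | None = None,
                 qaly_covariates: list[str] | None = None,
                 max_retries: int = 3) -> np.ndarray:
    """Bootstrap-then-impute draw set of paired (Δcost, ΔQALY) estimates.

    Each replicate resamples participants with replacement within arm x
    site stratum, imputes the replicate once, and re-fits the adjusted
    incremental models, yielding exactly ``B`` pairs.  ``resample=False``
    degenerates to repeated estimation on the full sample (useful to check
    the point estimate).  Failed replicates are redrawn up to
    ``max_retries`` times each before erroring.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    strata = [idx.to_numpy() for _, idx in
              dataset.groupby(["arm", "site"], sort=True).groups.items()]
    draws = np.empty((B, 2))
    for b in range(B):
        for attempt in range(max_retries + 1):
            if resample:
                rows = np.concatenate([rng.choice(s, size=len(s), replace=True)
                                       for s in strata])
                boot = dataset.loc[rows].reset_index(drop=True)
            else:
                boot = dataset
            rep_plan = ImputationPlan(
                m=1, pmm_donors=plan.pmm_donors, by_group=plan.by_group,
                stratify_by_site=plan.stratify_by_site,
                variables=dict(plan.variables), predictors=list(plan.predictors),
                n_cycles=plan.n_cycles,
                seed=int(rng.integers(0, 2 ** 31 - 1)))
            try:
                imp = mice_pmm(boot, rep_plan)
                # fixed site effects inside replicates: the stratified
                # resampling already propagates between-site uncertainty
                est = adjusted_incrementals(imp, cost_covariates,
                                            qaly_covariates,
                                            qaly_random_intercept=False)
                draws[b] = (est.delta_cost.estimate, est.delta_qaly.estimate)
                break
            except Exception as exc:
                if attempt == max_retries:
                    raise RuntimeError(
                        f"bootstrap replicate {b} failed after retries") from exc
                logger.warning("replicate %d attempt %d failed: %s",
                               b, attempt, exc)
    return draws


def percentile_ci(draws: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def ceac(draws: np.ndarray, thresholds=DEFAULT_THRESHOLDS) -> dict[float, float]:
    """Probability of positive net monetary benefit per threshold.

    For each willingness-to-pay λ, the fraction of (Δcost, ΔQALY) draws
    with λ·ΔQALY − Δcost > 0.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be non-empty")
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds < 0).any():
        raise ValueError("thresholds must be non-negative")
    dc, dq = draws[:, 0], draws[:, 1]
    return {float(lam): float(np.mean(lam * dq - dc > 0)) for lam in thresholds}


def cep(draws: np.ndarray) -> pd.DataFrame:
    """The raw cost-effectiveness-plane cloud, for plotting."""
    draws = np.asarray(draws, dtype=float)
    return pd.DataFrame({"delta_qaly": draws[:, 1], "delta_cost": draws[:, 0]})


def summarize_uncertainty(point: IncrementalEstimates, draws: np.ndarray,
                          thresholds=DEFAULT_THRESHOLDS) -> IncrementalResult:
    """Bundle point estimates with bootstrap CIs and the CEAC computed from
    one and the same draw set."""
    return IncrementalResult(
        delta_cost=point.delta_cost.estimate,
        delta_qaly=point.delta_qaly.estimate,
        delta_cost_ci=percentile_ci(draws[:, 0]),
        delta_qaly_ci=percentile_ci(draws[:, 1]),
        icer=point.icer(),
        draws=draws,
        ceac=ceac(draws, thresholds),
    )
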