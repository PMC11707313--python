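"""End-to-end orchestration of the economic evaluation.

Runs the stages in the analysis order — simulate (or load) the trial, cost
summaries, baseline mean imputation, chained-equation multiple imputation,
the adjusted cost-utility analysis (primary, complete-case, MNAR
pattern-mixture grid and broader-sample variants), the lifetime Markov
projection with probabilistic sensitivity analysis — and writes a results
bundle: JSON results, CSV tables mirroring the trial-report layout,
bootstrap draws, cost-effectiveness plane and acceptability-curve figures,
and a run manifest.  Re-running with the same configuration and seed
reproduces the JSON results bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cua, imputation as imp_mod, markov as markov_mod
from .imputation import ImputationPlan, choose_m
from .trialgen import TrialConfig, default_trial_config, generate_trial

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

MNAR_COST_FACTORS = (1.1, 1.2, 1.3)
MNAR_UTILITY_FACTORS = (0.9, 0.8, 0.7)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    ``m_max`` caps the imputation count chosen from the observed missing
    fraction; ``n_bootstrap`` is the bootstrap-with-imputation replicate
    count.  Both default well below a full production run (45 imputations,
    5000 replicates) to keep a complete pipeline pass in the minutes range;
    scale them up for substantive use.
    """

    trial: TrialConfig = field(default_factory=lambda: default_trial_config(
        n_accompanying=35))
    seed: int = 0
    m_max: int = 10
    n_cycles: int = 5
    pmm_donors: int = 10
    n_bootstrap: int = 500
    run_mnar: bool = True
    run_broader: bool = True
    run_markov: bool = True
    n_psa: int = 500
    make_figures: bool = True


@dataclass
class RunManifest:
    config: dict
    seed: int
    started: float
    finished: float
    outputs: list[str]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


def _arm_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean (SE) rows of costs and QALYs, trial-report style."""
    work = cua.add_total_cost_and_qalys(df)
    rows = []
    for arm, sub in work.groupby("arm", sort=True):
        for label, col in [
            ("baseline_healthcare_costs", "cost_baseline"),
            ("treatment_costs", "cost_treatment"),
            ("cessation_support_costs", "cost_cessation"),
            ("primary_care_costs", "cost_primary"),
            ("secondary_care_costs", "cost_secondary"),
            ("total_costs", "total_cost"),
            ("utility_baseline", "utility_baseline"),
            ("utility_6m", "utility_6m"),
            ("qalys", "qalys"),
        ]:
            x = sub[col].dropna()
            rows.append({"arm": arm, "quantity": label, "n": len(x),
                         "mean": x.mean(),
                         "se": x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1
                         else 0.0})
    return pd.DataFrame(rows)


def _analyse(df: pd.DataFrame, config: PipelineConfig, seed: int,
             label: str) -> dict:
    """Impute, estimate adjusted incrementals, bootstrap, CEAC."""
    base = imp_mod.abstinence_missing_rule(df)
    base = imp_mod.mean_impute_baseline(base)
    frac = base[list(imp_mod.DEFAULT_IMPUTED_VARIABLES)].isna().mean()
    m = min(choose_m(frac), config.m_max)
    plan = ImputationPlan(m=m, pmm_donors=config.pmm_donors,
                          n_cycles=config.n_cycles, seed=seed)
    imputed = imp_mod.mice_pmm(base, plan)
    point = cua.adjusted_incrementals(imputed)
    draws = cua.bootstrap_mi(base, plan, B=config.n_bootstrap, seed=seed + 1)
    result = cua.summarize_uncertainty(point, draws)
    logger.info("%s: Δcost %.1f, ΔQALY %.4f, %s", label,
                result.delta_cost, result.delta_qaly, result.icer)
    return {"result": result, "imputed": imputed, "base": base, "plan": plan,
            "m": m}


def _mnar_grid(primary: dict) -> list[dict]:
    out = []
    for cf in MNAR_COST_FACTORS:
        for uf in MNAR_UTILITY_FACTORS:
            adjusted = imp_mod.mnar_adjust(primary["imputed"], cost_factor=cf,
                                           utility_factor=uf)
            est = cua.adjusted_incrementals(adjusted)
            out.append({
                "cost_factor": cf, "utility_factor": uf,
                "delta_cost": est.delta_cost.estimate,
                "delta_qaly": est.delta_qaly.estimate,
                "icer_tag": est.icer().tag,
                "icer_value": est.icer().value,
            })
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the full analysis sequence into ``out_dir``."""
    started = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(name: str) -> Path:
        outputs.append(name)
        return out / name

    # -- simulate ----------------------------------------------------------
    dataset = generate_trial(config.trial, seed=config.seed)
    df = dataset.records
    randomized = df[df["is_randomized"]].reset_index(drop=True)
    dataset.to_csv(emit("dataset.csv"))
    dataset.data_dictionary().to_csv(emit("data_dictionary.csv"), index=False)

    results: dict = {"seed": config.seed}

    # -- trial statistics and costing summaries ----------------------------
    followed = {
        arm: (int(sub["followed"].sum()), len(sub))
        for arm, sub in randomized.groupby("arm", sort=True)
    }
    chi2, pval = cua.followup_chi2(followed)
    summary = cua.abstinence_stats(randomized, "abstinent_co")
    mean_tc = {arm: float(sub["cost_treatment"].mean())
               for arm, sub in randomized.groupby("arm", sort=True)}
    results["trial"] = {
        "followup": {a: {"followed": f, "n": n} for a, (f, n) in followed.items()},
        "followup_chi2": chi2, "followup_p": pval,
        "abstinence": {
            "control": summary.rate_control,
            "intervention": summary.rate_intervention,
            "rr": summary.rr, "rr_ci": summary.rr_ci,
        },
        "cost_per_abstainer": {
            "control": cua.cost_per_abstainer(
                mean_tc["control"], summary.n_control,
                summary.abstainers_control),
            "intervention": cua.cost_per_abstainer(
                mean_tc["intervention"], summary.n_intervention,
                summary.abstainers_intervention),
        },
    }
    _arm_table(randomized).to_csv(emit("table_costs_qalys.csv"), index=False)

    # -- primary analysis --------------------------------------------------
    primary = _analyse(randomized, config, config.seed, "primary")
    results["primary"] = primary["result"].to_dict()
    results["primary"]["m_imputations"] = primary["m"]
    pd.DataFrame(primary["result"].draws,
                 columns=["delta_cost", "delta_qaly"]).to_csv(
        emit("bootstrap_draws.csv"), index=False)
    primary["imputed"].write(out / "imputations")
    outputs.append("imputations/manifest.json")

    # -- complete case -----------------------------------------------------
    cc = cua.complete_cases(randomized)
    cc_est = cua.adjusted_incrementals([cc])
    results["complete_case"] = {
        "n_control": int((cc["arm"] == "control").sum()),
        "n_intervention": int((cc["arm"] == "intervention").sum()),
        "delta_cost": cc_est.delta_cost.estimate,
        "delta_qaly": cc_est.delta_qaly.estimate,
        "icer_tag": cc_est.icer().tag,
        "icer_value": cc_est.icer().value,
    }

    # -- MNAR pattern-mixture grid ----------------------------------------
    if config.run_mnar:
        results["mnar"] = _mnar_grid(primary)
        pd.DataFrame(results["mnar"]).to_csv(emit("mnar_grid.csv"), index=False)

    # -- broader sample ----------------------------------------------------
    if config.run_broader and (~df["is_randomized"]).any():
        broader = _analyse(df.reset_index(drop=True), config,
                           config.seed + 7, "broader")
        results["broader"] = broader["result"].to_dict()

    # -- lifetime Markov projection ---------------------------------------
    if config.run_markov:
        spec = markov_mod.default_markov_spec()
        spec.arm_quit_prob = {"control": summary.rate_control,
                              "intervention": summary.rate_intervention}
        spec.treatment_cost = mean_tc
        life = markov_mod.lifetime_icer(spec)
        psa_res = markov_mod.psa(
            spec, markov_mod.default_psa_spec(spec, n_simulations=config.n_psa,
                                              seed=config.seed + 11))
        results["lifetime"] = {
            "cost_control": life.cost_control,
            "cost_intervention": life.cost_intervention,
            "qalys_control": life.qalys_control,
            "qalys_intervention": life.qalys_intervention,
            "delta_cost": life.delta_cost,
            "delta_qaly": life.delta_qaly,
            "icer_tag": life.icer.tag,
            "icer_value": life.icer.value,
            "psa_ceac": {str(k): v for k, v in psa_res.ceac.items()},
        }
        psa_res.to_csv(emit("psa_draws.csv"))
        for arm in ("control", "intervention"):
            markov_mod.run_cohort(spec, arm).to_csv(emit(f"trace_{arm}.csv"))

    # -- figures -----------------------------------------------------------
    if config.make_figures:
        _figures(primary["result"], out, outputs)

    (out / "results.json").write_text(
        json.dumps(results, indent=2, default=_json_default))
    outputs.append("results.json")

    manifest = RunManifest(
        config={"pipeline": {k: v for k, v in dataclasses.asdict(config).items()
                             if k != "trial"},
                "trial": dataclasses.asdict(config.trial)},
        seed=config.seed, started=started, finished=time.time(),
        outputs=sorted(set(outputs)))
    manifest.write(out / "manifest.json")
    return manifest


def _figures(result: cua.IncrementalResult, out: Path,
             outputs: list[str]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cloud = cua.cep(result.draws)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(cloud["delta_qaly"], cloud["delta_cost"], s=4, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    for lam in (20_000, 30_000):
        xs = np.array(ax.get_xlim())
        ax.plot(xs, lam * xs, ls="--", lw=0.8, label=f"£{lam:,}/QALY")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (£)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "cep.png", dpi=150)
    plt.close(fig)
    outputs.append("cep.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    lams = sorted(result.ceac)
    ax.plot(lams, [result.ceac[k] for k in lams])
    ax.set_xlabel("Willingness to pay (£/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(out / "ceac.png", dpi=150)
    plt.close(fig)
    outputs.append("ceac.png")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
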