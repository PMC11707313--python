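"""Lifetime three-state Markov cohort model for smoking cessation.

States are smoker / ex-smoker / dead on annual cycles.  A cohort (default
1000) enters at the trial mean age split into ex-smokers (the arm's 6-month
quit probability) and continuing smokers, and is followed until age 90 or
death.  Smokers face the background mortality of their age and sex scaled
by a relative risk, may quit at a natural annual rate, and accrue an annual
smoking-attributable cost; ex-smokers face background mortality, may
relapse, and accrue no smoking-attributable cost.  Per-cycle costs and
utility-weighted life years are discounted (default 3.5%/year, first cycle
undiscounted) and summed.  Sex is handled by running female and male
sub-cohorts weighted by the cohort sex mix, because the mortality, cost and
utility schedules are sex-specific.

Parameter uncertainty is propagated by Monte-Carlo probabilistic
sensitivity analysis: each simulation draws the uncertain parameters from
their assigned distributions (beta for probabilities, lognormal for
relative risks, gamma for cost scalings by convention), reruns both arms,
and the resulting (Δcost, ΔQALY) cloud feeds the acceptability curve.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cua import ICERResult, ceac as _ceac, icer as _icer

__all__ = ["AgeSchedule", "MarkovSpec", "CohortTrace", "PSASpec",
           "transition_matrix", "run_cohort", "lifetime_icer",
           "smoking_attributable_cost", "psa", "default_markov_spec"]

STATES = ("smoker", "ex_smoker", "dead")
MAX_TABLE_AGE = 110


class AgeSchedule:
    """A piecewise-constant annual quantity by age, expanded to a per-age
    vector over 0..110 for O(1) lookup."""

    def __init__(self, bands: list[dict]):
        if not bands:
            raise ValueError("age schedule needs at least one band")
        values = np.empty(MAX_TABLE_AGE + 1)
        bands = sorted(bands, key=lambda b: b["age_from"])
        if bands[0]["age_from"] > 0:
            raise ValueError("first band must start at age 0")
        for i, band in enumerate(bands):
            start = int(band["age_from"])
            stop = int(bands[i + 1]["age_from"]) if i + 1 < len(bands) else MAX_TABLE_AGE + 1
            values[start:stop] = float(band["value"])
        self.values = values

    @classmethod
    def constant(cls, value: float) -> "AgeSchedule":
        return cls([{"age_from": 0, "value": value}])

    def __call__(self, age: float) -> float:
        return float(self.values[min(int(age), MAX_TABLE_AGE)])

    def scaled(self, factor: float) -> "AgeSchedule":
        out = copy.copy(self)
        out.values = self.values * factor
        return out


@dataclass
class GompertzMortality:
    """Annual death probability a*exp(b*age), capped at 1."""

    a: float
    b: float

    def __call__(self, age: float) -> float:
        return float(min(1.0, self.a * np.exp(self.b * age)))


@dataclass
class MarkovSpec:
    """All parameters of the lifetime model.

    ``mortality``, ``sac`` (smoking-attributable cost while a smoker) and
    ``utility_weights`` are per-sex lookups by age; ``utility_weights`` is
    further keyed by smoking status.  ``arm_quit_prob`` carries the 6-month
    quit probability each arm feeds into the model; ``treatment_cost`` is
    added once at entry, undiscounted.
    """

    start_age: float = 40.5
    max_age: float = 90.0
    sex_mix_female: float = 0.38
    cohort_size: int = 1000
    discount_rate: float = 0.035
    rr_smoker_death: float = 2.0
    natural_quit_rate: float = 0.02
    relapse_rate: float = 0.08
    mortality: dict = field(default_factory=dict)        # sex -> callable(age)
    sac: dict = field(default_factory=dict)              # sex -> AgeSchedule
    utility_weights: dict = field(default_factory=dict)  # sex -> status -> AgeSchedule
    arm_quit_prob: dict = field(
        default_factory=lambda: {"control": 0.041, "intervention": 0.072})
    treatment_cost: dict = field(
        default_factory=lambda: {"control": 0.0, "intervention": 0.0})

    def validate(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")
        if self.rr_smoker_death < 0:
            raise ValueError("rr_smoker_death must be non-negative")
        for p, name in ((self.natural_quit_rate, "natural_quit_rate"),
                        (self.relapse_rate, "relapse_rate"),
                        (self.sex_mix_female, "sex_mix_female")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for arm, p in self.arm_quit_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"arm_quit_prob[{arm}] must be in [0, 1]")
        if self.max_age <= self.start_age:
            raise ValueError("max_age must exceed start_age")
        for sex in ("female", "male"):
            if sex not in self.mortality or sex not in self.sac:
                raise ValueError(f"missing mortality/sac tables for sex {sex!r}")
            for status in ("smoker", "ex_smoker"):
                if status not in self.utility_weights.get(sex, {}):
                    raise ValueError(
                        f"missing utility weights for ({sex}, {status})")

    @classmethod
    def from_yaml(cls, path) -> "MarkovSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mortality = {
            sex: GompertzMortality(a=float(p["gompertz_a"]),
                                   b=float(p["gompertz_b"]))
            for sex, p in raw["mortality"].items()
        }
        sac = {sex: AgeSchedule(bands)
               for sex, bands in raw["smoking_attributable_cost"].items()}
        uw = {sex: {status: AgeSchedule(bands)
                    for status, bands in statuses.items()}
              for sex, statuses in raw["utility_weights"].items()}
        spec = cls(
            start_age=float(raw["start_age"]),
            max_age=float(raw["max_age"]),
            sex_mix_female=float(raw["sex_mix_female"]),
            cohort_size=int(raw["cohort_size"]),
            discount_rate=float(raw["discount_rate"]),
            rr_smoker_death=float(raw["rr_smoker_death"]),
            natural_quit_rate=float(raw["natural_quit_rate"]),
            relapse_rate=float(raw["relapse_rate"]),
            mortality=mortality,
            sac=sac,
            utility_weights=uw,
            arm_quit_prob={k: float(v) for k, v in raw["arm_quit_prob"].items()},
            treatment_cost={k: float(v)
                            for k, v in raw.get("treatment_cost", {}).items()},
        )
        spec.validate()
        return spec


def default_markov_spec() -> MarkovSpec:
    """The packaged parameter set (synthetic placeholder schedules)."""
    with resources.as_file(
        resources.files("quitcost.data") / "markov_params.yaml"
    ) as p:
        return MarkovSpec.from_yaml(p)


def transition_matrix(age: float, sex: str, spec: MarkovSpec) -> np.ndarray:
    """Annual transition matrix at one age for one sex.

    Rows/columns ordered (smoker, ex-smoker, dead).  Smoker death is
    background mortality x relative risk, capped at 1; quitting applies to
    smokers who survive the year; relapse likewise to surviving ex-smokers;
    dead is absorbing.  Rows sum to 1 to within 1e-12.
    """
    m = spec.mortality[sex](age)
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"mortality {m} out of [0, 1] at age {age}, sex {sex}")
    die_smoker = min(1.0, m * spec.rr_smoker_death)
    quit = spec.natural_quit_rate * (1.0 - die_smoker)
    relapse = spec.relapse_rate * (1.0 - m)
    P = np.array([
        [1.0 - die_smoker - quit, quit, die_smoker],
        [relapse, 1.0 - relapse - m, m],
        [0.0, 0.0, 1.0],
    ])
    if (P < -1e-12).any():
        raise ValueError(
            f"negative transition probability at age {age}, sex {sex}: {P}")
    rowsum_err = np.abs(P.sum(axis=1) - 1.0).max()
    if rowsum_err > 1e-12:
        raise ValueError(f"transition rows do not sum to 1 (err {rowsum_err})")
    return P


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and discounted accumulators for one arm."""

    arm: str
    occupancy: pd.DataFrame      # columns smoker, ex_smoker, dead per cycle
    cost_increments: np.ndarray  # discounted, per cycle
    qaly_increments: np.ndarray  # discounted, per cycle
    cohort_size: int

    @property
    def total_cost(self) -> float:
        return float(self.cost_increments.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qaly_increments.sum())

    @property
    def per_person_cost(self) -> float:
        return self.total_cost / self.cohort_size

    @property
    def per_person_qalys(self) -> float:
        return self.total_qalys / self.cohort_size

    def to_csv(self, path) -> None:
        df = self.occupancy.copy()
        df["cost_increment"] = self.cost_increments
        df["qaly_increment"] = self.qaly_increments
        df.to_csv(path, index_label="cycle")


def run_cohort(spec: MarkovSpec, arm: str) -> CohortTrace:
    """Project one arm's cohort to ``max_age``.

    The cohort enters split by the arm's quit probability (quitters start
    as ex-smokers).  Each cycle accrues smoker-occupancy x
    smoking-attributable cost and occupancy-weighted utility, discounted at
    ``(1 + r)^-t`` with the first cycle at t = 0, then transitions.
    Female and male sub-cohorts run separately and are summed.
    """
    spec.validate()
    if arm not in spec.arm_quit_prob:
        raise KeyError(f"no quit probability for arm {arm!r}")
    quit_p = spec.arm_quit_prob[arm]
    n_cycles = int(np.ceil(spec.max_age - spec.start_age))
    weights = {"female": spec.sex_mix_female, "male": 1.0 - spec.sex_mix_female}

    occ_total = np.zeros((n_cycles, 3))
    cost_inc = np.zeros(n_cycles)
    qaly_inc = np.zeros(n_cycles)
    for sex, w in weights.items():
        if w == 0.0:
            continue
        n = spec.cohort_size * w
        state = np.array([n * (1.0 - quit_p), n * quit_p, 0.0])
        for t in range(n_cycles):
            age = spec.start_age + t
            disc = (1.0 + spec.discount_rate) ** -t
            occ_total[t] += state
            cost_inc[t] += disc * state[0] * spec.sac[sex](age)
            u_s = spec.utility_weights[sex]["smoker"](age)
            u_e = spec.utility_weights[sex]["ex_smoker"](age)
            qaly_inc[t] += disc * (state[0] * u_s + state[1] * u_e)
            state = state @ transition_matrix(age, sex, spec)
    occupancy = pd.DataFrame(occ_total, columns=list(STATES))
    return CohortTrace(arm=arm, occupancy=occupancy, cost_increments=cost_inc,
                       qaly_increments=qaly_inc, cohort_size=spec.cohort_size)


@dataclass
class LifetimeResult:
    """Per-person discounted lifetime totals and the incremental comparison."""

    cost_control: float
    cost_intervention: float
    qalys_control: float
    qalys_intervention: float
    delta_cost: float
    delta_qaly: float
    icer: ICERResult


def lifetime_icer(spec: MarkovSpec, quit_control: float | None = None,
                  quit_intervention: float | None = None) -> LifetimeResult:
    """Run both arms and form the lifetime incremental comparison.

    Per-person treatment costs are added once at entry, undiscounted.
    Quit probabilities default to those on the spec.
    """
    work = copy.deepcopy(spec)
    if quit_control is not None:
        work.arm_quit_prob["control"] = quit_control
    if quit_intervention is not None:
        work.arm_quit_prob["intervention"] = quit_intervention
    for arm, p in work.arm_quit_prob.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"quit probability for {arm} outside [0, 1]")
    traces = {arm: run_cohort(work, arm) for arm in ("control", "intervention")}
    costs = {arm: traces[arm].per_person_cost + work.treatment_cost.get(arm, 0.0)
             for arm in traces}
    qalys = {arm: traces[arm].per_person_qalys for arm in traces}
    dc = costs["intervention"] - costs["control"]
    dq = qalys["intervention"] - qalys["control"]
    return LifetimeResult(
        cost_control=costs["control"], cost_intervention=costs["intervention"],
        qalys_control=qalys["control"], qalys_intervention=qalys["intervention"],
        delta_cost=dc, delta_qaly=dq, icer=_icer(dc, dq))


def smoking_attributable_cost(prevalence: float, rr_disease: float,
                              total_cost: float) -> float:
    """Smoking-attributable share of a disease cost.

    Attributable fraction = p(RR-1) / (1 + p(RR-1)) at smoking prevalence p;
    returns the fraction times the total cost.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if rr_disease < 0:
        raise ValueError("relative risk must be non-negative")
    excess = prevalence * (rr_disease - 1.0)
    fraction = excess / (1.0 + excess)
    return fraction * total_cost


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis
# --------------------------------------------------------------------------

_SCALAR_PARAMS = {"rr_smoker_death", "natural_quit_rate", "relapse_rate"}
_QUIT_PARAMS = {"quit_control": "control", "quit_intervention": "intervention"}


@dataclass
class PSASpec:
    """Distributions for the uncertain parameters.

    ``distributions`` maps parameter name to a spec dict, e.g.
    ``{"dist": "beta", "alpha": 35, "beta": 449}`` for probabilities,
    ``{"dist": "lognormal", "mu": 0.69, "sigma": 0.1}`` for relative risks,
    ``{"dist": "gamma", "shape": 100, "scale": 0.01}`` for the
    ``sac_multiplier`` cost scaling, or ``{"dist": "fixed", "value": x}``.
    Recognized parameters: rr_smoker_death, natural_quit_rate, relapse_rate,
    quit_control, quit_intervention, sac_multiplier.
    """

    distributions: dict
    n_simulations: int = 1000
    seed: int = 0
    max_resample: int = 100

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        known = _SCALAR_PARAMS | set(_QUIT_PARAMS) | {"sac_multiplier"}
        unknown = set(self.distributions) - known
        if unknown:
            raise ValueError(f"unknown PSA parameters: {sorted(unknown)}")


def _draw_param(rng: np.random.Generator, dist: dict) -> float:
    kind = dist["dist"]
    if kind == "beta":
        return float(rng.beta(dist["alpha"], dist["beta"]))
    if kind == "lognormal":
        return float(rng.lognormal(dist["mu"], dist["sigma"]))
    if kind == "gamma":
        return float(rng.gamma(dist["shape"], dist["scale"]))
    if kind == "fixed":
        return float(dist["value"])
    raise ValueError(f"unknown distribution kind: {kind!r}")


@dataclass
class PSAResult:
    draws: np.ndarray            # (n, 2): Δcost, ΔQALY
    ceac: dict[float, float]
    parameter_draws: pd.DataFrame

    def to_csv(self, path) -> None:
        df = self.parameter_draws.copy()
        df["delta_cost"] = self.draws[:, 0]
        df["delta_qaly"] = self.draws[:, 1]
        df.to_csv(path, index=False)


def psa(spec: MarkovSpec, psa_spec: PSASpec,
        thresholds=None) -> PSAResult:
    """Monte-Carlo parameter uncertainty through the lifetime model.

    Each simulation redraws the uncertain parameters (invalid probability
    draws are resampled up to a cap), reruns both arms, and records the
    per-person (Δcost, ΔQALY) pair; the acceptability curve is computed
    from the full draw set.  Deterministic under ``psa_spec.seed``.
    """
    from .cua import DEFAULT_THRESHOLDS

    spec.validate()
    rng = np.random.default_rng(psa_spec.seed)
    n = psa_spec.n_simulations
    draws = np.empty((n, 2))
    param_rows = []
    prob_params = (_SCALAR_PARAMS - {"rr_smoker_death"}) | set(_QUIT_PARAMS)
    for i in range(n):
        params = {}
        for name, dist in psa_spec.distributions.items():
            value = _draw_param(rng, dist)
            tries = 0
            while name in prob_params and not 0.0 <= value <= 1.0:
                tries += 1
                if tries > psa_spec.max_resample:
                    raise RuntimeError(
                        f"PSA draw for {name!r} out of [0, 1] after "
                        f"{psa_spec.max_resample} resamples")
                value = _draw_param(rng, dist)
            params[name] = value
        sim = copy.deepcopy(spec)
        for name in _SCALAR_PARAMS & set(params):
            setattr(sim, name, params[name])
        for name, arm in _QUIT_PARAMS.items():
            if name in params:
                sim.arm_quit_prob[arm] = params[name]
        if "sac_multiplier" in params:
            sim.sac = {sex: sched.scaled(params["sac_multiplier"])
                       for sex, sched in sim.sac.items()}
        res = lifetime_icer(sim)
        draws[i] = (res.delta_cost, res.delta_qaly)
        param_rows.append(params)
    curve = _ceac(draws, DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    return PSAResult(draws=draws, ceac=curve,
                     parameter_draws=pd.DataFrame(param_rows))


def default_psa_spec(spec: MarkovSpec, n_simulations: int = 1000,
                     seed: int = 0) -> PSASpec:
    """A PSA around the spec's point values: beta for probabilities (moment
    matched at modest effective sample sizes), lognormal for the mortality
    relative risk, gamma (mean 1) for the cost scaling."""

    def beta_for(p: float, ess: float = 400.0) -> dict:
        p = min(max(p, 1e-4), 1 - 1e-4)
        return {"dist": "beta", "alpha": p * ess, "beta": (1 - p) * ess}

    return PSASpec(
        distributions={
            "rr_smoker_death": {"dist": "lognormal",
                                "mu": float(np.log(spec.rr_smoker_death)),
                                "sigma": 0.1},
            "natural_quit_rate": beta_for(spec.natural_quit_rate),
            "relapse_rate": beta_for(spec.relapse_rate),
            "quit_control": beta_for(spec.arm_quit_prob["control"], ess=488),
            "quit_intervention": beta_for(spec.arm_quit_prob["intervention"],
                                          ess=484),
            "sac_multiplier": {"dist": "gamma", "shape": 100.0, "scale": 0.01},
        },
        n_simulations=n_simulations,
        seed=seed,
    )
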