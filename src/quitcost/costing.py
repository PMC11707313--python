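"""Micro-costing engine.

Builds up the per-participant cost of the intervention (staff training,
carbon-monoxide monitors, e-cigarette starter kits, printed materials and
brief-advice staff time) and values self-reported resource use against a
unit-cost schedule.  All monetary values are GBP at 2021/22 prices.

The packaged unit-cost schedule (``data/unit_costs.csv``) covers prescribed
pharmacotherapies, smoking-cessation advice contacts and primary/secondary
healthcare services; counts must be supplied in the table's own unit
(``unit_label`` column), e.g. packs for nicotine patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TrainerSession",
    "TraineeSpec",
    "InterventionCostSpec",
    "UnitCostTable",
    "CostBreakdown",
    "training_cost",
    "advice_cost",
    "equipment_cost",
    "intervention_cost_per_participant",
    "value_resource_use",
    "default_intervention_spec",
    "CONTROL_CARD_COST",
]

#: Printing cost of the control-arm information card, per card (GBP).
CONTROL_CARD_COST = 0.20

#: Cost of CO monitors and mouthpieces over the trial period, carried as a
#: printed constant (see :func:`equipment_cost` for recomputation options).
DEFAULT_EQUIPMENT_TOTAL = 276.30

VALID_CATEGORIES = {"pharmacotherapy", "cessation-advice", "healthcare"}


@dataclass(frozen=True)
class TrainerSession:
    """One delivered training session: staff cost per hour x session length."""

    hourly_cost: float
    hours: float

    def __post_init__(self) -> None:
        if self.hourly_cost < 0 or self.hours < 0:
            raise ValueError("trainer session costs and hours must be non-negative")


@dataclass(frozen=True)
class TraineeSpec:
    """Opportunity cost of trainee time: hourly cost x total hours x headcount."""

    hourly_cost: float
    hours_total: float
    n_trainees: int

    def __post_init__(self) -> None:
        if self.hourly_cost < 0 or self.hours_total < 0 or self.n_trainees < 0:
            raise ValueError("trainee spec values must be non-negative")


@dataclass
class InterventionCostSpec:
    """Complete intervention cost build-up for one trial arm.

    ``advice_minutes`` may be a scalar mean or a per-participant list; the
    per-participant total is ``advice_cost`` applied element-wise.
    """

    trainer_sessions: list[TrainerSession] = field(default_factory=list)
    trainee: TraineeSpec | None = None
    equipment_total: float = 0.0
    kit_price: float = 0.0
    kit_recipients: int = 0
    leaflet_price: float = 0.0
    bag_price: float = 0.0
    advice_hourly_cost: float = 0.0
    advice_minutes: float | list[float] = 0.0
    n_participants: int = 1

    def __post_init__(self) -> None:
        for name in ("equipment_total", "kit_price", "leaflet_price", "bag_price",
                     "advice_hourly_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.kit_recipients < 0 or self.kit_recipients > self.n_participants:
            raise ValueError("kit_recipients must be in [0, n_participants]")


def training_cost(spec: InterventionCostSpec) -> float:
    """Total opportunity cost of staff training (GBP).

    Sum over trainer sessions of hourly cost x hours, plus trainee hourly
    cost x total training hours x number of trainees.
    """
    total = sum(s.hourly_cost * s.hours for s in spec.trainer_sessions)
    if spec.trainee is not None:
        t = spec.trainee
        total += t.hourly_cost * t.hours_total * t.n_trainees
    return total


def advice_cost(minutes: float, hourly_cost: float) -> float:
    """Staff-time cost of one brief-advice contact: minutes x hourly cost / 60."""
    if minutes < 0:
        raise ValueError("minutes must be non-negative")
    if hourly_cost < 0:
        raise ValueError("hourly_cost must be non-negative")
    return minutes * hourly_cost / 60.0


def _annuity_factor(life_years: float, rate: float) -> float:
    if rate == 0:
        return life_years
    return (1.0 - (1.0 + rate) ** -life_years) / rate


def equipment_cost(
    device_price: float,
    n_devices: int,
    life_years: float,
    annual_rate: float,
    period_years: float,
    consumables: float = 0.0,
    convention: str = "straight_line",
) -> float:
    """Depreciated equipment cost over a use period, plus consumables.

    ``straight_line`` charges price x period/life per device; ``annuity``
    charges the equivalent annual cost (price / annuity factor at
    ``annual_rate`` over ``life_years``) x period.  The default pipeline does
    not call this: it carries the trial-period monitor total as the input
    constant ``DEFAULT_EQUIPMENT_TOTAL`` because the published figure is not
    exactly reproduced by either textbook convention.
    """
    if life_years <= 0:
        raise ValueError("life_years must be positive")
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    if period_years > life_years:
        raise ValueError("period_years cannot exceed life_years")
    if convention == "straight_line":
        per_device = device_price * period_years / life_years
    elif convention == "annuity":
        per_device = device_price / _annuity_factor(life_years, annual_rate) * period_years
    else:
        raise ValueError(f"unknown depreciation convention: {convention!r}")
    return per_device * n_devices + consumables


def intervention_cost_per_participant(
    spec: InterventionCostSpec,
) -> tuple[float, dict[str, float]]:
    """Mean intervention cost per randomized participant with its breakdown.

    Returns ``(mean_total, components)`` where ``components`` maps component
    name to its per-participant mean.  Training and equipment are spread over
    all randomized participants; kits over the participants who received one
    (expressed per randomized participant); leaflets and bags are given to
    every randomized participant.
    """
    n = spec.n_participants
    mins = spec.advice_minutes
    if isinstance(mins, (int, float)):
        advice_total = advice_cost(float(mins), spec.advice_hourly_cost) * n
    else:
        advice_total = sum(advice_cost(m, spec.advice_hourly_cost) for m in mins)
    components = {
        "training": training_cost(spec) / n,
        "equipment": spec.equipment_total / n,
        "starter_kit": spec.kit_price * spec.kit_recipients / n,
        "leaflet": spec.leaflet_price,
        "tote_bag": spec.bag_price,
        "brief_advice": advice_total / n,
    }
    return sum(components.values()), components


def default_intervention_spec() -> InterventionCostSpec:
    """Cost build-up of the delivered intervention arm (n = 484).

    Two research-team trainers (£32.28 and £29.50/h) each delivered a 3-hour
    bespoke session; two stop-smoking advisers (£18.01/h) delivered a 2-hour
    generic session; 27 band-4 trainees (£19.06/h) spent 12.5 hours each
    (7.5 h e-learning + 3 h bespoke + 2 h generic).  483 of 484 participants
    received a £23.15 starter kit; every participant received a £0.39
    leaflet and £1.47 tote bag plus a mean 25.7 minutes of brief advice at
    band-4 staff cost.
    """
    return InterventionCostSpec(
        trainer_sessions=[
            TrainerSession(hourly_cost=32.28, hours=3.0),
            TrainerSession(hourly_cost=29.50, hours=3.0),
            TrainerSession(hourly_cost=18.01, hours=2.0),
            TrainerSession(hourly_cost=18.01, hours=2.0),
        ],
        trainee=TraineeSpec(hourly_cost=19.06, hours_total=12.5, n_trainees=27),
        equipment_total=DEFAULT_EQUIPMENT_TOTAL,
        kit_price=23.15,
        kit_recipients=483,
        leaflet_price=0.39,
        bag_price=1.47,
        advice_hourly_cost=19.06,
        advice_minutes=25.7,
        n_participants=484,
    )


class UnitCostTable:
    """Schedule mapping resource item codes to money per unit.

    Columns: ``item_code`` (unique), ``unit_cost_gbp`` (>= 0), ``unit_label``,
    ``category`` (pharmacotherapy | cessation-advice | healthcare) and, for
    healthcare items, ``care_level`` (primary | secondary).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"item_code", "unit_cost_gbp", "unit_label", "category"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"unit cost table missing columns: {sorted(missing)}")
        if table["item_code"].duplicated().any():
            dupes = table.loc[table["item_code"].duplicated(), "item_code"].tolist()
            raise ValueError(f"duplicate item codes: {dupes}")
        if (table["unit_cost_gbp"] < 0).any():
            raise ValueError("unit costs must be non-negative")
        bad = set(table["category"]) - VALID_CATEGORIES
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        self._df = table.reset_index(drop=True)
        self._index = table.set_index("item_code")

    @classmethod
    def from_csv(cls, path) -> "UnitCostTable":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "UnitCostTable":
        """The packaged 2021/22 schedule."""
        with resources.as_file(
            resources.files("quitcost.data") / "unit_costs.csv"
        ) as p:
            return cls.from_csv(p)

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def scaled(self, factor: float) -> "UnitCostTable":
        """A copy with every unit cost multiplied by ``factor`` (e.g. a
        scalar inflation adjustment to another cost year)."""
        df = self._df.copy()
        df["unit_cost_gbp"] *= factor
        return UnitCostTable(df)

    def __contains__(self, item_code: str) -> bool:
        return item_code in self._index.index

    def unit_cost(self, item_code: str) -> float:
        try:
            return float(self._index.at[item_code, "unit_cost_gbp"])
        except KeyError:
            raise KeyError(f"unknown resource item code: {item_code!r}") from None

    def category(self, item_code: str) -> str:
        try:
            return str(self._index.at[item_code, "category"])
        except KeyError:
            raise KeyError(f"unknown resource item code: {item_code!r}") from None

    def care_level(self, item_code: str) -> str | None:
        lvl = self._index.at[item_code, "care_level"]
        return None if pd.isna(lvl) else str(lvl)

    @property
    def item_codes(self) -> list[str]:
        return self._df["item_code"].tolist()


@dataclass
class CostBreakdown:
    """Per-participant costs by payer-perspective category (GBP).

    ``total_nhs_pss`` is the health-and-social-care payer total; the
    participant's own spending on NRT/e-cigarettes is carried alongside but
    excluded from it.
    """

    treatment: float = 0.0
    cessation_support: float = 0.0
    primary_care: float = 0.0
    secondary_care: float = 0.0
    spending_nrt_ecig: float = 0.0

    @property
    def total_nhs_pss(self) -> float:
        return (self.treatment + self.cessation_support
                + self.primary_care + self.secondary_care)

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            treatment=self.treatment + other.treatment,
            cessation_support=self.cessation_support + other.cessation_support,
            primary_care=self.primary_care + other.primary_care,
            secondary_care=self.secondary_care + other.secondary_care,
            spending_nrt_ecig=self.spending_nrt_ecig + other.spending_nrt_ecig,
        )

    def as_dict(self) -> dict[str, float]:
        d = {
            "treatment": self.treatment,
            "cessation_support": self.cessation_support,
            "primary_care": self.primary_care,
            "secondary_care": self.secondary_care,
            "spending_nrt_ecig": self.spending_nrt_ecig,
        }
        d["total_nhs_pss"] = self.total_nhs_pss
        return d


def value_resource_use(
    counts: Mapping[str, float],
    table: UnitCostTable,
    arm: str | None = None,
) -> CostBreakdown:
    """Value resource-use counts against a unit-cost schedule.

    Pharmacotherapy and cessation-advice items accrue to cessation support;
    healthcare items split into primary vs secondary care by the table's
    ``care_level``.  When ``arm == "control"`` the information-card printing
    cost is added to treatment.  Unknown item codes raise ``KeyError`` naming
    the offending code.
    """
    out = CostBreakdown()
    for code, qty in counts.items():
        if qty < 0:
            raise ValueError(f"negative quantity for {code!r}")
        cost = table.unit_cost(code) * qty
        cat = table.category(code)
        if cat in ("pharmacotherapy", "cessation-advice"):
            out.cessation_support += cost
        else:  # healthcare
            level = table.care_level(code)
            if level == "primary":
                out.primary_care += cost
            elif level == "secondary":
                out.secondary_care += cost
            else:
                raise ValueError(
                    f"healthcare item {code!r} has no care_level (primary/secondary)"
                )
    if arm == "control":
        out.treatment += CONTROL_CARD_COST
    return out
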