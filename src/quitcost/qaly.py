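"""Utility handling and QALY construction.

Health states are EQ-5D-5L descriptors: five digits, one per domain
(mobility, self-care, usual activities, pain/discomfort, anxiety/depression),
each at level 1 (no problems) to 5 (extreme problems).  A value set maps
each of the 3125 states to a utility anchored at 1 = full health, 0 = dead;
states worse than dead take negative values.  QALYs over the trial window
come from the area under the utility curve between baseline and follow-up.

Country value sets are licensed and not redistributable, so the packaged
default is a clearly-labelled synthetic linear set; any tariff can be
plugged in as a (state, utility) CSV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

__all__ = ["ValueSet", "UtilityProfile", "utility_from_state", "qaly_auc",
           "toy_value_set"]

N_STATES = 5 ** 5


def _validate_state(state: str) -> str:
    s = str(state)
    if len(s) != 5 or any(c not in "12345" for c in s):
        raise ValueError(f"malformed EQ-5D-5L state descriptor: {state!r}")
    return s


class ValueSet:
    """A total mapping from 5-digit EQ-5D-5L states to utilities.

    The mapping must cover all 3125 states and anchor 11111 at exactly 1.0.
    ``feasible_range`` is (floor, 1.0) where floor is the worst-state value.
    """

    def __init__(self, mapping: dict[str, float], label: str = "custom"):
        if len(mapping) != N_STATES:
            raise ValueError(
                f"value set must cover all {N_STATES} states, got {len(mapping)}"
            )
        for state in mapping:
            _validate_state(state)
        if mapping["11111"] != 1.0:
            raise ValueError("state 11111 must map to utility 1.0")
        self._mapping = dict(mapping)
        self.label = label
        self.floor = min(mapping.values())

    @property
    def feasible_range(self) -> tuple[float, float]:
        return (self.floor, 1.0)

    def __getitem__(self, state: str) -> float:
        return self._mapping[_validate_state(state)]

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "ValueSet":
        df = pd.read_csv(path, comment="#", dtype={"state": str})
        mapping = dict(zip(df["state"], df["utility"].astype(float)))
        return cls(mapping, label=label or "csv")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"state": list(self._mapping), "utility": list(self._mapping.values())}
        ).to_csv(path, index=False)


def toy_value_set(decrement: float = 0.05) -> ValueSet:
    """Synthetic linear tariff for testing: 1 - decrement x sum(levels - 1).

    Not a published country tariff; its floor at the default decrement is
    1 - 0.05 x 20 = 0.
    """
    mapping = {
        "".join(map(str, levels)): 1.0 - decrement * (sum(levels) - 5)
        for levels in itertools.product(range(1, 6), repeat=5)
    }
    return ValueSet(mapping, label=f"toy-linear(decrement={decrement})")


def utility_from_state(state: str, vs: ValueSet) -> float:
    """Look up the utility of one 5-digit descriptor under a value set."""
    return vs[state]


@dataclass(frozen=True)
class UtilityProfile:
    """Utilities at the two measurement points spanning ``horizon_years``."""

    u_baseline: float
    u_6m: float
    horizon_years: float = 0.5

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")


def qaly_auc(p: UtilityProfile) -> float:
    """QALYs by trapezoidal area under the utility curve.

    Linear interpolation between the two utilities over the horizon:
    ``horizon_years x (u_baseline + u_6m) / 2``.  No discounting (the trial
    window is six months).
    """
    return p.horizon_years * (p.u_baseline + p.u_6m) / 2.0
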