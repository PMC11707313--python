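import numpy as np
import pandas as pd
import pytest

from quitcost.markov import AgeSchedule, MarkovSpec
from quitcost.trialgen import default_trial_config, generate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A small complete-data synthetic trial (no missingness)."""
    cfg = default_trial_config(
        seed=11, n_control=150, n_intervention=150, n_sites=3,
        followup_prob={"control": 1.0, "intervention": 1.0},
        mar_coefficients={}, item_missing_prob=0.0, baseline_missing_prob=0.0)
    return generate_trial(cfg).records


@pytest.fixture(scope="session")
def mar_trial():
    """A trial with differential MAR follow-up, for imputation tests."""
    cfg = default_trial_config(seed=7, n_control=300, n_intervention=300,
                               n_sites=3)
    return generate_trial(cfg).records


def constant_spec(mortality: float = 0.0, sac: float = 0.0,
                  utility: float = 1.0, utility_ex: float | None = None,
                  quit: float = 0.0, relapse: float = 0.0, rr: float = 1.0,
                  discount: float = 0.0, start_age: float = 40.0,
                  max_age: float = 50.0, cohort: int = 1000,
                  sex_mix: float = 0.0,
                  quit_control: float = 0.0,
                  quit_intervention: float = 0.0) -> MarkovSpec:
    """Markov spec with age-constant schedules, for closed-form checks."""

    class ConstMortality:
        def __init__(self, q):
            self.q = q

        def __call__(self, age):
            return self.q

    uw = {"smoker": AgeSchedule.constant(utility),
          "ex_smoker": AgeSchedule.constant(
              utility if utility_ex is None else utility_ex)}
    return MarkovSpec(
        start_age=start_age, max_age=max_age, sex_mix_female=sex_mix,
        cohort_size=cohort, discount_rate=discount, rr_smoker_death=rr,
        natural_quit_rate=quit, relapse_rate=relapse,
        mortality={s: ConstMortality(mortality) for s in ("female", "male")},
        sac={s: AgeSchedule.constant(sac) for s in ("female", "male")},
        utility_weights={s: dict(uw) for s in ("female", "male")},
        arm_quit_prob={"control": quit_control,
                       "intervention": quit_intervention},
    )


@pytest.fixture
def toy_counts_dataset():
    """Arm/outcome table matching the published abstinence counts:
    20/488 control and 35/484 intervention CO-validated abstainers,
    122/484 self-reported in the intervention arm."""
    rows = []
    for arm, n, a_co, a_sr in [("control", 488, 20, 64),
                               ("intervention", 484, 35, 122)]:
        for i in range(n):
            rows.append({"arm": arm,
                         "abstinent_co": 1.0 if i < a_co else 0.0,
                         "abstinent_sr": 1.0 if i < a_sr else 0.0})
    return pd.DataFrame(rows)


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
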