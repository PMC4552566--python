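import numpy as np
import pandas as pd
import pytest

import metakin as mk


def toy_cohort_frame() -> pd.DataFrame:
    """2 subjects x 1 metabolite, stages rest / 50 W / 75 W / recovery."""
    rows = []
    for sid, base in (("1", 10.0), ("2", 20.0)):
        for stage, w, t, c in (
            ("rest", np.nan, 0.0, base),
            ("50W", 50.0, 2.5, base * 1.1),
            ("75W", 75.0, 5.5, base * 1.2),
            ("recovery", np.nan, 11.0, base * 1.15),
        ):
            rows.append(
                {
                    "subject_id": sid,
                    "group": "male_average",
                    "metabolite": "alanine",
                    "stage": stage,
                    "workload_w": w,
                    "time_min": t,
                    "concentration_um": c,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    return toy_cohort_frame()


@pytest.fixture
def toy_cohort(toy_frame) -> mk.Cohort:
    return mk.Cohort(toy_frame)


@pytest.fixture(scope="session")
def demo_config() -> mk.SimulationConfig:
    return mk.SimulationConfig(panel=mk.demo_panel(), seed=7)


@pytest.fixture(scope="session")
def noiseless_cohort(demo_config):
    """47-subject noiseless cohort, one metabolite per kinetic shape."""
    return mk.simulate_cohort(mk.noiseless(demo_config))


@pytest.fixture(scope="session")
def noiseless_results(noiseless_cohort):
    cohort, _ = noiseless_cohort
    return mk.KineticProfileModel(cohort).fit()
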