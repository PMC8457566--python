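import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wormspan.cohort import COLUMNS, CohortTable
from wormspan.datasets import STRAINS
from wormspan.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_cohort(worms, metadata=None) -> CohortTable:
    """Compact cohort builder for hand-written examples.

    Each worm is (worm_id, strain, replicate, stages, terminal[, cause]):
    ``stages`` is the per-day motility string while alive (e.g. "AAB"),
    ``terminal`` is "dead" or "censored" on day ``len(stages)``.
    """
    rows = []
    for worm in worms:
        wid, strain, rep, stages, terminal = worm[:5]
        cause = worm[5] if len(worm) > 5 else ("other" if terminal == "censored" else "none")
        for day, stage in enumerate(stages):
            rows.append((wid, strain, rep, day, "alive", "none", stage))
        rows.append((wid, strain, rep, len(stages), terminal,
                     cause if terminal == "censored" else "none", "not_scored"))
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return CohortTable(df, metadata or {})


@pytest.fixture
def make_cohort():
    return build_cohort


@pytest.fixture(scope="session")
def panel_strains():
    return [STRAINS["WT(EV)"], STRAINS["odr-3"], STRAINS["ife-2"],
            STRAINS["odr-3;ife-2"]]


@pytest.fixture(scope="session")
def sim_cohort(panel_strains):
    """A mid-size simulated panel cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=11), panel_strains)
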