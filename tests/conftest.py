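import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from presbydose import ReferenceCohortCounts, SimulationConfig, simulate_cohort
from presbydose.model import fit_mle

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort300():
    return simulate_cohort(SimulationConfig(n=300, seed=11))


@pytest.fixture(scope="session")
def cohort3000():
    return simulate_cohort(SimulationConfig(n=3000, seed=5))


@pytest.fixture(scope="session")
def mgm_fit(cohort3000):
    return fit_mle(cohort3000, "MGM", ["age"])


@pytest.fixture(scope="session")
def reference_counts():
    return ReferenceCohortCounts()


def counts_to_cohort(counts: ReferenceCohortCounts) -> pd.DataFrame:
    """Expand stratum contingency counts into a patient-level table.

    Ages are placed at each stratum's representative mid-decade value;
    only the (age, outcome) margins matter for the checks using this.
    """
    rep_ages = (45.0, 55.0, 65.0, 75.0)
    rows = []
    for age, n, ev in zip(rep_ages, counts.stratum_n, counts.stratum_events):
        rows.extend({"age": age, "outcome": 1} for _ in range(ev))
        rows.extend({"age": age, "outcome": 0} for _ in range(n - ev))
    df = pd.DataFrame(rows)
    df["patient_id"] = [f"C{i:04d}" for i in range(len(df))]
    return df


@pytest.fixture(scope="session")
def counts_cohort(reference_counts):
    return counts_to_cohort(reference_counts)


def grid_search_logistic(doses, outcome):
    """Brute-force (intercept, dose-slope) MLE by two-stage grid scan.

    The refinement step is sized so that one intercept step matches the
    intercept shift compensating one slope step along the likelihood
    valley; returns (b0, bD, b0_step, bD_step) of the fine-grid argmin.
    """
    from scipy import special

    doses = np.asarray(doses, float)
    outcome = np.asarray(outcome, int)

    def scan(b0_grid, bd_grid):
        B0, BD = np.meshgrid(b0_grid, bd_grid, indexing="ij")
        lp = B0[..., None] + BD[..., None] * doses[None, None, :]
        pr = np.clip(special.expit(lp), 1e-12, 1 - 1e-12)
        nll = -(outcome * np.log(pr) + (1 - outcome) * np.log(1 - pr)).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        return b0_grid[i], bd_grid[j]

    b0c, bdc = scan(np.arange(-25.0, 5.0, 0.05), np.arange(-0.2, 0.6, 0.002))
    b0_step, bd_step = 0.002, 5e-5
    b0f, bdf = scan(np.arange(b0c - 0.2, b0c + 0.2, b0_step),
                    np.arange(bdc - 0.008, bdc + 0.008, bd_step))
    return b0f, bdf, b0_step, bd_step
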