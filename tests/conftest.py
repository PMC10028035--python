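import numpy as np
import pandas as pd
import pytest

from qoltraj import (
    GrowthMixtureSpec,
    QoLPanel,
    SurvivalData,
    default_scenario,
    fit_gmm,
    recovery_scenario,
    simulate_cohort,
)


def make_panel(scores, weeks=None, covariates=None, ids=None):
    scores = np.asarray(scores, dtype=float)
    n, m = scores.shape
    ids = ids or [f"P{i+1}" for i in range(n)]
    weeks = np.asarray(weeks if weeks is not None else [0, 2, 4, 6, 8, 12, 16][:m], float)
    if covariates is None:
        covariates = pd.DataFrame(
            {
                "sex": ["male" if i % 2 else "female" for i in range(n)],
                "ecog": [i % 3 for i in range(n)],
                "age": 60.0 + np.arange(n),
                "arm": ["experimental" if i % 2 else "standard" for i in range(n)],
            },
            index=ids,
        )
    return QoLPanel(ids, weeks, scores, covariates)


@pytest.fixture(scope="session")
def recovery_cohort():
    """One well-separated three-class cohort (n=600)."""
    return simulate_cohort(recovery_scenario(), seed=42)


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    """A converged 3-class fit on the well-separated cohort, reused across tests."""
    spec = GrowthMixtureSpec(n_classes=3, growth_covariates=("sex", "ecog"))
    return fit_gmm(recovery_cohort.panel, spec, n_starts=10, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort from the shipped default scenario (n=360)."""
    return simulate_cohort(default_scenario(), seed=11)


@pytest.fixture()
def tiny_survival():
    return SurvivalData(
        [f"s{i}" for i in range(6)],
        [2.0, 3.0, 4.0, 5.0, 8.0, 10.0],
        [1, 0, 1, 1, 0, 1],
    )
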