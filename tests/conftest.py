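import numpy as np
import pytest

from covhawkes import Cohort, ModelParams, RecipientHistory
from covhawkes.simulate import CovariateSpec, SimConfig, simulate_cohort


def random_params(rng: np.random.Generator, p: int) -> ModelParams:
    """Moderate random parameters for oracle comparisons."""
    return ModelParams(
        theta=rng.uniform(0.4, 1.6),
        alpha=rng.normal(0.0, 0.4, size=p),
        beta=rng.uniform(0.0, 0.9),
        gamma=rng.uniform(0.05, 0.5),
    )


def random_recipient(
    rng: np.random.Generator, p: int, obs_length: float = 50.0,
    max_events: int = 5, recipient_id=0,
) -> RecipientHistory:
    n = rng.integers(0, max_events + 1)
    times = np.sort(rng.uniform(0.5, obs_length - 0.5, size=n))
    times = np.unique(times)
    return RecipientHistory(
        recipient_id=recipient_id,
        event_times=times,
        covariates=rng.normal(0.0, 1.0, size=p),
        obs_length=obs_length,
    )


def random_cohort(
    rng: np.random.Generator, n_recipients: int, p: int, **kw
) -> Cohort:
    recs = tuple(
        random_recipient(rng, p, recipient_id=i, **kw)
        for i in range(n_recipients)
    )
    return Cohort(recs, tuple(f"x{k}" for k in range(p)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def two_flag_spec():
    """Minimal two-covariate design used by recovery checks."""
    return (
        CovariateSpec("x1", ("no", "yes"), (0.5, 0.5)),
        CovariateSpec("x2", ("no", "yes"), (0.5, 0.5)),
    )


@pytest.fixture(scope="session")
def small_sim_cohort():
    """A small cohort drawn from the default study conditions."""
    return simulate_cohort(SimConfig(n_recipients=60, obs_length=200.0, seed=7))
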