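"""Intensity, compensator and risk of the triggering process."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covhawkes import (
    ModelParams,
    RecipientHistory,
    baseline_intensity,
    cumulative_intensity,
    event_risk,
    total_intensity,
    triggering_intensity,
)

from conftest import random_params, random_recipient
from oracles import cumulative_intensity_quad


def mk_params(theta=1.0, alpha=(0.0,), beta=0.0, gamma=1.0):
    return ModelParams(theta=theta, alpha=np.asarray(alpha, float),
                       beta=beta, gamma=gamma)


def mk_recipient(times, obs_length=100.0, x=(0.0,)):
    return RecipientHistory("r", np.asarray(times, float),
                            np.asarray(x, float), obs_length)


@pytest.mark.parametrize(
    "theta,alpha,x,t,expected",
    [
        (1.0, (0.0, 0.0), (1.0, 1.0), 5.0, 1.0),   # constant unit rate
        (2.0, (0.0,), (0.0,), 3.0, 6.0),            # 2 * 3^1
        (1.0, (np.log(2.0),), (1.0,), 10.0, 2.0),   # exp(ln 2)
    ],
)
def test_baseline_examples(theta, alpha, x, t, expected):
    p = mk_params(theta=theta, alpha=alpha)
    assert baseline_intensity(p, np.asarray(x), t) == pytest.approx(expected)


def test_baseline_rejects_nonpositive_time_and_bad_shape():
    p = mk_params()
    with pytest.raises(ValueError, match="t > 0"):
        baseline_intensity(p, np.array([0.0]), 0.0)
    with pytest.raises(ValueError, match="length"):
        baseline_intensity(p, np.array([0.0, 1.0]), 1.0)


def test_triggering_examples():
    p = mk_params(beta=1.0, gamma=1.0)
    assert triggering_intensity(p, np.array([]), 5.0) == 0.0
    t = 7.0
    assert triggering_intensity(
        p, np.array([t - np.log(2.0)]), t
    ) == pytest.approx(0.5)
    # two-term sum evaluated by hand
    p2 = mk_params(beta=0.5, gamma=0.2)
    val = triggering_intensity(p2, np.array([t - 1.0, t - 2.0]), t)
    assert val == pytest.approx(
        0.5 * 0.2 * (np.exp(-0.2) + np.exp(-0.4))
    )


def test_triggering_rejects_future_history():
    p = mk_params(beta=1.0)
    with pytest.raises(ValueError, match="before"):
        triggering_intensity(p, np.array([3.0]), 3.0)


def test_total_is_baseline_plus_triggering(rng):
    for _ in range(50):
        p = random_params(rng, 3)
        rec = random_recipient(rng, 3)
        t = float(rng.uniform(0.1, rec.obs_length))
        past = rec.event_times[rec.event_times < t]
        expected = baseline_intensity(p, rec.covariates, t) + (
            triggering_intensity(p, past, t)
        )
        assert total_intensity(p, rec, t) == expected  # exact decomposition


def test_total_example():
    p = mk_params(theta=1.0, beta=1.0, gamma=1.0)
    t = 10.0
    rec = mk_recipient([t - np.log(2.0)])
    assert total_intensity(p, rec, t) == pytest.approx(1.5)


def test_event_at_t_does_not_excite_itself():
    p = mk_params(beta=1.0, gamma=1.0)
    rec = mk_recipient([5.0])
    assert total_intensity(p, rec, 5.0) == pytest.approx(
        baseline_intensity(p, rec.covariates, 5.0)
    )


def test_cumulative_examples():
    p = mk_params(theta=1.0, beta=0.0)
    rec = mk_recipient([])
    assert cumulative_intensity(p, rec, 10.0) == pytest.approx(10.0)
    # triggering contribution saturates at beta as the horizon grows
    p2 = mk_params(theta=1.0, beta=1.0, gamma=1.0)
    rec2 = RecipientHistory("r", np.array([0.0]), np.array([0.0]), 1e9)
    trig_part = cumulative_intensity(p2, rec2, 1e8) - 1e8
    assert trig_part == pytest.approx(1.0, abs=1e-6)


def test_cumulative_monotone_and_matches_quadrature(rng):
    for _ in range(20):
        p = random_params(rng, 2)
        rec = random_recipient(rng, 2)
        t1, t2 = np.sort(rng.uniform(0.5, rec.obs_length, size=2))
        assert cumulative_intensity(p, rec, t2) >= cumulative_intensity(
            p, rec, t1
        )
        closed = cumulative_intensity(p, rec, t2)
        numeric = cumulative_intensity_quad(p, rec, t2)
        assert closed == pytest.approx(numeric, rel=1e-6)


def test_cumulative_rejects_nonpositive_horizon():
    with pytest.raises(ValueError, match="t_end > 0"):
        cumulative_intensity(mk_params(), mk_recipient([]), 0.0)


def test_risk_examples(rng):
    p = mk_params(theta=1.0)
    rec = mk_recipient([])
    assert event_risk(p, rec, np.log(2.0)) == pytest.approx(0.5)
    assert event_risk(p, rec, 1e-12) == pytest.approx(0.0, abs=1e-10)
    pr = random_params(rng, 1)
    rec2 = random_recipient(rng, 1)
    val = event_risk(pr, rec2, 20.0)
    assert 0.0 <= val <= 1.0  # mathematically < 1; float may round up
    assert val == pytest.approx(
        1.0 - np.exp(-cumulative_intensity(pr, rec2, 20.0))
    )


def test_beta_zero_reduces_to_poisson_baseline(rng):
    """With beta=0 the process is the NHPP; with theta=1, alpha=0 a unit HPP."""
    p = random_params(rng, 2)
    p0 = ModelParams(theta=p.theta, alpha=p.alpha, beta=0.0, gamma=p.gamma)
    rec = random_recipient(rng, 2)
    t = 13.0
    assert total_intensity(p0, rec, t) == baseline_intensity(
        p0, rec.covariates, t
    )
    unit = ModelParams(theta=1.0, alpha=np.zeros(2), beta=0.0, gamma=1.0)
    assert total_intensity(unit, rec, t) == pytest.approx(1.0)


def test_triggering_jump_and_decay():
    """lambda_t jumps by beta*gamma right after an event and decays between."""
    p = mk_params(beta=0.7, gamma=0.3)
    rec = mk_recipient([5.0, 20.0])
    eps = 1e-9
    before = total_intensity(p, rec, 20.0)
    after = total_intensity(p, rec, 20.0 + eps)
    assert after - before == pytest.approx(0.7 * 0.3, rel=1e-6)
    # non-increasing between events
    ts = np.linspace(5.0 + 1e-6, 20.0, 50)
    vals = [triggering_intensity(p, np.array([5.0]), t) for t in ts]
    assert np.all(np.diff(vals) <= 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    theta=st.floats(0.3, 2.0),
    beta=st.floats(0.0, 0.95),
    gamma=st.floats(0.02, 1.0),
    times=st.lists(st.floats(0.1, 49.0), min_size=0, max_size=6, unique=True),
    t1=st.floats(0.5, 50.0),
    t2=st.floats(0.5, 50.0),
)
def test_compensator_properties_hold_generally(theta, beta, gamma, times,
                                               t1, t2):
    """For any admissible parameters and history: the intensity decomposes
    exactly, and the compensator is non-negative and monotone."""
    p = ModelParams(theta=theta, alpha=np.array([0.1]), beta=beta,
                    gamma=gamma)
    rec = RecipientHistory("h", np.sort(np.asarray(times)), np.array([1.0]),
                           50.0)
    lo, hi = sorted((t1, t2))
    c_lo = cumulative_intensity(p, rec, lo)
    c_hi = cumulative_intensity(p, rec, hi)
    assert 0.0 <= c_lo <= c_hi
    t = hi
    past = rec.event_times[rec.event_times < t]
    assert total_intensity(p, rec, t) == baseline_intensity(
        p, rec.covariates, t
    ) + triggering_intensity(p, past, t)


def test_event_at_zero_is_shifted_with_warning():
    with pytest.warns(UserWarning, match="shifted"):
        rec = RecipientHistory("r", np.array([0.0, 3.0]), np.array([0.0]), 10.0)
    assert rec.event_times[0] == pytest.approx(1e-6)
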