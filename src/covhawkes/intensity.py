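"""Conditional intensity of the covariate-adjusted triggering process.

The intensity for recipient i decomposes as

    lambda_i(t | H_i(t)) = lambda_b(t) + lambda_t(t)

with a power-law baseline modulated log-linearly by static covariates,

    lambda_b(t) = theta * t**(theta - 1) * exp(alpha' x_i),

and a self-exciting triggering term in which every past event contributes an
exponentially decaying excitation,

    lambda_t(t) = sum_{j : t_ij < t} beta * gamma * exp(-gamma * (t - t_ij)).

The cumulative intensity Lambda(t) = int_0^t lambda(u) du has the closed form

    Lambda(t) = t**theta * exp(alpha' x_i)
                + beta * sum_{t_ij < t} (1 - exp(-gamma * (t - t_ij))),

and 1 - exp(-Lambda(t)) is the probability of at least one event by t.
"""

from __future__ import annotations

import numpy as np

from .data import ModelParams, RecipientHistory

__all__ = [
    "baseline_intensity",
    "triggering_intensity",
    "total_intensity",
    "cumulative_intensity",
    "event_risk",
]


def _check_alpha_x(params: ModelParams, x: np.ndarray) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != params.alpha.shape:
        raise ValueError(
            f"covariate vector has length {x.size}, "
            f"alpha has length {params.alpha.size}"
        )
    return x


def baseline_intensity(params: ModelParams, x: np.ndarray, t: float) -> float:
    """History-independent event rate theta*t**(theta-1)*exp(alpha'x) at t > 0.

    The power law is singular at t = 0 when theta < 1, so t must be
    strictly positive.
    """
    x = _check_alpha_x(params, x)
    t = float(t)
    if t <= 0:
        raise ValueError(f"baseline intensity requires t > 0, got {t}")
    return float(
        params.theta * t ** (params.theta - 1.0) * np.exp(params.alpha @ x)
    )


def triggering_intensity(
    params: ModelParams, history: np.ndarray, t: float
) -> float:
    """Self-excitation at t from events strictly before t.

    Each past event at t_j contributes beta * gamma * exp(-gamma*(t - t_j));
    an empty history contributes 0.  Events at or after t are an ordering
    error (an event exactly at t does not excite itself).
    """
    history = np.asarray(history, dtype=float)
    t = float(t)
    if history.size == 0:
        return 0.0
    if np.any(history >= t):
        raise ValueError("all history times must be strictly before t")
    return float(
        params.beta
        * params.gamma
        * np.sum(np.exp(-params.gamma * (t - history)))
    )


def total_intensity(
    params: ModelParams, recipient: RecipientHistory, t: float
) -> float:
    """Conditional intensity at t: baseline plus triggering from events < t."""
    history = recipient.event_times
    past = history[history < t]
    return baseline_intensity(params, recipient.covariates, t) + (
        triggering_intensity(params, past, t)
    )


def cumulative_intensity(
    params: ModelParams, recipient: RecipientHistory, t_end: float
) -> float:
    """Closed-form Lambda(t_end); events at or after t_end are ignored."""
    t_end = float(t_end)
    if t_end <= 0:
        raise ValueError(f"cumulative intensity requires t_end > 0, got {t_end}")
    x = _check_alpha_x(params, recipient.covariates)
    base = t_end**params.theta * np.exp(params.alpha @ x)
    past = recipient.event_times[recipient.event_times < t_end]
    trig = params.beta * np.sum(1.0 - np.exp(-params.gamma * (t_end - past)))
    return float(base + trig)


def event_risk(
    params: ModelParams, recipient: RecipientHistory, t_end: float
) -> float:
    """Probability of at least one event by t_end: 1 - exp(-Lambda(t_end))."""
    return float(-np.expm1(-cumulative_intensity(params, recipient, t_end)))
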