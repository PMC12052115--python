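"""Memoryless benchmark models: homogeneous and non-homogeneous Poisson.

Both ignore the event-to-event triggering mechanism.  The HPP has constant
intensity ``lambda_i(t) = theta``; the NHPP shares the full model's baseline
``theta * t**(theta-1) * exp(alpha' x_i)`` and is exactly the triggering
model with beta pinned at 0, which is how it is fitted.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .data import Cohort
from .models import TriggeringPointProcess

__all__ = [
    "HomogeneousPoissonProcess",
    "NonhomogeneousPoissonProcess",
    "fit_hpp",
    "fit_nhpp",
    "predict_counts_benchmark",
]


class HomogeneousPoissonProcess(BaseEstimator):
    """Constant-rate Poisson benchmark with the closed-form MLE
    rate_ = total events / total observation time."""

    def fit(self, X: Cohort, y=None) -> "HomogeneousPoissonProcess":
        if not isinstance(X, Cohort):
            raise TypeError("X must be a covhawkes Cohort")
        total_time = float(np.sum(X.obs_lengths()))
        if total_time <= 0:
            raise ValueError("total observation time must be positive")
        n_events = X.n_events
        if n_events == 0:
            warnings.warn("cohort has no events; fitted rate is 0",
                          stacklevel=2)
        self.rate_ = n_events / total_time
        return self

    def predict(self, X: Cohort, horizon: float) -> np.ndarray:
        """Per-recipient expected counts rate_ * horizon."""
        if not hasattr(self, "rate_"):
            raise AttributeError("estimator is not fitted; call fit first")
        if horizon <= 0:
            raise ValueError(f"horizon must be > 0, got {horizon}")
        return np.full(len(X), self.rate_ * float(horizon))

    def predict_decomposed(
        self, X: Cohort, horizon: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """All-baseline decomposition (no triggering component)."""
        base = self.predict(X, horizon)
        return base, np.zeros_like(base)


class NonhomogeneousPoissonProcess(TriggeringPointProcess):
    """Power-law/covariate Poisson benchmark: the full model with beta = 0."""

    def __init__(
        self,
        theta_init: float = 1.0,
        gamma_init: float = 0.1,
        bounds: dict | None = None,
        gradient: str = "analytic",
        n_restarts: int = 0,
        random_state: int | None = None,
    ):
        super().__init__(
            theta_init=theta_init,
            beta_init=0.0,
            gamma_init=gamma_init,
            bounds=bounds,
            gradient=gradient,
            n_restarts=n_restarts,
            random_state=random_state,
            fix_beta_zero=True,
        )


def fit_hpp(cohort: Cohort) -> HomogeneousPoissonProcess:
    """Closed-form HPP fit (rate = events / person-time)."""
    return HomogeneousPoissonProcess().fit(cohort)


def fit_nhpp(cohort: Cohort, **kwargs) -> NonhomogeneousPoissonProcess:
    """Bounded-MLE NHPP fit (theta, alpha; beta fixed at 0)."""
    return NonhomogeneousPoissonProcess(**kwargs).fit(cohort)


def predict_counts_benchmark(
    model: HomogeneousPoissonProcess | NonhomogeneousPoissonProcess,
    test: Cohort,
    horizon: float,
) -> float:
    """Total expected test-set count over [0, horizon) under a benchmark."""
    return float(np.sum(model.predict(test, horizon)))
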