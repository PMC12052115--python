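"""Core containers for recurrent-event cohorts.

A cohort is a collection of recipients; each recipient carries a strictly
increasing sequence of event times (days since their index date), a static
dummy-encoded covariate vector, and a per-recipient observation horizon
(administrative censoring). Time ``t = 0`` is the recipient's index date and
intervals are half-open ``[0, T)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RecipientHistory",
    "Cohort",
    "ModelParams",
    "EPSILON_DAYS",
]

#: Events recorded exactly at t=0 are shifted to this offset (days).  The
#: power-law baseline is singular at 0 for theta < 1, so a literal zero time
#: cannot enter the likelihood.
EPSILON_DAYS = 1e-6


@dataclass(frozen=True)
class RecipientHistory:
    """One recipient's observed event stream.

    Parameters
    ----------
    recipient_id : hashable
        Opaque identifier.
    event_times : ndarray of float
        Strictly increasing event times in days since the index date, all in
        ``[0, obs_length)``.  A time of exactly 0 is shifted to
        :data:`EPSILON_DAYS` with a warning.
    covariates : ndarray of float
        Dummy-encoded covariate vector of length ``p``.
    obs_length : float
        Observation horizon ``T`` in days (> 0).
    event_sources : ndarray of int, optional
        Simulator-side generation labels (0 = immigrant, k>0 = offspring of
        generation k).  Absent for observed data.
    """

    recipient_id: object
    event_times: np.ndarray
    covariates: np.ndarray
    obs_length: float
    event_sources: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        cov = np.atleast_1d(np.asarray(self.covariates, dtype=float))
        if times.ndim != 1:
            raise ValueError("event_times must be one-dimensional")
        if not np.isfinite(self.obs_length) or self.obs_length <= 0:
            raise ValueError(
                f"obs_length must be positive, got {self.obs_length!r}"
            )
        if times.size and times[0] == 0.0:
            warnings.warn(
                f"recipient {self.recipient_id!r}: event at t=0 shifted to "
                f"{EPSILON_DAYS} days (baseline intensity is singular at 0)",
                stacklevel=2,
            )
            times = times.copy()
            times[0] = EPSILON_DAYS
        if np.any(times < 0):
            raise ValueError("event times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"recipient {self.recipient_id!r}: event times must be "
                "strictly increasing"
            )
        if times.size and times[-1] >= self.obs_length:
            raise ValueError(
                f"recipient {self.recipient_id!r}: events must lie in "
                f"[0, obs_length={self.obs_length})"
            )
        if self.event_sources is not None:
            src = np.asarray(self.event_sources, dtype=int)
            if src.shape != times.shape:
                raise ValueError("event_sources must align with event_times")
            object.__setattr__(self, "event_sources", src)
        object.__setattr__(self, "event_times", times)
        object.__setattr__(self, "covariates", cov)

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


@dataclass(frozen=True)
class Cohort:
    """A collection of recipients sharing one covariate design.

    ``covariate_names`` labels the dummy-encoded columns; ``encoding`` maps
    each original categorical variable to its (reference level, kept levels)
    so fitted coefficients stay interpretable.
    """

    recipients: tuple[RecipientHistory, ...]
    covariate_names: tuple[str, ...]
    encoding: Mapping[str, Mapping[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        recs = tuple(self.recipients)
        if not recs:
            raise ValueError("a Cohort needs at least one recipient")
        p = len(self.covariate_names)
        for r in recs:
            if r.covariates.shape != (p,):
                raise ValueError(
                    f"recipient {r.recipient_id!r} has covariate dimension "
                    f"{r.covariates.shape[0]}, expected {p}"
                )
        object.__setattr__(self, "recipients", recs)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))

    def __len__(self) -> int:
        return len(self.recipients)

    def __iter__(self):
        return iter(self.recipients)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def n_events(self) -> int:
        return sum(r.n_events for r in self.recipients)

    def covariate_matrix(self) -> np.ndarray:
        """Stacked (N, p) covariate design matrix."""
        return np.array([r.covariates for r in self.recipients], dtype=float)

    def obs_lengths(self) -> np.ndarray:
        return np.array([r.obs_length for r in self.recipients], dtype=float)

    def subset(self, indices: Iterable[int]) -> "Cohort":
        """New cohort restricted to the given recipient positions."""
        recs = tuple(self.recipients[i] for i in indices)
        return Cohort(recs, self.covariate_names, self.encoding)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the covariate-adjusted triggering process.

    theta : float
        Power-law shape of the baseline rate lambda0(t) = theta * t**(theta-1)
        (theta = 1 constant, < 1 decreasing, > 1 increasing); theta > 0.
    alpha : ndarray
        Log-linear covariate coefficients, length p.
    beta : float
        Triggering magnitude = expected offspring per event (branching
        ratio); beta >= 0.  Only the simulator requires beta < 1.
    gamma : float
        Exponential decay rate of the triggering kernel, per day; gamma > 0.
    """

    theta: float
    alpha: np.ndarray
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if alpha.ndim != 1:
            raise ValueError("alpha must be a vector")
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta!r}")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma!r}")
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError(f"beta must be >= 0, got {self.beta!r}")
        if not np.all(np.isfinite(alpha)):
            raise ValueError("alpha must be finite")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "theta", float(self.theta))
        object.__setattr__(self, "beta", float(self.beta))
        object.__setattr__(self, "gamma", float(self.gamma))

    @property
    def n_params(self) -> int:
        return 3 + self.alpha.size

    def to_vector(self) -> np.ndarray:
        """Flatten as [theta, beta, gamma, alpha...] for the optimizer."""
        return np.concatenate([[self.theta, self.beta, self.gamma], self.alpha])

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        return cls(theta=vec[0], beta=vec[1], gamma=vec[2], alpha=vec[3:])

    def as_dict(self) -> dict:
        return {
            "theta": self.theta,
            "alpha": self.alpha.tolist(),
            "beta": self.beta,
            "gamma": self.gamma,
        }
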