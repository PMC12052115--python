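"""Independent numerical oracles used to validate closed-form quantities.

The cumulative intensity and the log-likelihood are recomputed here by
adaptive quadrature of the pointwise conditional intensity, deliberately
avoiding the package's closed-form compensator.
"""

import numpy as np
from scipy.integrate import quad

from covhawkes import Cohort, ModelParams, RecipientHistory
from covhawkes.intensity import total_intensity


def cumulative_intensity_quad(
    params: ModelParams, recipient: RecipientHistory, t_end: float
) -> float:
    """Integral of the conditional intensity by adaptive quadrature."""
    pts = [t for t in recipient.event_times if 0 < t < t_end]
    val, _ = quad(
        lambda t: total_intensity(params, recipient, t),
        0.0,
        t_end,
        points=pts or None,
        limit=400,
    )
    return val


def log_likelihood_quad(params: ModelParams, cohort: Cohort) -> float:
    """Cohort log-likelihood with the compensator from quadrature."""
    ll = 0.0
    for rec in cohort:
        for t in rec.event_times:
            ll += np.log(total_intensity(params, rec, t))
        ll -= cumulative_intensity_quad(params, rec, rec.obs_length)
    return ll
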