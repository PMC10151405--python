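"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

#: floor applied to sampled variances so full conditionals stay proper
VAR_FLOOR = 1e-10


def rng_from(seed) -> np.random.Generator:
    """Return a Generator; pass through if already one."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_scaled_inv_chi2(rng: np.random.Generator, nu: float, s: float) -> float:
    """Draw from a scaled inverse chi-square distribution.

    Density proportional to (sigma^2)^-(nu/2+1) exp(-nu*s / (2 sigma^2)),
    i.e. nu*s / chi2(nu); prior mean nu*s/(nu-2) for nu > 2.
    """
    draw = nu * s / rng.chisquare(nu)
    return max(float(draw), VAR_FLOOR)


def scale_from_prior_mean(prior_mean: float, nu: float) -> float:
    """Scale s such that the scaled-inv-chi2 mean nu*s/(nu-2) equals prior_mean."""
    if nu <= 2:
        raise ValueError("nu must exceed 2 for the prior mean to exist")
    return prior_mean * (nu - 2.0) / nu
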