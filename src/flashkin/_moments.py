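"""Moment-matched positive distributions used by the flash-parameter sampler.

Both families are parameterized directly by (mean, sd) of the target
distribution. The lognormal match is exact; the zero-truncated normal uses
the naive truncation of N(mean, sd) at 0, which is a good approximation
whenever the coefficient of variation is well below 1 (the truncated mass is
negligible for every built-in library entry that would use it).
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) of a lognormal with the given moments."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def lognormal_from_z(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Map standard-normal draws onto the moment-matched lognormal."""
    mu, sigma = lognormal_mu_sigma(mean, sd)
    return np.exp(mu + sigma * np.asarray(z, dtype=float))


def truncnorm_from_z(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Map standard-normal draws onto N(mean, sd) truncated at 0.

    Comonotone in z, like :func:`lognormal_from_z`, so the two families are
    interchangeable in the sampler's shared-latent construction.
    """
    z = np.asarray(z, dtype=float)
    if sd == 0:
        return np.full(z.shape, mean)
    a = -mean / sd
    u = stats.norm.cdf(z)
    return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def from_z(z: np.ndarray, mean: float, sd: float, family: str) -> np.ndarray:
    if family == "lognormal":
        return lognormal_from_z(z, mean, sd)
    if family == "truncnorm":
        return truncnorm_from_z(z, mean, sd)
    raise ValueError(f"unknown distribution family: {family!r}")
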