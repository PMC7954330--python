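"""Shared numerical helpers: seeded RNG derivation and calibrated draws.

The generator quotes summary statistics (mean, SD) for quantities that are
physically constrained to an interval (durations > 0, frequencies within a
groupable band, delays > 0).  Drawing from a plainly truncated normal would
shift the realized mean away from the quoted one (for example a
Normal(4.09, 2.60) truncated at zero has mean 4.41), so truncated draws are
calibrated: the parent (mu, sigma) is solved so that the post-truncation
mean and SD equal the requested targets.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, stats

#: refractory floor between successive single discharges, seconds
REFRACTORY_S = 2.0


def derive_seed(seed: int, *key: int) -> int:
    """Derive a child seed from ``seed`` and an index path.

    Stable across runs and library versions: uses numpy's ``SeedSequence``
    with ``seed`` as entropy and ``key`` as the spawn key, and returns the
    first generated 32-bit word.  ``simulate_population`` documents this as
    its per-slice seed protocol.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def rng_from(seed: int, *key: int) -> np.random.Generator:
    """A ``numpy.random.Generator`` for ``seed`` (optionally a child key)."""
    if key:
        seed = derive_seed(seed, *key)
    return np.random.default_rng(int(seed))


@lru_cache(maxsize=256)
def _truncnorm_parent(mean: float, sd: float, lower: float, upper: float):
    """Solve for parent (mu, sigma) of a truncated normal on [lower, upper]
    whose post-truncation mean and SD equal ``mean`` and ``sd``.
    """
    if sd <= 0:
        return float(mean), 0.0

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, np.sqrt(float(v)) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    mu, log_sigma = sol.x
    sigma = float(np.exp(log_sigma))
    if not sol.success:
        # Fall back to matching the mean only (SD infeasible on a narrow
        # support); a wide parent truncated to the interval is the closest
        # admissible distribution.
        def mean_only(mu_):
            a, b = (lower - mu_) / sd, (upper - mu_) / sd
            return float(stats.truncnorm.mean(a, b, loc=mu_, scale=sd)) - mean

        mu = float(optimize.brentq(mean_only, lower - 10 * sd, upper + 10 * sd))
        sigma = sd
    return float(mu), sigma


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size,
    lower: float = 0.0,
    upper: float = np.inf,
) -> np.ndarray:
    """Draw from a truncated normal calibrated so the realized distribution
    has the requested mean and SD on ``[lower, upper]``."""
    if sd <= 0:
        return np.full(size, float(mean))
    mu, sigma = _truncnorm_parent(float(mean), float(sd), float(lower), float(upper))
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def truncated_normal_moments(mean, sd, lower=0.0, upper=np.inf):
    """Realized (mean, sd) of the calibrated truncated normal (for tests)."""
    mu, sigma = _truncnorm_parent(float(mean), float(sd), float(lower), float(upper))
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def lognormal(rng: np.random.Generator, mean: float, sd: float, size,
              lower: float = 0.0) -> np.ndarray:
    """Log-normal draws parameterized by arithmetic mean and SD.

    With ``lower`` > 0 the distribution is conditioned on exceeding that
    value (inverse-CDF sampling, no rejection).
    """
    if sd <= 0:
        return np.full(size, float(mean))
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    if lower <= 0:
        return rng.lognormal(mu, np.sqrt(s2), size)
    s = np.sqrt(s2)
    f_lo = stats.norm.cdf((np.log(lower) - mu) / s)
    u = rng.uniform(f_lo, 1.0, size)
    return np.exp(mu + s * stats.norm.ppf(u))
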