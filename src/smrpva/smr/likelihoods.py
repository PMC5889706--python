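"""Observation-model components of the spatial mark-resight likelihood.

These are the pure, vectorized building blocks: half-normal detection
kernels on the capture (trapping) and resight (camera) sides, the
inhomogeneous point-process prior over state-space cells, the bivariate
normal telemetry likelihood, and the exact marginal likelihood of unmarked
count data.  The MCMC engine re-implements the same quantities in compiled
loops; the test suite holds the two routes together and checks both
against brute-force enumeration on tiny instances.

Sex is coded female = 1, male = 0 throughout, so the ``*1`` coefficients
are female effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from ..habitat import StateSpace

__all__ = [
    "SMRParams",
    "capture_probability",
    "resight_probability",
    "activity_center_logprior",
    "telemetry_loglik",
    "poisson_binomial_logpmf",
    "unmarked_loglik",
]

FEMALE, MALE = 1, 0


@dataclass
class SMRParams:
    """One point in parameter space.

    ``beta*`` are capture (trap) logit coefficients, ``delta*`` resight
    (camera) logit coefficients (intercept, female effect, days-since-baiting
    effect), ``alpha*`` the point-process coefficients (``alpha0`` cancels
    from the normalized cell probabilities and is kept only for interface
    completeness), ``sigma_*`` the sex-specific half-normal movement scales
    in meters, ``psi`` the data-augmentation inclusion probability and
    ``phi`` the latent probability that an individual is female.  ``z`` and
    ``s`` optionally carry the latent inclusion flags and activity-center
    cell assignments of an augmented population.
    """

    beta0: float = 0.0
    beta1: float = 0.0
    delta0: float = 0.0
    delta1: float = 0.0
    delta2: float = 0.0
    alpha0: float = 0.0
    alpha1: float = 0.0
    sigma_female: float = 300.0
    sigma_male: float = 1000.0
    psi: float = 0.5
    phi: float = 0.5
    z: np.ndarray | None = None
    s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sigma_female <= 0 or self.sigma_male <= 0:
            raise ValueError("movement scales sigma must be positive")
        for name in ("psi", "phi"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    def sigma(self, sex) -> np.ndarray | float:
        """Movement scale for a sex code or array of codes."""
        sex = np.asarray(sex)
        out = np.where(sex == FEMALE, self.sigma_female, self.sigma_male)
        return float(out) if out.ndim == 0 else out


def _halfnormal_kernel(d, sigma) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be >= 0")
    return np.exp(-(d**2) / (2.0 * np.asarray(sigma, dtype=float) ** 2))


def capture_probability(params: SMRParams, d, sex):
    """Per-night probability of capture at a trap distance ``d`` from the center.

    ``expit(beta0 + beta1 * sex) * exp(-d^2 / (2 sigma_sex^2))``.
    """
    p0 = expit(params.beta0 + params.beta1 * np.asarray(sex))
    out = p0 * _halfnormal_kernel(d, params.sigma(sex))
    return float(out) if np.ndim(out) == 0 else out


def resight_probability(params: SMRParams, d, sex, days):
    """Per-occasion probability of a camera resight.

    ``expit(delta0 + delta1 * sex + delta2 * days) * exp(-d^2 / (2 sigma_sex^2))``;
    ``days`` is the integer days-since-baiting covariate.
    """
    days = np.asarray(days)
    if (days < 0).any():
        raise ValueError("days since baiting must be >= 0")
    p0 = expit(params.delta0 + params.delta1 * np.asarray(sex) + params.delta2 * days)
    out = p0 * _halfnormal_kernel(d, params.sigma(sex))
    return float(out) if np.ndim(out) == 0 else out


def activity_center_logprior(
    state_space: StateSpace, alpha0: float = 0.0, alpha1: float = 0.0
) -> np.ndarray:
    """Log cell probabilities of the inhomogeneous point process.

    ``mu_g = area_g * exp(alpha0 + alpha1 * veg_g)`` normalized over the
    state space, so ``alpha0`` cancels and ``sum(exp(result)) == 1``.
    """
    logmu = np.log(state_space.area_km2) + alpha0 + alpha1 * state_space.veg
    if not np.isfinite(logmu).all():
        raise ValueError("point-process intensity is not finite")
    return logmu - logsumexp(logmu)


def telemetry_loglik(locations: np.ndarray, s: np.ndarray, sigma: float) -> float:
    """Log-likelihood of telemetry fixes under an isotropic bivariate normal.

    Locations are assumed pre-thinned to be at least one hour apart so they
    can be treated as independent draws centered on the activity center ``s``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if locations.shape[0] == 0:
        raise ValueError("at least one telemetry location is required")
    d2 = ((locations - np.asarray(s, dtype=float)) ** 2).sum(axis=1)
    n = locations.shape[0]
    return float(-n * np.log(2.0 * np.pi * sigma**2) - d2.sum() / (2.0 * sigma**2))


def poisson_binomial_logpmf(n: int, p: np.ndarray) -> float:
    """Exact log P(sum of independent Bernoulli(p_i) == n), by dynamic programming."""
    p = np.asarray(p, dtype=float)
    if n < 0 or n > p.size:
        return -np.inf
    f = np.zeros(n + 1)
    f[0] = 1.0
    for pi in p:
        f[1:] = f[1:] * (1.0 - pi) + f[:-1] * pi
        f[0] *= 1.0 - pi
    return float(np.log(f[n])) if f[n] > 0 else -np.inf


def unmarked_loglik(nU: np.ndarray, pcam: np.ndarray) -> float:
    """Marginal log-likelihood of the unmarked count data.

    Each live unmarked (augmented, included) individual generates a latent
    Bernoulli detection per station-occasion with its own ``pcam``; the
    observed count ``nU[j, k]`` is their sum.  The latent detections are
    marginalized exactly: per station-occasion the count is
    Poisson-binomial over the individuals' probabilities.  Marked
    individuals never contribute here.

    Parameters
    ----------
    nU
        (n_stations, n_occasions) nonnegative counts.
    pcam
        (n_latent, n_stations, n_occasions) per-individual resight
        probabilities for the live unmarked individuals.

    Returns
    -------
    float
        Log-likelihood; ``-inf`` if some count exceeds the number of live
        latent individuals (an impossible state the sampler never proposes).
    """
    nU = np.asarray(nU)
    pcam = np.asarray(pcam, dtype=float)
    if pcam.ndim != 3 or pcam.shape[1:] != nU.shape:
        raise ValueError("pcam must be (n_latent, n_stations, n_occasions)")
    if (nU < 0).any():
        raise ValueError("unmarked counts must be >= 0")
    total = 0.0
    for j, k in zip(*np.nonzero(np.ones_like(nU, dtype=bool))):
        total += poisson_binomial_logpmf(int(nU[j, k]), pcam[:, j, k])
        if not np.isfinite(total):
            return -np.inf
    return float(total)
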