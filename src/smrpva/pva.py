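"""Stochastic theta-logistic projections with Poisson human-caused mortality.

Population dynamics follow the discrete theta-logistic model with annual
environmental noise and a density-independent mortality (harvest) term:

    N_{t+1} = max(0, N_t * exp(r * (1 - (N_t / K)^theta) + eps_t) - H_t),

with ``eps_t ~ Normal(0, sigma_env)`` and ``H_t ~ Poisson(lambda)`` drawn
independently each year.  ``theta = 1`` is ordinary logistic growth;
``theta > 1`` delays the onset of density dependence, as expected for
long-lived territorial mammals.  A trajectory counts as (quasi-)extinct if
it ever drops below the extinction threshold within the horizon.

Abundance is continuous-valued; the quasi-extinction threshold (default 2
individuals, strict) absorbs the discreteness of very small populations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["PVAScenario", "TrajectorySet", "step", "project", "scenario_grid"]


@dataclass(frozen=True)
class PVAScenario:
    """Settings for one projection experiment.

    Attributes
    ----------
    K
        Carrying capacity (individuals).
    lam
        Mean (and variance) of annual human-caused mortalities.
    theta
        Shape of density dependence (> 0).
    r
        Maximum intrinsic growth rate (per year).
    sigma_env
        Standard deviation of the annual environmental noise ``eps``.
    N0
        Initial population size; defaults to ``K``.
    horizon
        Projection length (years).
    n_sims
        Number of independent trajectories.
    extinction_threshold
        Quasi-extinction level; a trajectory is extinct if ``N_t`` falls
        strictly below it at any time step.
    seed
        RNG seed for this scenario.
    """

    K: float = 30.0
    lam: float = 2.0
    theta: float = 1.0
    r: float = 0.205
    sigma_env: float = 0.06
    N0: float | None = None
    horizon: int = 30
    n_sims: int = 1000
    extinction_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")
        if self.lam < 0:
            raise ValueError("mean annual mortality lam must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.sigma_env < 0:
            raise ValueError("sigma_env must be >= 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 year")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.N0 is not None and self.N0 < 0:
            raise ValueError("N0 must be >= 0")

    @property
    def initial_size(self) -> float:
        return float(self.K if self.N0 is None else self.N0)


@dataclass
class TrajectorySet:
    """Simulated trajectories plus their extinction summary."""

    N: np.ndarray  # (n_sims, horizon + 1), N[:, 0] = N0
    extinct: np.ndarray  # (n_sims,) bool
    scenario: PVAScenario

    @property
    def pr_ext(self) -> float:
        """Probability of quasi-extinction within the horizon."""
        return float(self.extinct.mean())

    @property
    def mean_trajectory(self) -> np.ndarray:
        return self.N.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long table (sim, year, N), one row per trajectory-year."""
        n_sims, n_years = self.N.shape
        return pd.DataFrame(
            {
                "sim": np.repeat(np.arange(n_sims), n_years),
                "year": np.tile(np.arange(n_years), n_sims),
                "N": self.N.ravel(),
            }
        )


def step(
    N_t: float | np.ndarray, scenario: PVAScenario, eps_t: float | np.ndarray = 0.0,
    H_t: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """One year of theta-logistic growth followed by harvest, clamped at 0."""
    N_t = np.asarray(N_t, dtype=float)
    if (N_t < 0).any():
        raise ValueError("N_t must be >= 0")
    growth = np.exp(scenario.r * (1.0 - (N_t / scenario.K) ** scenario.theta) + eps_t)
    out = np.maximum(0.0, N_t * growth - H_t)
    return float(out) if out.ndim == 0 else out


def project(
    scenario: PVAScenario,
    noise: np.ndarray | None = None,
    harvest: np.ndarray | None = None,
) -> TrajectorySet:
    """Simulate ``n_sims`` trajectories over the horizon.

    ``noise`` and ``harvest`` override the random draws with fixed arrays of
    shape (n_sims, horizon) — useful for deterministic checks; by default
    ``eps ~ N(0, sigma_env)`` and ``H ~ Poisson(lam)`` are drawn per
    trajectory-year from ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    n, T = scenario.n_sims, scenario.horizon
    if noise is None:
        noise = rng.normal(0.0, scenario.sigma_env, size=(n, T))
    if harvest is None:
        harvest = rng.poisson(scenario.lam, size=(n, T)).astype(float)
    noise = np.broadcast_to(np.asarray(noise, dtype=float), (n, T))
    harvest = np.broadcast_to(np.asarray(harvest, dtype=float), (n, T))

    N = np.empty((n, T + 1))
    N[:, 0] = scenario.initial_size
    for t in range(T):
        N[:, t + 1] = step(N[:, t], scenario, noise[:, t], harvest[:, t])
    extinct = (N < scenario.extinction_threshold).any(axis=1)
    return TrajectorySet(N=N, extinct=extinct, scenario=scenario)


def scenario_grid(
    Ks: Iterable[float],
    lams: Iterable[float],
    thetas: Iterable[float],
    base: PVAScenario | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Extinction probability over a (K, lambda, theta) factorial grid.

    Each cell is an independent seeded run (children of ``seed``, which
    defaults to ``base.seed``), so rows are reproducible in isolation.
    """
    base = base or PVAScenario()
    Ks, lams, thetas = list(Ks), list(lams), list(thetas)
    if not (Ks and lams and thetas):
        raise ValueError("all three grids must be nonempty")
    root = np.random.SeedSequence(base.seed if seed is None else seed)
    children = root.spawn(len(Ks) * len(lams) * len(thetas))
    rows = []
    i = 0
    for K in Ks:
        for lam in lams:
            for theta in thetas:
                child_seed = int(children[i].generate_state(1)[0] % (2**31))
                i += 1
                sc = replace(base, K=K, lam=lam, theta=theta, N0=None, seed=child_seed)
                rows.append(
                    {"K": K, "lam": lam, "theta": theta, "pr_ext": project(sc).pr_ext}
                )
    return pd.DataFrame(rows)
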