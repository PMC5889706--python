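"""Fitting front-end: data preparation, chain orchestration, summaries."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..habitat import StateSpace
from . import _sampler
from .data import SMRData
from .diagnostics import rhat

__all__ = [
    "MCMCConfig",
    "SMRPosterior",
    "fit_smr",
    "estimate_density",
    "extrapolate_abundance",
]

SCALAR_PARAMS = [
    "beta0",
    "beta1",
    "delta0",
    "delta1",
    "delta2",
    "alpha1",
    "sigma_female",
    "sigma_male",
    "psi",
    "phi",
]
MONITORED = SCALAR_PARAMS + ["N", "density"]


@dataclass
class MCMCConfig:
    """Sampler protocol and priors.

    Defaults follow the survey's protocol: 3 chains of 10,000 iterations,
    5,000 burn-in, thinning by 5 (3,000 retained draws), augmented
    superpopulation of 60 (about six times the plausible abundance in the
    sampled area).  Priors are weakly informative Normal(0, 10) on the logit
    and log-intensity coefficients and Uniform(0, 5000 m) on the movement
    scales; inclusion and sex probabilities get Uniform(0, 1).
    """

    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    M_aug: int = 60
    seed: int = 0
    prior_sd_beta: float = 10.0
    prior_sd_delta: float = 10.0
    prior_sd_alpha: float = 10.0
    sigma_max: float = 5_000.0
    # random-walk base scales: b0 b1 d0 d1 d2 a1 log-sig_f log-sig_m
    proposal_scales: tuple = (0.4, 0.4, 0.15, 0.15, 0.02, 0.4, 0.05, 0.05)
    p_global: float = 0.15
    local_sd_cells: float = 2.0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 1 or self.thin < 1:
            raise ValueError("chains, iterations and thin must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must lie in [0, iterations)")
        if self.M_aug < 1:
            raise ValueError("M_aug must be >= 1")

    @property
    def n_keep_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class SMRPosterior:
    """Retained MCMC draws with convergence diagnostics.

    ``draws`` has one row per retained draw with columns ``chain``,
    ``draw``, the scalar parameters, the realized population size ``N``,
    the count of included individuals centered in habitat ``n_habitat`` and
    the implied ``density`` (individuals per km^2 of habitat).
    """

    draws: pd.DataFrame
    rhat: dict[str, float]
    config: MCMCConfig
    habitat_area_km2: float
    saturated: bool = False
    warnings_: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and 2.5/50/97.5 percentiles per monitored quantity."""
        rows = {}
        for name in MONITORED:
            v = self.draws[name].to_numpy()
            rows[name] = {
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "q2.5": np.percentile(v, 2.5),
                "q50": np.percentile(v, 50),
                "q97.5": np.percentile(v, 97.5),
                "rhat": self.rhat[name],
            }
        return pd.DataFrame(rows).T

    def max_rhat(self) -> float:
        return max(self.rhat.values())


def _prepare_arrays(data: SMRData, config: MCMCConfig):
    """Flatten the dataset into the compiled sampler's array arguments."""
    ss = data.state_space
    G = ss.n_cells
    cx, cy = ss.x, ss.y
    nm = data.n_marked
    M = int(config.M_aug)
    if M < nm:
        raise ValueError(f"M_aug = {M} is smaller than the {nm} marked individuals")
    if data.nU.size and M - nm < int(data.nU.max()):
        raise ValueError(
            "M_aug leaves fewer latent unmarked individuals than the largest "
            f"unmarked count ({int(data.nU.max())})"
        )

    D2t = (cx[:, None] - data.trap_xy[None, :, 0]) ** 2 + (
        cy[:, None] - data.trap_xy[None, :, 1]
    ) ** 2
    D2c = (cx[:, None] - data.cam_xy[None, :, 0]) ** 2 + (
        cy[:, None] - data.cam_xy[None, :, 1]
    ) ** 2

    # sparse capture lists per marked individual
    capt_j, capt_y, capt_ptr = [], [], [0]
    for i in range(nm):
        jj = np.nonzero(data.ycap[i])[0]
        capt_j.extend(jj.tolist())
        capt_y.extend(data.ycap[i, jj].tolist())
        capt_ptr.append(len(capt_j))

    # day-value histograms per camera; occasions collapse by days covariate
    C, K = data.n_cameras, data.n_occasions
    dvals, dinv = np.unique(data.days, return_inverse=True)
    D = dvals.size
    didx = dinv.reshape(C, K) if data.days.size else np.zeros((C, K), dtype=np.int64)
    hist_all = np.zeros((C, D))
    hist_zero = np.zeros((C, D))
    zero = data.nU == 0
    for j in range(C):
        for k in range(K):
            hist_all[j, didx[j, k]] += 1.0
            if zero[j, k]:
                hist_zero[j, didx[j, k]] += 1.0

    # sparse detection lists per marked individual
    det_j, det_didx, det_ptr = [], [], [0]
    for i in range(nm):
        jj, kk = np.nonzero(data.ycam[i]) if data.ycam.size else ([], [])
        det_j.extend(np.asarray(jj).tolist())
        det_didx.extend(didx[jj, kk].tolist() if len(jj) else [])
        det_ptr.append(len(det_j))

    # station-occasions with positive unmarked counts
    pj, pk = np.nonzero(data.nU)
    pos_j = pj.astype(np.int64)
    pos_didx = didx[pj, pk].astype(np.int64)
    pos_n = data.nU[pj, pk].astype(np.int64)

    tel_n = np.zeros(nm)
    tel_sx = np.zeros(nm)
    tel_sy = np.zeros(nm)
    tel_ss = np.zeros(nm)
    for i, locs in enumerate(data.telemetry):
        tel_n[i] = locs.shape[0]
        if locs.shape[0]:
            tel_sx[i] = locs[:, 0].sum()
            tel_sy[i] = locs[:, 1].sum()
            tel_ss[i] = (locs**2).sum()

    return dict(
        cx=cx,
        cy=cy,
        veg=ss.veg,
        log_area=np.log(ss.area_km2),
        habitat_u8=ss.habitat.astype(np.uint8),
        cell_row=ss.row.astype(np.int64),
        cell_col=ss.col.astype(np.int64),
        grid_idx=ss.cell_index_map(),
        D2t=D2t,
        Ktrapf=data.Ktrap.astype(float),
        capt_j=np.asarray(capt_j, dtype=np.int64),
        capt_y=np.asarray(capt_y, dtype=float),
        capt_ptr=np.asarray(capt_ptr, dtype=np.int64),
        D2c=D2c,
        dvals=dvals.astype(float),
        histc_all=hist_all,
        histc_zero=hist_zero,
        det_j=np.asarray(det_j, dtype=np.int64),
        det_didx=np.asarray(det_didx, dtype=np.int64),
        det_ptr=np.asarray(det_ptr, dtype=np.int64),
        sex_m=data.sex.astype(np.int64),
        tel_n=tel_n,
        tel_sx=tel_sx,
        tel_sy=tel_sy,
        tel_ss=tel_ss,
        pos_j=pos_j,
        pos_didx=pos_didx,
        pos_n=pos_n,
        M=M,
    )


def _chain_inits(data: SMRData, config: MCMCConfig, chain: int, arrays: dict):
    """Overdispersed but sane starting values for one chain."""
    rng = np.random.default_rng((config.seed + 7919 * (chain + 1)) % 2**31)
    nm = data.n_marked
    M = arrays["M"]
    cx, cy = arrays["cx"], arrays["cy"]

    def _emp_sigma(sex):
        sp = []
        for i in range(nm):
            locs = data.telemetry[i]
            if data.sex[i] == sex and locs.shape[0] >= 3:
                sp.append(np.sqrt(((locs - locs.mean(axis=0)) ** 2).sum(axis=1).mean()))
        return float(np.median(sp)) if sp else (300.0 if sex == 1 else 1000.0)

    sigf = max(25.0, _emp_sigma(1) * math.exp(rng.normal(0.0, 0.3)))
    sigm = max(25.0, _emp_sigma(0) * math.exp(rng.normal(0.0, 0.3)))
    sigf = min(sigf, config.sigma_max * 0.9)
    sigm = min(sigm, config.sigma_max * 0.9)

    init_par = np.array(
        [
            rng.normal(-1.5, 0.7),
            rng.normal(0.0, 0.5),
            rng.normal(-1.5, 0.7),
            rng.normal(0.0, 0.5),
            rng.normal(0.0, 0.03),
            rng.normal(0.0, 0.7),
            sigf,
            sigm,
            rng.uniform(0.2, 0.8),
            rng.uniform(0.3, 0.7),
        ]
    )

    init_g = np.empty(M, dtype=np.int64)
    for i in range(nm):
        locs = data.telemetry[i]
        if locs.shape[0]:
            px, py = locs[:, 0].mean(), locs[:, 1].mean()
        elif data.ycap[i].sum() > 0:
            w = data.ycap[i].astype(float)
            px = (w * data.trap_xy[:, 0]).sum() / w.sum()
            py = (w * data.trap_xy[:, 1]).sum() / w.sum()
        else:
            px, py = cx.mean(), cy.mean()
        init_g[i] = int(np.argmin((cx - px) ** 2 + (cy - py) ** 2))
    init_g[nm:] = rng.integers(0, cx.size, size=M - nm)
    return init_par, init_g


def fit_smr(data: SMRData, config: MCMCConfig | None = None) -> SMRPosterior:
    """Fit the generalized spatial mark-resight model by MCMC.

    Runs ``config.chains`` independent chains (seeded ``seed + chain``),
    retains ``(iterations - burn_in) / thin`` draws per chain, and attaches
    split-chain R-hat per monitored parameter.  Non-convergence (R-hat >=
    1.1) and augmentation saturation (posterior mass near ``N = M_aug``)
    are flagged with warnings, not errors.
    """
    config = config or MCMCConfig()
    data.validate()
    arrays = _prepare_arrays(data, config)
    hab_area = data.state_space.habitat_area_km2

    frames = []
    for chain in range(config.chains):
        init_par, init_g = _chain_inits(data, config, chain, arrays)
        out = _sampler.run_chain(
            (config.seed + chain) % 2**31,
            config.iterations,
            config.burn_in,
            config.thin,
            arrays["cx"],
            arrays["cy"],
            arrays["veg"],
            arrays["log_area"],
            arrays["habitat_u8"],
            arrays["cell_row"],
            arrays["cell_col"],
            arrays["grid_idx"],
            arrays["D2t"],
            arrays["Ktrapf"],
            arrays["capt_j"],
            arrays["capt_y"],
            arrays["capt_ptr"],
            arrays["D2c"],
            arrays["dvals"],
            arrays["histc_all"],
            arrays["histc_zero"],
            arrays["det_j"],
            arrays["det_didx"],
            arrays["det_ptr"],
            arrays["sex_m"],
            arrays["tel_n"],
            arrays["tel_sx"],
            arrays["tel_sy"],
            arrays["tel_ss"],
            arrays["pos_j"],
            arrays["pos_didx"],
            arrays["pos_n"],
            arrays["M"],
            config.prior_sd_beta,
            config.prior_sd_delta,
            config.prior_sd_alpha,
            config.sigma_max,
            np.asarray(config.proposal_scales, dtype=float),
            config.local_sd_cells,
            config.p_global,
            init_par,
            init_g,
        )
        df = pd.DataFrame(out, columns=SCALAR_PARAMS + ["N", "n_habitat"])
        df.insert(0, "chain", chain)
        df.insert(1, "draw", np.arange(out.shape[0]))
        frames.append(df)
    draws = pd.concat(frames, ignore_index=True)
    if hab_area > 0:
        draws["density"] = draws["n_habitat"] / hab_area
    else:
        draws["density"] = np.nan

    diag = {}
    n_keep = config.n_keep_per_chain
    for name in MONITORED:
        mat = draws[name].to_numpy().reshape(config.chains, n_keep)
        diag[name] = rhat(mat) if config.chains >= 2 and n_keep >= 4 else float("nan")

    msgs = []
    sat = float((draws["N"] > 0.9 * config.M_aug).mean()) > 0.05
    if sat:
        msgs.append(
            f"augmentation may be saturated: Pr(N > 0.9 * M_aug) = "
            f"{(draws['N'] > 0.9 * config.M_aug).mean():.3f}"
        )
    bad = {k: v for k, v in diag.items() if np.isfinite(v) and v >= 1.1}
    if bad:
        msgs.append(f"chains may not have converged, R-hat >= 1.1 for: {sorted(bad)}")
    for m in msgs:
        warnings.warn(m, stacklevel=2)
    return SMRPosterior(
        draws=draws,
        rhat=diag,
        config=config,
        habitat_area_km2=hab_area,
        saturated=sat,
        warnings_=msgs,
    )


def estimate_density(posterior: SMRPosterior, state_space: StateSpace) -> dict:
    """Summarize density (individuals per km^2 of habitat) from the posterior.

    The numerator of each draw is the number of included individuals whose
    activity center lies in a habitat cell; the denominator is the habitat
    (vegetated) area of ``state_space``.
    """
    area = state_space.habitat_area_km2
    if area <= 0:
        raise ValueError("state space has zero habitat area")
    dens = posterior.draws["n_habitat"].to_numpy() / area
    return {
        "mean": float(dens.mean()),
        "sd": float(dens.std(ddof=1)),
        "q2.5": float(np.percentile(dens, 2.5)),
        "q50": float(np.percentile(dens, 50)),
        "q97.5": float(np.percentile(dens, 97.5)),
        "habitat_area_km2": float(area),
    }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def extrapolate_abundance(density, area_km2: float) -> dict:
    """Scale a density estimate to a larger vegetated area.

    ``density`` may be a summary dict with ``q2.5``/``q50``/``q97.5`` keys
    (as returned by :func:`estimate_density`), an array of posterior density
    draws, or a single number.  Abundance percentiles are the density
    percentiles times ``area_km2``, rounded to the nearest whole animal
    (ties up).
    """
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    if isinstance(density, dict):
        lo, med, hi = density["q2.5"], density["q50"], density["q97.5"]
    else:
        d = np.asarray(density, dtype=float)
        if d.ndim == 0:
            lo = med = hi = float(d)
        else:
            lo, med, hi = np.percentile(d, [2.5, 50, 97.5])
    return {
        "median": _round_half_up(med * area_km2),
        "lo95": _round_half_up(lo * area_km2),
        "hi95": _round_half_up(hi * area_km2),
    }
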