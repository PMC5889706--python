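"""Synthetic landscapes, populations and survey data with the SMR model's structure.

The generator emulates a camera transect through a narrow coastal dune
forest: an autocorrelated canopy-height raster, a state space of 100-m
cells buffered around a line of camera stations, activity centers drawn
from the vegetation-weighted point process, sex-specific half-normal
detection at traps (captures) and cameras (resights) with a
days-since-baiting effect, aggregate counts for individuals never trapped
(the unmarked), and bivariate-normal telemetry for the collared marked
animals.  Defaults mirror the study conditions: 31 cameras ~311 m apart on
a linear transect, 39 daily occasions, baiting at setup and three ~8-day
revisits, traps ~1 km apart with 30 nights of effort, movement scales
sigma_female = 278 m and sigma_male = 1,141 m, and detection/point-process
coefficients at the fitted posterior means.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .habitat import CanopyGrid, StateSpace, build_state_space, compute_cover_fraction
from .smr.data import SMRData

__all__ = [
    "SimConfig",
    "TruePopulation",
    "simulate_landscape",
    "simulate_population",
    "simulate_captures",
    "simulate_resights",
    "simulate_telemetry",
    "camera_transect",
    "trap_line",
    "days_since_baiting",
    "simulate_dataset",
]

FEMALE, MALE = 1, 0


@dataclass
class SimConfig:
    """Study-condition constants for the generator.

    Detection and point-process coefficients default to the fitted values
    for the dune population; survey geometry defaults to the transect
    design (31 cameras ~311 m apart, 39 nightly occasions, rebaiting every
    ~8 days, trap line at ~1 km spacing with 30 nights each).
    """

    seed: int = 0
    N_true: int = 12
    sex_ratio_female: float = 0.6
    # point process (alpha0 only shifts the unnormalized intensity)
    alpha0: float = -1.55
    alpha1: float = 1.07
    # movement scales (m)
    sigma_female: float = 278.0
    sigma_male: float = 1141.0
    # capture (trap) logit: beta0 + beta1 * sex
    beta0: float = -1.91
    beta1: float = 0.79
    # resight (camera) logit: delta0 + delta1 * sex + delta2 * days
    delta0: float = -1.26
    delta1: float = 0.75
    delta2: float = -0.06
    # survey geometry / effort
    n_cameras: int = 31
    camera_spacing: float = 311.0
    n_occasions: int = 39
    baiting_occasions: tuple = (0, 8, 16, 24)
    trap_spacing: float = 1000.0
    trap_nights: int = 30
    # telemetry
    telemetry_locs_per_individual: int = 79
    # landscape / state space
    pixel_size: float = 50.0
    landscape_correlation_m: float = 300.0
    cover_radius: float = 100.0
    height_threshold: float = 1.0
    cover_threshold: float = 0.40
    buffer: float = 5000.0
    cell_size: float = 100.0

    def __post_init__(self) -> None:
        if self.N_true < 1:
            raise ValueError("N_true must be >= 1")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ValueError("sex_ratio_female must lie in [0, 1]")
        if self.sigma_female <= 0 or self.sigma_male <= 0:
            raise ValueError("movement scales must be positive")
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")
        if self.n_cameras < 1:
            raise ValueError("n_cameras must be >= 1")

    def sigma(self, sex) -> np.ndarray | float:
        sex = np.asarray(sex)
        out = np.where(sex == FEMALE, self.sigma_female, self.sigma_male)
        return float(out) if out.ndim == 0 else out


@dataclass
class TruePopulation:
    """Ground truth: activity centers, sexes, and (after trapping) marked flags."""

    s: np.ndarray  # (N, 2) activity centers (m)
    sex: np.ndarray  # (N,) 1 = female, 0 = male
    cell: np.ndarray  # (N,) state-space cell index of each center
    marked: np.ndarray = field(default=None)  # (N,) bool, set by simulate_captures

    @property
    def n(self) -> int:
        return self.s.shape[0]


def simulate_landscape(
    seed: int,
    n_rows: int = 60,
    n_cols: int = 240,
    pixel_size: float = 50.0,
    spatial_correlation_scale: float = 300.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> CanopyGrid:
    """Autocorrelated canopy-height raster (m) with vegetated patches and open sand.

    A Gaussian random field (white noise smoothed at the given correlation
    length, in meters) is rescaled to heights ``max(0, 2 + 2 * field)``:
    roughly a third of the landscape falls below a 1-m canopy, so cover
    fractions span [0, 1].  ``spatial_correlation_scale = 0`` gives
    independent pixels.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("raster dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_rows, n_cols))
    sigma_pix = spatial_correlation_scale / pixel_size
    if sigma_pix > 0:
        fieldv = ndimage.gaussian_filter(white, sigma_pix, mode="reflect")
        sd = fieldv.std()
        if sd > 0:
            fieldv = fieldv / sd
    else:
        fieldv = white
    heights = np.maximum(0.0, 2.0 + 2.0 * fieldv)
    return CanopyGrid(heights, origin=origin, pixel_size=pixel_size)


def simulate_population(
    state_space: StateSpace, config: SimConfig, rng: np.random.Generator | None = None
) -> TruePopulation:
    """Draw activity centers from the vegetation-weighted point process.

    Cell probabilities are ``p_g = area_g * exp(alpha1 * veg_g)`` normalized
    over the state space (the intercept cancels); each center is jittered
    uniformly within its cell, and sexes are i.i.d. Bernoulli.
    """
    rng = rng or np.random.default_rng(config.seed)
    mu = state_space.area_km2 * np.exp(config.alpha0 + config.alpha1 * state_space.veg)
    if not np.isfinite(mu).any() or mu.sum() <= 0:
        raise ValueError("point-process intensity is zero everywhere")
    p = mu / mu.sum()
    cells = rng.choice(state_space.n_cells, size=config.N_true, p=p)
    half = state_space.cell_size / 2.0
    jitter = rng.uniform(-half, half, size=(config.N_true, 2))
    s = np.column_stack((state_space.x[cells], state_space.y[cells])) + jitter
    sex = (rng.random(config.N_true) < config.sex_ratio_female).astype(np.int64)
    return TruePopulation(s=s, sex=sex, cell=cells)


def simulate_captures(
    pop: TruePopulation,
    traps: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial live-capture histories; individuals with >= 1 capture are marked.

    Returns ``(ycap, marked)`` where ``ycap`` is (N, n_traps) counts out of
    ``trap_nights`` and ``marked`` the boolean marked flags (also stored on
    ``pop``).
    """
    rng = rng or np.random.default_rng(config.seed)
    traps = np.atleast_2d(np.asarray(traps, dtype=float))
    d2 = ((pop.s[:, None, :] - traps[None, :, :]) ** 2).sum(axis=2)
    p0 = expit(config.beta0 + config.beta1 * pop.sex)[:, None]
    pcap = p0 * np.exp(-d2 / (2.0 * config.sigma(pop.sex)[:, None] ** 2))
    ycap = rng.binomial(config.trap_nights, pcap)
    marked = ycap.sum(axis=1) > 0
    pop.marked = marked
    return ycap, marked


def days_since_baiting(config: SimConfig) -> np.ndarray:
    """Integer days since the most recent baiting event, per camera and occasion.

    Bait is placed at setup (occasion 0) and replaced on each revisit; all
    cameras share the schedule.
    """
    resets = np.asarray(sorted(config.baiting_occasions))
    if resets.size == 0 or resets[0] != 0:
        raise ValueError("the baiting schedule must include occasion 0 (setup)")
    occ = np.arange(config.n_occasions)
    last = resets[np.searchsorted(resets, occ, side="right") - 1]
    days = occ - last
    return np.tile(days, (config.n_cameras, 1))


def simulate_resights(
    pop: TruePopulation,
    cameras: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    days: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bernoulli camera detections: identified for marked, counts for unmarked.

    Returns ``(ycam, nU, days)``: ``ycam`` is (n_marked, n_cameras,
    n_occasions) binary histories in the order of the marked individuals
    within ``pop``; the latent detections of unmarked individuals are summed
    into ``nU`` (n_cameras, n_occasions) without identity.
    """
    if pop.marked is None:
        raise ValueError("run simulate_captures first: marked status is undefined")
    rng = rng or np.random.default_rng(config.seed)
    cameras = np.atleast_2d(np.asarray(cameras, dtype=float))
    if days is None:
        days = days_since_baiting(config)
    d2 = ((pop.s[:, None, :] - cameras[None, :, :]) ** 2).sum(axis=2)
    kern = np.exp(-d2 / (2.0 * config.sigma(pop.sex)[:, None] ** 2))
    logit0 = config.delta0 + config.delta1 * pop.sex
    pcam = expit(logit0[:, None, None] + config.delta2 * days[None, :, :]) * kern[
        :, :, None
    ]
    y_all = (rng.random(pcam.shape) < pcam).astype(np.int8)
    ycam = y_all[pop.marked]
    nU = y_all[~pop.marked].sum(axis=0).astype(np.int64)
    return ycam, nU, days


def simulate_telemetry(
    pop: TruePopulation,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    collared: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Bivariate-normal telemetry fixes around each collared individual's center.

    ``collared`` is a boolean mask over the *marked* individuals (all marked
    by default; collars go only on trapped animals).  Returns one (n_i, 2)
    array per marked individual, empty for the uncollared; fixes are
    conceptually >= 1 h apart (independent draws).
    """
    if pop.marked is None:
        raise ValueError("run simulate_captures first: collars go on marked animals")
    rng = rng or np.random.default_rng(config.seed)
    marked_idx = np.nonzero(pop.marked)[0]
    if collared is None:
        collared = np.ones(marked_idx.size, dtype=bool)
    collared = np.asarray(collared, dtype=bool)
    out = []
    for pos, i in enumerate(marked_idx):
        if collared[pos] and config.telemetry_locs_per_individual > 0:
            locs = rng.normal(
                loc=pop.s[i],
                scale=config.sigma(int(pop.sex[i])),
                size=(config.telemetry_locs_per_individual, 2),
            )
        else:
            locs = np.empty((0, 2))
        out.append(locs)
    return out


def camera_transect(config: SimConfig, y: float = 0.0) -> np.ndarray:
    """Camera stations on a west-east line at the given northing."""
    x = np.arange(config.n_cameras) * config.camera_spacing
    return np.column_stack((x, np.full(config.n_cameras, y)))


def trap_line(config: SimConfig, state_space: StateSpace, y: float = 0.0) -> np.ndarray:
    """Traps at ``trap_spacing`` along the transect axis, clipped to the state space.

    The nominal line is centered on the camera transect and extends past it;
    traps outside the state-space bounding box are dropped so every trap can
    plausibly catch an animal whose center is in the state space.
    """
    cams = camera_transect(config, y=y)
    mid = cams[:, 0].mean()
    half_extent = max(np.ptp(cams[:, 0]) / 2.0 + config.trap_spacing, config.trap_spacing)
    n_side = int(np.ceil(half_extent / config.trap_spacing)) + 5
    x = mid + np.arange(-n_side, n_side + 1) * config.trap_spacing
    traps = np.column_stack((x, np.full(x.size, y)))
    inside = (
        (traps[:, 0] >= state_space.x.min() - state_space.cell_size / 2)
        & (traps[:, 0] <= state_space.x.max() + state_space.cell_size / 2)
        & (traps[:, 1] >= state_space.y.min() - state_space.cell_size / 2)
        & (traps[:, 1] <= state_space.y.max() + state_space.cell_size / 2)
    )
    return traps[inside]


def simulate_dataset(
    config: SimConfig | None = None,
) -> tuple[SMRData, TruePopulation, StateSpace]:
    """End-to-end generator: landscape -> state space -> population -> survey.

    One ``config.seed`` drives child streams for the landscape, population,
    captures, resights and telemetry, so each stage is independently
    reproducible.  Returns the assembled :class:`SMRData`, the ground truth
    and the state space.
    """
    config = config or SimConfig()
    kids = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(k) for k in kids]

    cams = camera_transect(config)
    extent_x = cams[:, 0].max() - cams[:, 0].min()
    pad = config.buffer + 2 * config.cover_radius
    n_cols = int(np.ceil((extent_x + 2 * pad) / config.pixel_size))
    n_rows = int(np.ceil(2 * pad / config.pixel_size))
    origin = (cams[:, 0].min() - pad, -pad)
    canopy = simulate_landscape(
        seed=int(kids[0].generate_state(1)[0] % 2**31),
        n_rows=n_rows,
        n_cols=n_cols,
        pixel_size=config.pixel_size,
        spatial_correlation_scale=config.landscape_correlation_m,
        origin=origin,
    )
    cover = compute_cover_fraction(canopy, config.cover_radius, config.height_threshold)
    ss = build_state_space(
        cams,
        buffer=config.buffer,
        cell_size=config.cell_size,
        cover=cover,
        cover_threshold=config.cover_threshold,
    )

    pop = simulate_population(ss, config, rngs[1])
    traps = trap_line(config, ss)
    ycap, marked = simulate_captures(pop, traps, config, rngs[2])
    ycam, nU, days = simulate_resights(pop, cams, config, rngs[3])
    telemetry = simulate_telemetry(pop, config, rngs[4])

    data = SMRData(
        ycap=ycap[marked],
        Ktrap=np.full(traps.shape[0], config.trap_nights),
        trap_xy=traps,
        ycam=ycam,
        cam_xy=cams,
        nU=nU,
        days=days,
        sex=pop.sex[marked],
        telemetry=telemetry,
        state_space=ss,
    )
    return data, pop, ss
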