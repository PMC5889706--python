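"""MCMC engine checks: internal kernels, posterior invariants, degenerate cases."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from smrpva.habitat import StateSpace
from smrpva.smr import (
    MCMCConfig,
    SMRData,
    SMRParams,
    SMRPosterior,
    estimate_density,
    extrapolate_abundance,
    fit_smr,
    poisson_binomial_logpmf,
    resight_probability,
)
from smrpva.smr import _sampler
from smrpva.smr.data import thin_locations
from smrpva.synthetic import simulate_dataset

from conftest import small_sim_config


def tiny_space(n=4):
    return StateSpace(
        x=np.arange(n) * 100.0 + 50.0,
        y=np.full(n, 50.0),
        area_km2=np.full(n, 0.01),
        veg=np.linspace(0, 1, n),
        habitat=np.ones(n, bool),
        cell_size=100.0,
        row=np.zeros(n, int),
        col=np.arange(n),
        grid_shape=(1, n),
        grid_origin=(0.0, 0.0),
    )


class TestCompiledKernelsAgainstPureLikelihoods:
    """The njit likelihood pieces must reproduce the reference functions."""

    def test_camera_loglik_histogram_plus_corrections(self):
        rng = np.random.default_rng(0)
        C, K = 5, 11
        days = np.tile(np.arange(K) % 4, (C, 1))
        cam_xy = np.column_stack((np.arange(C) * 250.0, np.zeros(C)))
        cell = np.array([125.0, 40.0])
        params = SMRParams(delta0=-1.1, delta1=0.6, delta2=-0.07,
                           sigma_female=300.0, sigma_male=900.0)
        ycam = (rng.random((C, K)) < 0.25).astype(np.int8)

        d = np.sqrt(((cam_xy - cell) ** 2).sum(axis=1))
        p = resight_probability(params, d[:, None], 1, days)
        want = float((ycam * np.log(p) + (1 - ycam) * np.log1p(-p)).sum())

        dvals, dinv = np.unique(days, return_inverse=True)
        didx = dinv.reshape(C, K)
        hist = np.zeros((C, dvals.size))
        for j in range(C):
            for k in range(K):
                hist[j, didx[j, k]] += 1.0
        base = expit(params.delta0 + params.delta1 + params.delta2 * dvals)
        D2c = ((np.array([[cell[0]]]) - cam_xy[:, 0]) ** 2
               + (np.array([[cell[1]]]) - cam_xy[:, 1]) ** 2)
        jj, kk = np.nonzero(ycam)
        got = _sampler._cam_hist_ll_i(
            0, params.sigma_female**2, base, D2c, hist
        ) + _sampler._cam_det_corr_i(
            0, params.sigma_female**2, base, D2c,
            jj.astype(np.int64), didx[jj, kk].astype(np.int64), 0, jj.size,
        )
        assert got == pytest.approx(want, abs=1e-9)

    def test_capture_loglik_matches_binomial_logpmf(self):
        rng = np.random.default_rng(1)
        J = 6
        trap_xy = np.column_stack((np.arange(J) * 400.0, np.zeros(J)))
        cell = np.array([700.0, 30.0])
        Ktrap = np.full(J, 12.0)
        sigma, p0 = 500.0, 0.3
        d2 = ((trap_xy - cell) ** 2).sum(axis=1)
        p = p0 * np.exp(-d2 / (2 * sigma**2))
        y = rng.binomial(12, p)
        want = float(stats.binom.logpmf(y, 12, p).sum())
        # the compiled kernel drops the constant binomial coefficients
        const = float(
            sum(stats.binom.logpmf(yi, 12, 0.5) - yi * np.log(0.5)
                - (12 - yi) * np.log(0.5) for yi in y)
        )
        jj = np.nonzero(y)[0].astype(np.int64)
        got = _sampler._cap_ll_i(
            0, p0, sigma**2, d2[None, :], Ktrap,
            jj, y[jj].astype(float), 0, jj.size,
        )
        assert got + const == pytest.approx(want, abs=1e-9)

    def test_poisson_binomial_add_remove_roundtrip(self):
        rng = np.random.default_rng(2)
        P, nmax = 4, 3
        f = np.zeros((P, nmax + 1))
        f[:, 0] = 1.0
        probs = [rng.uniform(0.05, 0.6, P) for _ in range(5)]
        for p in probs:
            _sampler._pb_add(f, p)
        pos_n = np.array([0, 1, 2, 3], dtype=np.int64)
        want = sum(
            poisson_binomial_logpmf(int(n), np.array([p[c] for p in probs]))
            for c, n in enumerate(pos_n)
        )
        assert _sampler._pb_base(f, pos_n) == pytest.approx(want, abs=1e-10)
        # removing and re-adding an individual must be an exact inverse
        snap = f.copy()
        _sampler._pb_remove(f, probs[2])
        _sampler._pb_add(f, probs[2])
        assert np.allclose(f, snap, atol=1e-12)
        # the include-one ratio agrees with a fresh dynamic program
        _sampler._pb_remove(f, probs[2])
        got = _sampler._pb_w(f, probs[2], pos_n)
        assert got == pytest.approx(want, abs=1e-10)


class TestPosterior:
    def test_draw_bookkeeping_and_invariants(self, tiny_fit):
        data, pop, ss, mcmc, post = tiny_fit
        n_expected = mcmc.chains * (mcmc.iterations - mcmc.burn_in) // mcmc.thin
        assert len(post.draws) == n_expected
        assert set(post.rhat) == set(
            ["beta0", "beta1", "delta0", "delta1", "delta2", "alpha1",
             "sigma_female", "sigma_male", "psi", "phi", "N", "density"]
        )
        d = post.draws
        assert (d["N"] <= mcmc.M_aug).all()
        assert (d["N"] >= data.n_marked).all()
        assert (d["density"] >= 0).all()
        assert np.allclose(d["density"], d["n_habitat"] / ss.habitat_area_km2)
        assert ((d["sigma_female"] > 0) & (d["sigma_female"] < 5000)).all()
        assert ((d["psi"] > 0) & (d["psi"] < 1)).all()
        summ = post.summary()
        assert {"mean", "sd", "q2.5", "q50", "q97.5", "rhat"} <= set(summ.columns)

    def test_no_data_recovers_uniform_inclusion_prior(self):
        # no traps, no cameras, no telemetry: psi must return its U(0,1) prior
        data = SMRData(
            ycap=np.zeros((0, 0), dtype=int),
            Ktrap=np.zeros(0, dtype=int),
            trap_xy=np.zeros((0, 2)),
            ycam=np.zeros((0, 0, 0), dtype=np.int8),
            cam_xy=np.zeros((0, 2)),
            nU=np.zeros((0, 0), dtype=int),
            days=np.zeros((0, 0), dtype=int),
            sex=np.zeros(0, dtype=int),
            telemetry=[],
            state_space=tiny_space(),
        )
        post = fit_smr(
            data,
            MCMCConfig(chains=2, iterations=3000, burn_in=500, thin=1, M_aug=30,
                       seed=3),
        )
        psi = post.draws["psi"].to_numpy()
        assert psi.mean() == pytest.approx(0.5, abs=0.05)
        assert psi.std() == pytest.approx(np.sqrt(1 / 12), abs=0.04)
        # N | psi ~ Binomial(M, psi) marginalizes to uniform on 0..M
        assert post.draws["N"].mean() == pytest.approx(15.0, abs=1.5)

    def test_individual_order_does_not_move_the_posterior(self):
        cfg = small_sim_config(seed=31, trap_nights=6)
        data, pop, ss = simulate_dataset(cfg)
        assert data.n_marked >= 2
        flipped = SMRData(
            ycap=data.ycap[::-1].copy(),
            Ktrap=data.Ktrap,
            trap_xy=data.trap_xy,
            ycam=data.ycam[::-1].copy(),
            cam_xy=data.cam_xy,
            nU=data.nU,
            days=data.days,
            sex=data.sex[::-1].copy(),
            telemetry=list(reversed(data.telemetry)),
            state_space=ss,
        )
        mcmc = MCMCConfig(chains=2, iterations=2500, burn_in=1000, thin=1,
                          M_aug=20, seed=5)
        a = fit_smr(data, mcmc).draws
        b = fit_smr(flipped, mcmc).draws
        assert a["N"].mean() == pytest.approx(b["N"].mean(), abs=0.5)
        assert a["density"].mean() == pytest.approx(b["density"].mean(), rel=0.1)

    def test_more_telemetry_sharpens_movement_scale(self):
        sds = []
        for nlocs in (5, 50, 500):
            cfg = small_sim_config(seed=17, sex_ratio_female=1.0,
                                   telemetry_locs_per_individual=nlocs)
            data, _, _ = simulate_dataset(cfg)
            post = fit_smr(
                data,
                MCMCConfig(chains=2, iterations=1200, burn_in=600, thin=2,
                           M_aug=16, seed=9),
            )
            sds.append(post.draws["sigma_female"].std())
        assert sds[0] > sds[1] > sds[2]

    def test_saturated_augmentation_warns(self):
        cfg = small_sim_config(seed=19, beta0=8.0, trap_nights=10)  # census
        data, pop, _ = simulate_dataset(cfg)
        assert data.nU.sum() == 0
        with pytest.warns(UserWarning, match="saturated"):
            fit_smr(
                data,
                MCMCConfig(chains=2, iterations=600, burn_in=300, thin=1,
                           M_aug=data.n_marked, seed=2),
            )

    def test_augmentation_too_small_for_counts_rejected(self):
        data, _, _ = simulate_dataset(small_sim_config(seed=23))
        data.nU[0, 0] = 99
        with pytest.raises(ValueError, match="M_aug"):
            fit_smr(data, MCMCConfig(chains=2, iterations=100, burn_in=50,
                                     M_aug=data.n_marked + 1, seed=0))


class TestDensitySummaries:
    def _posterior_with_counts(self, counts, area):
        draws = pd.DataFrame({"n_habitat": np.asarray(counts, float)})
        return SMRPosterior(
            draws=draws, rhat={}, config=MCMCConfig(), habitat_area_km2=area
        )

    def _space_with_area(self, km2):
        n = 2
        return StateSpace(
            x=[50.0, 150.0], y=[50.0, 50.0], area_km2=[km2 / 2, km2 / 2],
            veg=[0.9, 0.9], habitat=[True, True], cell_size=100.0,
            row=np.zeros(n, int), col=np.arange(n), grid_shape=(1, n),
            grid_origin=(0.0, 0.0),
        )

    def test_constant_draws_fixed_area(self):
        post = self._posterior_with_counts([10] * 40, 8.6)
        out = estimate_density(post, self._space_with_area(8.6))
        assert out["mean"] == pytest.approx(10 / 8.6, abs=1e-12)
        assert out["mean"] == pytest.approx(1.1628, abs=1e-4)
        assert out["sd"] == 0.0

    def test_halving_habitat_doubles_density(self):
        post = self._posterior_with_counts(np.arange(5, 15), 4.3)
        a = estimate_density(post, self._space_with_area(8.6))
        b = estimate_density(post, self._space_with_area(4.3))
        assert b["mean"] == pytest.approx(2 * a["mean"])

    def test_zero_habitat_area_rejected(self):
        post = self._posterior_with_counts([1], 0.0)
        space = self._space_with_area(8.6)
        space.habitat[:] = False
        with pytest.raises(ValueError):
            estimate_density(post, space)

    def test_extrapolation_rounding(self):
        summ = {"q2.5": 0.81, "q50": 1.15, "q97.5": 1.39}
        north = extrapolate_abundance(summ, 36.9)
        assert north == {"median": 42, "lo95": 30, "hi95": 51}
        # ties round up, densities of zero stay zero
        assert extrapolate_abundance({"q2.5": 0.5, "q50": 0.5, "q97.5": 0.5},
                                     85.0)["median"] == 43
        assert extrapolate_abundance(0.0, 10.0)["median"] == 0
        with pytest.raises(ValueError):
            extrapolate_abundance(summ, -1.0)

    def test_extrapolation_from_draws_uses_percentiles(self):
        draws = np.linspace(0.8, 1.4, 1001)
        out = extrapolate_abundance(draws, 10.0)
        assert out["median"] == round(np.percentile(draws, 50) * 10)


def test_telemetry_thinning_keeps_hourly_spacing():
    xy = np.column_stack((np.arange(10.0), np.zeros(10)))
    times = np.array([0, 600, 3600, 4000, 7200, 7300, 10800, 10900, 14400, 20000.0])
    out = thin_locations(xy, times, min_gap_s=3600.0)
    assert out[:, 0].tolist() == [0.0, 2.0, 4.0, 6.0, 8.0, 9.0]
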