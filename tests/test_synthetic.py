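"""Generator checks: determinism, analytic detection rates, file round-trips."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from smrpva.habitat import StateSpace, compute_cover_fraction, make_habitat_mask
from smrpva.io import read_ascii_grid, read_dataset, write_ascii_grid, write_dataset
from smrpva.synthetic import (
    SimConfig,
    TruePopulation,
    camera_transect,
    days_since_baiting,
    simulate_captures,
    simulate_dataset,
    simulate_landscape,
    simulate_population,
    simulate_resights,
    simulate_telemetry,
)

from conftest import small_sim_config


def uniform_space(n=10, veg=0.5):
    return StateSpace(
        x=np.arange(n) * 100.0 + 50.0,
        y=np.full(n, 50.0),
        area_km2=np.full(n, 0.01),
        veg=np.full(n, veg),
        habitat=np.ones(n, bool),
        cell_size=100.0,
        row=np.zeros(n, int),
        col=np.arange(n),
        grid_shape=(1, n),
        grid_origin=(0.0, 0.0),
    )


class TestLandscape:
    def test_seed_determinism(self):
        a = simulate_landscape(3, 20, 30)
        b = simulate_landscape(3, 20, 30)
        assert np.array_equal(a.values, b.values)

    def test_zero_correlation_gives_independent_pixels(self):
        g = simulate_landscape(1, 200, 200, spatial_correlation_scale=0.0)
        v = g.values
        lag1 = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert abs(lag1) < 0.05

    def test_default_landscape_yields_habitat_under_cover_rule(self):
        g = simulate_landscape(2, 60, 60, pixel_size=50.0,
                               spatial_correlation_scale=300.0)
        cover = compute_cover_fraction(g, 100.0, 1.0)
        mask = make_habitat_mask(cover, 0.40)
        assert 0 < mask.sum() < mask.size  # vegetated patches and open sand


class TestPopulation:
    def test_homogeneous_intensity_is_uniform(self):
        ss = uniform_space(n=8)
        cfg = SimConfig(seed=0, N_true=8000, alpha1=0.0)
        pop = simulate_population(ss, cfg)
        counts = np.bincount(pop.cell, minlength=8)
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_two_cell_closed_form_weighting(self, two_cell_space):
        cfg = SimConfig(seed=1, N_true=20000, alpha1=np.log(4.0))
        pop = simulate_population(two_cell_space, cfg)
        frac = (pop.cell == 1).mean()
        assert frac == pytest.approx(0.8, abs=0.01)

    def test_fitted_effect_concentrates_centers_in_cover(self):
        rng_ss = np.random.default_rng(2)
        n = 50
        ss = uniform_space(n)
        ss.veg = rng_ss.uniform(0, 1, n)
        pop = simulate_population(ss, SimConfig(seed=3, N_true=4000, alpha1=1.07))
        assert ss.veg[pop.cell].mean() > ss.veg.mean() + 0.02

    def test_sexes_follow_ratio(self):
        pop = simulate_population(uniform_space(), SimConfig(seed=4, N_true=5000,
                                                             sex_ratio_female=0.6))
        assert pop.sex.mean() == pytest.approx(0.6, abs=0.03)

    def test_jitter_stays_within_cell(self):
        ss = uniform_space()
        pop = simulate_population(ss, SimConfig(seed=5, N_true=500))
        assert (np.abs(pop.s[:, 0] - ss.x[pop.cell]) <= 50.0).all()
        assert (np.abs(pop.s[:, 1] - ss.y[pop.cell]) <= 50.0).all()


class TestCaptures:
    def test_monte_carlo_rate_matches_halfnormal_logistic_product(self):
        # one female at 300 m from a single trap, many independent nights
        cfg = SimConfig(seed=6, trap_nights=40000, beta0=-1.0, beta1=0.5,
                        sigma_female=278.0)
        pop = TruePopulation(
            s=np.array([[0.0, 0.0]]), sex=np.array([1]), cell=np.array([0])
        )
        ycap, marked = simulate_captures(pop, np.array([[300.0, 0.0]]), cfg)
        want = expit(-0.5) * np.exp(-(300.0**2) / (2 * 278.0**2))
        se = np.sqrt(want * (1 - want) / cfg.trap_nights)
        assert ycap[0, 0] / cfg.trap_nights == pytest.approx(want, abs=4 * se)
        assert marked[0]

    def test_capture_rate_at_one_sigma_is_e_minus_half(self):
        cfg = SimConfig(seed=7, trap_nights=40000, beta0=0.0, beta1=0.0,
                        sigma_male=500.0)
        pop = TruePopulation(
            s=np.array([[0.0, 0.0]]), sex=np.array([0]), cell=np.array([0])
        )
        ycap, _ = simulate_captures(pop, np.array([[500.0, 0.0]]), cfg)
        want = 0.5 * np.exp(-0.5)
        se = np.sqrt(want * (1 - want) / cfg.trap_nights)
        assert ycap[0, 0] / cfg.trap_nights == pytest.approx(want, abs=4 * se)

    def test_saturation_limit_marks_everyone(self):
        cfg = SimConfig(seed=8, beta0=30.0, sigma_female=1e9, sigma_male=1e9,
                        trap_nights=5)
        pop = TruePopulation(s=np.random.default_rng(0).uniform(0, 1000, (20, 2)),
                             sex=np.zeros(20, int), cell=np.zeros(20, int))
        ycap, marked = simulate_captures(pop, np.array([[500.0, 500.0]]), cfg)
        assert (ycap == cfg.trap_nights).all() and marked.all()


class TestResights:
    def test_logistic_identity_at_camera(self):
        # marked female sitting on the camera, delta0 + delta1 = 0: p = 0.5
        cfg = SimConfig(seed=9, delta0=-0.75, delta1=0.75, delta2=0.0,
                        n_cameras=1, n_occasions=20000, baiting_occasions=(0,))
        pop = TruePopulation(s=np.array([[0.0, 0.0]]), sex=np.array([1]),
                             cell=np.array([0]))
        pop.marked = np.array([True])
        ycam, nU, _ = simulate_resights(pop, np.array([[0.0, 0.0]]), cfg)
        freq = ycam[0, 0].mean()
        assert freq == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / cfg.n_occasions))
        assert nU.sum() == 0

    def test_bait_decay_lowers_detection_eight_days_out(self):
        # rebait every 9 days so the days covariate cycles 0..8
        n_occ = 4500
        cfg = SimConfig(seed=10, delta0=0.0, delta1=0.0, delta2=-0.06,
                        n_cameras=1, n_occasions=n_occ,
                        baiting_occasions=tuple(range(0, n_occ, 9)))
        pop = TruePopulation(s=np.array([[0.0, 0.0]]), sex=np.array([0]),
                             cell=np.array([0]))
        pop.marked = np.array([True])
        ycam, _, days = simulate_resights(pop, np.array([[0.0, 0.0]]), cfg)
        hist = ycam[0, 0]
        f0 = hist[days[0] == 0].mean()
        f8 = hist[days[0] == 8].mean()
        assert f0 > f8
        assert f0 == pytest.approx(expit(0.0), abs=0.04)
        assert f8 == pytest.approx(expit(-0.48), abs=0.04)

    def test_fully_marked_population_leaves_no_unmarked_counts(self):
        cfg = small_sim_config(seed=12, beta0=10.0, trap_nights=20)
        data, pop, _ = simulate_dataset(cfg)
        assert pop.marked.all()
        assert data.nU.sum() == 0

    def test_days_matrix_resets_at_baiting(self):
        cfg = SimConfig(n_occasions=12, baiting_occasions=(0, 5), n_cameras=2)
        days = days_since_baiting(cfg)
        assert days.shape == (2, 12)
        assert days[0].tolist() == [0, 1, 2, 3, 4, 0, 1, 2, 3, 4, 5, 6]


class TestTelemetry:
    def test_location_moments(self):
        cfg = SimConfig(seed=13, telemetry_locs_per_individual=10000,
                        sigma_female=278.0)
        pop = TruePopulation(s=np.array([[120.0, -40.0]]), sex=np.array([1]),
                             cell=np.array([0]))
        pop.marked = np.array([True])
        locs = simulate_telemetry(pop, cfg)[0]
        n = locs.shape[0]
        assert locs.mean(axis=0) == pytest.approx([120.0, -40.0],
                                                  abs=4 * 278.0 / np.sqrt(n))
        assert locs[:, 0].std() == pytest.approx(278.0, rel=0.05)

    def test_uncollared_marked_get_empty_tracks(self):
        cfg = SimConfig(seed=14, telemetry_locs_per_individual=25)
        pop = TruePopulation(s=np.zeros((3, 2)), sex=np.array([1, 0, 1]),
                             cell=np.zeros(3, int))
        pop.marked = np.array([True, True, True])
        tel = simulate_telemetry(pop, cfg, collared=np.array([True, False, True]))
        assert tel[0].shape == (25, 2) and tel[1].shape == (0, 2)


class TestDatasetAssembly:
    def test_shapes_and_seed_determinism(self):
        cfg = small_sim_config()
        d1, pop, ss = simulate_dataset(cfg)
        d2, _, _ = simulate_dataset(cfg)
        assert d1.ycap.shape == (d1.n_marked, d1.n_traps)
        assert d1.ycam.shape == (d1.n_marked, cfg.n_cameras, cfg.n_occasions)
        assert d1.nU.shape == (cfg.n_cameras, cfg.n_occasions)
        assert np.array_equal(d1.ycap, d2.ycap)
        assert np.array_equal(d1.nU, d2.nU)
        assert all(np.array_equal(a, b) for a, b in zip(d1.telemetry, d2.telemetry))
        # marked animals all have at least one capture
        assert (d1.ycap.sum(axis=1) > 0).all()

    def test_transect_geometry(self):
        cams = camera_transect(SimConfig(n_cameras=31, camera_spacing=311.0))
        assert cams.shape == (31, 2)
        assert np.allclose(np.diff(cams[:, 0]), 311.0)

    def test_csv_round_trip(self, tmp_path):
        data, _, _ = simulate_dataset(small_sim_config(seed=21))
        write_dataset(data, tmp_path)
        back = read_dataset(tmp_path)
        assert np.array_equal(back.ycap, data.ycap)
        assert np.array_equal(back.ycam, data.ycam)
        assert np.array_equal(back.nU, data.nU)
        assert np.array_equal(back.days, data.days)
        assert np.array_equal(back.sex, data.sex)
        assert back.state_space.n_cells == data.state_space.n_cells
        assert np.allclose(back.state_space.veg, data.state_space.veg)
        for a, b in zip(back.telemetry, data.telemetry):
            assert np.allclose(a, b)

    def test_ascii_grid_round_trip(self, tmp_path):
        g = simulate_landscape(5, 12, 9, pixel_size=25.0, origin=(100.0, -200.0))
        g.values[3, 4] = np.nan
        write_ascii_grid(g, tmp_path / "canopy.asc")
        back = read_ascii_grid(tmp_path / "canopy.asc")
        assert np.allclose(back.values, g.values, equal_nan=True, atol=1e-5)
        assert back.origin == g.origin and back.pixel_size == g.pixel_size
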