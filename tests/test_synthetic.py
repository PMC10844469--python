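"""Synthetic culture generator and response-model tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microstim import (
    CELL_COLUMNS,
    CultureConfig,
    ResponseModelParams,
    activation_probability,
    generate_culture,
    simulate_response,
)
from microstim.synthetic import DENSE_DENSITY, SPARSE_DENSITY, sparse_preset


class TestGenerateCulture:
    def test_zero_density_gives_empty_culture(self):
        cells = generate_culture(CultureConfig(density=0.0, seed=1))
        assert len(cells) == 0
        assert list(cells.columns) == CELL_COLUMNS

    def test_mean_count_matches_poisson_expectation(self):
        """Thomas process realized counts average to density * area."""
        counts = [
            len(generate_culture(CultureConfig(density=400.0, seed=s))) for s in range(200)
        ]
        mean = np.mean(counts)
        # Thomas-process count variance: mean * (1 + offspring mean)
        se = np.sqrt(400.0 * (1 + 8.0) / 200)
        assert abs(mean - 400.0) < 3 * se

    def test_sparse_preset_below_1000_per_mm2(self):
        cells = generate_culture(sparse_preset(seed=3))
        cfg = sparse_preset(seed=3)
        assert len(cells) / cfg.area_mm2 < 1000.0

    def test_positions_inside_field(self):
        cfg = CultureConfig(density=800.0, field_width_um=600.0, field_height_um=400.0, seed=5)
        cells = generate_culture(cfg)
        assert cells["x_um"].between(0, 600).all()
        assert cells["y_um"].between(0, 400).all()

    def test_ratio_consistency_and_positivity(self):
        cells = generate_culture(CultureConfig(density=500.0, seed=7))
        assert (cells["cyt_intensity"] > 0).all()
        np.testing.assert_allclose(
            cells["nuc_cyt_ratio"], cells["nuc_intensity"] / cells["cyt_intensity"]
        )

    def test_seed_determinism_byte_identical(self):
        a = generate_culture(CultureConfig(density=400.0, seed=9))
        b = generate_culture(CultureConfig(density=400.0, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_overflow_guard(self):
        with pytest.raises(ValueError, match="refusing"):
            generate_culture(CultureConfig(density=1e6, field_width_um=2000, field_height_um=2000))

    def test_clustering_produces_more_neighbors_than_uniform(self):
        """The point of the Thomas process: clumped cultures."""
        from microstim import neighbor_counts

        cells = generate_culture(CultureConfig(density=400.0, seed=13))
        clustered = neighbor_counts(cells)["n_neighbors"].mean()
        rng = np.random.default_rng(13)
        uniform = cells.copy()
        uniform["x_um"] = rng.uniform(0, 1000, len(cells))
        uniform["y_um"] = rng.uniform(0, 1000, len(cells))
        assert clustered > 2 * neighbor_counts(uniform)["n_neighbors"].mean()


class TestActivationProbability:
    def test_zero_concentration_gives_background(self, response_params):
        assert activation_probability(0.0, 15.0, 400.0, response_params) == pytest.approx(
            response_params.background_rate
        )

    def test_logistic_midpoint_at_ec50(self):
        params = ResponseModelParams(background_rate=0.0)
        ec50 = params.ec50_effective(400.0, 15.0)
        assert activation_probability(ec50, 15.0, 400.0, params) == pytest.approx(0.5)

    def test_dense_5min_threshold_is_tenfold_sparse(self, response_params):
        """At 5-min stimulation the dense-culture threshold is 10x higher."""
        dense = response_params.ec50_effective(DENSE_DENSITY, 5.0)
        sparse = response_params.ec50_effective(SPARSE_DENSITY, 5.0)
        assert dense / sparse == pytest.approx(10.0)

    def test_below_minimum_stimulation_time_only_background(self, response_params):
        p = activation_probability(1e4, 3.0, 400.0, response_params)
        assert p == pytest.approx(response_params.background_rate)

    def test_density_shift_vanishes_at_restore_time(self, response_params):
        assert response_params.ec50_effective(DENSE_DENSITY, 15.0) == pytest.approx(
            response_params.ec50_base_nM
        )

    def test_monotonicity_in_dose_time_density(self, response_params):
        conc = np.logspace(-1, 4, 60)
        p = activation_probability(conc, 5.0, 400.0, response_params)
        assert np.all(np.diff(p) >= 0)
        for c in (10.0, 100.0, 1000.0):
            p_times = [
                activation_probability(c, t, DENSE_DENSITY, response_params)
                for t in (5.0, 8.0, 11.0, 15.0, 30.0)
            ]
            assert np.all(np.diff(p_times) >= -1e-12)
            p_dens = [
                activation_probability(c, 5.0, d, response_params)
                for d in (200.0, 1000.0, 2500.0, 3750.0)
            ]
            assert np.all(np.diff(p_dens) <= 1e-12)

    def test_invalid_inputs_rejected(self, response_params):
        with pytest.raises(ValueError):
            activation_probability(-1.0, 5.0, 400.0, response_params)
        with pytest.raises(ValueError):
            activation_probability(1.0, -5.0, 400.0, response_params)


class TestSimulateResponse:
    def test_zero_concentration_background_fraction(self, sparse_culture, response_params):
        """Null bath: ground-truth activated fraction ~ background rate."""
        big = generate_culture(CultureConfig(density=1000.0, seed=2))
        out = simulate_response(big, 0.0, 5.0, response_params, seed=3, density=1000.0)
        k = int(out["ground_truth"].sum())
        lo, hi = stats.binom.interval(0.99, len(out), response_params.background_rate)
        assert lo <= k <= hi

    def test_forced_activation_probability_one(self, sparse_culture):
        params = ResponseModelParams(background_rate=0.0)
        out = simulate_response(sparse_culture, 1e9, 15.0, params, seed=4, density=400.0)
        assert out["ground_truth"].all()

    def test_activated_cells_draw_higher_ratios(self, sparse_culture, response_params):
        out = simulate_response(sparse_culture, 100.0, 15.0, response_params, seed=5, density=400.0)
        act = out.loc[out["ground_truth"].astype(bool), "nuc_cyt_ratio"]
        rest = out.loc[~out["ground_truth"].astype(bool), "nuc_cyt_ratio"]
        assert act.median() > 1.2 * rest.median()

    def test_single_cell_target_vs_dense_bath_contrast(self, response_params):
        """100 nM for 5 min: strong single-cell response, weak dense-culture one."""
        p_target = activation_probability(100.0, 5.0, SPARSE_DENSITY, response_params)
        p_dense_bath = activation_probability(100.0, 5.0, DENSE_DENSITY, response_params)
        assert p_target > 0.5
        assert p_dense_bath < 0.15

    @pytest.mark.parametrize("p_target", [0.06, 0.5, 0.85])
    def test_parameter_recovery_within_binomial_interval(self, p_target):
        """Configured activation probabilities are recovered over n = 2000."""
        b = 0.05
        if p_target <= b:
            params = ResponseModelParams(background_rate=p_target)
            conc = 0.0
        else:
            # invert the logistic: choose conc so p(conc) == p_target
            params = ResponseModelParams()
            u = (p_target - b) / (1 - b)
            conc = 100.0 * 10 ** (np.log(u / (1 - u)) / 4.0)
        cells = generate_culture(CultureConfig(density=2000.0, seed=31))
        assert len(cells) > 1500
        out = simulate_response(cells, conc, 15.0, params, seed=32, density=1000.0)
        k = int(out["ground_truth"].sum())
        lo, hi = stats.binom.interval(0.99, len(out), p_target)
        assert lo <= k <= hi

    def test_seed_determinism(self, sparse_culture, response_params):
        a = simulate_response(sparse_culture, 50.0, 5.0, response_params, seed=8, density=400.0)
        b = simulate_response(sparse_culture, 50.0, 5.0, response_params, seed=8, density=400.0)
        pd.testing.assert_frame_equal(a, b)

    def test_field_stimulus_fills_local_concentration(self, sparse_culture, cluster_cond):
        from microstim import ConcentrationField

        field = ConcentrationField(cluster_cond, origin_um=(500.0, 500.0))
        out = simulate_response(sparse_culture, field, 5.0, seed=9, density=400.0)
        assert out["conc_nM"].notna().all()
        r = np.hypot(out["x_um"] - 500.0, out["y_um"] - 500.0)
        # nearest cell to the dispensing point sees the highest concentration
        assert out["conc_nM"].idxmax() == r.idxmin()
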