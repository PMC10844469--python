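"""Dispensing-diffusion concentration field tests against closed-form and
finite-difference oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microstim import (
    ConcentrationField,
    DispenseConditions,
    calibrated_flow,
    cmax_uncertainty,
    concentration_at_cells,
    relative_cmax_uncertainty,
    steady_state_concentration,
    transient_concentration,
)
from microstim.diffusion import field_table

from _oracles import oracle_for_conditions


class TestDispenseConditions:
    def test_mode_height_defaults(self):
        assert DispenseConditions(c0_nM=5500, mode="single_cell").height_um == 4.0
        assert DispenseConditions(c0_nM=318, mode="cluster").height_um == 20.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            DispenseConditions(c0_nM=-1.0, mode="cluster")
        with pytest.raises(ValueError):
            DispenseConditions(c0_nM=100.0, mode="bath")
        with pytest.raises(ValueError):
            DispenseConditions(c0_nM=100.0, mode="cluster", duration_s=0.0)

    def test_calibrated_flows_match_expected_magnitudes(self):
        # ~0.23 pL/s single-cell, ~20 pL/s cluster
        assert calibrated_flow("single_cell") == pytest.approx(0.23e-15, rel=0.05)
        assert calibrated_flow("cluster") == pytest.approx(20e-15, rel=0.05)


class TestSteadyState:
    def test_cluster_cmax_anchor(self, cluster_cond):
        """C0 = 318 nM cluster dispensing peaks near 100 nM at the surface."""
        assert steady_state_concentration(0.0, cluster_cond) == pytest.approx(100.0, rel=1e-6)

    def test_single_cell_cmax_anchor(self, single_cell_cond):
        assert steady_state_concentration(0.0, single_cell_cond) == pytest.approx(100.0, rel=1e-6)

    def test_linear_in_c0(self, cluster_cond):
        from dataclasses import replace

        doubled = replace(cluster_cond, c0_nM=cluster_cond.c0_nM * 2)
        r = np.array([0.0, 10.0, 100.0, 400.0])
        np.testing.assert_allclose(
            steady_state_concentration(r, doubled),
            2.0 * steady_state_concentration(r, cluster_cond),
        )

    def test_monotone_nonincreasing_in_r(self, cluster_cond):
        r = np.linspace(0, 600, 200)
        c = steady_state_concentration(r, cluster_cond)
        assert np.all(np.diff(c) <= 1e-12)

    def test_negative_r_rejected(self, cluster_cond):
        with pytest.raises(ValueError):
            steady_state_concentration(-1.0, cluster_cond)
        with pytest.raises(ValueError):
            steady_state_concentration(np.nan, cluster_cond)

    def test_matches_finite_difference_oracle(self, cluster_cond):
        """Steady profile vs an independent finite-volume radial solve."""
        oracle = oracle_for_conditions(cluster_cond, r_max_um=40000.0, dr_um=2.0)
        profile = oracle.steady_state()
        r = np.array([5.0, 20.0, 50.0, 100.0, 300.0, 500.0])
        r_eff = np.hypot(r, cluster_cond.height_um)
        numeric = oracle.at(profile, r_eff)
        analytic = steady_state_concentration(r, cluster_cond)
        np.testing.assert_allclose(numeric, analytic, rtol=0.02)

    def test_mass_rate_consistency(self, cluster_cond):
        """Diffusive flux through a hemisphere around the source = flow * c0."""
        R_um = 200.0
        eps = 1e-3
        # spherical symmetry around the source: evaluate C along the 3-D radius
        def c_of_rho(rho_um):
            r_inplane = np.sqrt(np.maximum(rho_um**2 - cluster_cond.height_um**2, 0.0))
            return steady_state_concentration(r_inplane, cluster_cond)

        grad = (c_of_rho(R_um + eps) - c_of_rho(R_um - eps)) / (2 * eps * 1e-6)  # nM/m
        flux = -2.0 * np.pi * (R_um * 1e-6) ** 2 * cluster_cond.diffusivity_m2_per_s * grad
        assert flux == pytest.approx(cluster_cond.flow_m3_per_s * cluster_cond.c0_nM, rel=0.01)


class TestTransient:
    def test_zero_before_dispensing(self, cluster_cond):
        r = np.array([1.0, 10.0, 100.0])
        np.testing.assert_array_equal(transient_concentration(r, 0.0, cluster_cond), 0.0)

    def test_long_time_limit_reaches_steady_state(self, cluster_cond):
        r = 30.0
        r_eff_m = cluster_cond.r_eff_um(r) * 1e-6
        # erfc(x) -> 1 deviation is 2x/sqrt(pi); x = 5e-4 here, well under 0.1%
        t = 1e6 * r_eff_m**2 / cluster_cond.diffusivity_m2_per_s
        from dataclasses import replace

        cond = replace(cluster_cond, duration_s=2 * t)
        assert transient_concentration(r, t, cond) == pytest.approx(
            steady_state_concentration(r, cond), rel=1e-3
        )

    def test_negative_time_rejected(self, cluster_cond):
        with pytest.raises(ValueError):
            transient_concentration(10.0, -1.0, cluster_cond)

    def test_monotone_buildup_during_dispensing(self, cluster_cond):
        t = np.linspace(0.0, cluster_cond.duration_s, 50)
        for r in (0.0, 25.0, 100.0, 300.0):
            c = transient_concentration(np.full_like(t, r), t, cluster_cond)
            assert np.all(np.diff(c) >= -1e-12)

    def test_buildup_matches_finite_difference_oracle(self, cluster_cond):
        oracle = oracle_for_conditions(cluster_cond, r_max_um=1500.0, dr_um=2.0)
        profile = oracle.transient(t_on=1e9, t_total=30.0)
        r = np.array([5.0, 20.0, 50.0, 100.0, 300.0])
        numeric = oracle.at(profile, np.hypot(r, cluster_cond.height_um))
        analytic = transient_concentration(r, 30.0, cluster_cond)
        np.testing.assert_allclose(numeric, analytic, rtol=0.05)

    def test_decay_matches_finite_difference_oracle(self):
        """Post-dispense superposition decay vs switched-off numeric solve."""
        cond = DispenseConditions(c0_nM=318.0, mode="cluster", duration_s=60.0)
        oracle = oracle_for_conditions(cond, r_max_um=1500.0, dr_um=2.0)
        profile = oracle.transient(t_on=60.0, t_total=180.0)
        numeric = oracle.at(profile, np.hypot(50.0, cond.height_um))
        analytic = transient_concentration(50.0, 180.0, cond)
        assert numeric == pytest.approx(analytic, rel=0.05)

    def test_agonist_decays_within_minutes_after_dispensing(self, cluster_cond):
        """Five minutes after the probe stops, the field has collapsed."""
        for r in (0.0, 50.0, 100.0):
            c_after = transient_concentration(r, cluster_cond.duration_s + 300.0, cluster_cond)
            assert c_after < 0.10 * steady_state_concentration(r, cluster_cond)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        r=st.floats(0.0, 500.0),
        t=st.floats(0.0, 900.0),
        k=st.floats(0.1, 10.0),
    )
    def test_linearity_and_bounds_property(self, r, t, k):
        """C is linear in c0, non-negative, and never exceeds steady state."""
        from dataclasses import replace

        cond = DispenseConditions(c0_nM=318.0, mode="cluster", duration_s=300.0)
        c = transient_concentration(r, t, cond)
        assert c >= 0.0
        assert c <= steady_state_concentration(r, cond) * (1 + 1e-9)
        scaled = transient_concentration(r, t, replace(cond, c0_nM=cond.c0_nM * k))
        assert scaled == pytest.approx(k * c, rel=1e-9, abs=1e-12)


class TestConcentrationAtCells:
    def test_empty_cell_list(self, cluster_cond):
        cells = pd.DataFrame({"x_um": [], "y_um": []})
        out = concentration_at_cells(cells, cluster_cond, 300.0)
        assert len(out) == 0 and "conc_nM" in out.columns

    def test_cell_at_dispensing_point_sees_cmax(self, cluster_cond):
        cells = pd.DataFrame({"x_um": [0.0], "y_um": [0.0]})
        from dataclasses import replace

        cond = replace(cluster_cond, duration_s=1e7)
        out = concentration_at_cells(cells, cond, 1e7)
        assert out["conc_nM"].iloc[0] == pytest.approx(100.0, rel=0.01)

    def test_ring_of_cells_equal_concentration(self, cluster_cond):
        theta = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        cells = pd.DataFrame({"x_um": 80 * np.cos(theta), "y_um": 80 * np.sin(theta)})
        out = concentration_at_cells(cells, cluster_cond, 100.0)
        np.testing.assert_allclose(out["conc_nM"], out["conc_nM"].iloc[0])

    def test_missing_positions_rejected(self, cluster_cond):
        cells = pd.DataFrame({"x_um": [1.0, np.nan], "y_um": [0.0, 1.0]})
        with pytest.raises(ValueError):
            concentration_at_cells(cells, cluster_cond, 10.0)


class TestCmaxUncertainty:
    def test_degenerate_interval(self, single_cell_cond):
        lo, hi = cmax_uncertainty(single_cell_cond, (4.0, 4.0))
        assert lo == hi == pytest.approx(single_cell_cond.cmax_nM)

    def test_single_cell_height_ambiguity_is_about_half_cmax(self, single_cell_cond):
        """Cell-height ambiguity of 4-8 um maps to ~50% uncertainty in C_max."""
        assert relative_cmax_uncertainty(single_cell_cond, (4.0, 8.0)) == pytest.approx(0.5, abs=0.02)

    def test_widening_never_shrinks(self, single_cell_cond):
        lo1, hi1 = cmax_uncertainty(single_cell_cond, (4.0, 6.0))
        lo2, hi2 = cmax_uncertainty(single_cell_cond, (3.0, 8.0))
        assert lo2 <= lo1 and hi2 >= hi1

    def test_empty_interval_rejected(self, single_cell_cond):
        with pytest.raises(ValueError):
            cmax_uncertainty(single_cell_cond, (8.0, 4.0))


def test_field_table_long_format(cluster_cond):
    table = field_table(cluster_cond, r_um=[0, 50, 100], t_s=[10, 300])
    assert list(table.columns) == ["r_um", "t_s", "conc_nM"]
    assert len(table) == 6
    assert (table["conc_nM"] >= 0).all()


def test_field_at_points_radial_symmetry(cluster_cond):
    field = ConcentrationField(cluster_cond, origin_um=(500.0, 500.0))
    a = field.at_points(550.0, 500.0, 100.0)
    b = field.at_points(500.0, 450.0, 100.0)
    assert a == pytest.approx(b)
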