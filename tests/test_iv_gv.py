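"""Reversal estimation, conductance conversion, normalization, diff-at-0."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import channeliphys as cp
from channeliphys.series import TO_ANCHOR_VOLTAGE, TO_MAX

from conftest import random_ghk_condition


def linear_iv(erev=10.0, slope=2.0, volts=None):
    v = np.arange(-100.0, 101.0, 10.0) if volts is None else np.asarray(volts)
    return cp.IVSeries(v, slope * (v - erev))


class TestEstimateReversal:
    def test_linear_iv_recovers_intercept(self):
        est = cp.estimate_reversal(linear_iv(erev=10.0))
        assert est.erev == pytest.approx(10.0, abs=1e-9)
        assert est.polynomial_degree == 9

    def test_symmetric_na_reversal_near_zero(self, symmetric_na, voltage_grid):
        iv = cp.gen_iv_ghk(symmetric_na, voltage_grid)
        assert cp.estimate_reversal(iv).erev == pytest.approx(0.0, abs=0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bisection_oracle_on_ghk(self, seed):
        rng = np.random.default_rng(1000 + seed)
        cond = random_ghk_condition(rng)
        if cp.ghk_current(cond, -100.0) * cp.ghk_current(cond, 100.0) >= 0:
            pytest.skip("no crossing in range")
        iv = cp.gen_iv_ghk(cond, np.arange(-100.0, 101.0, 10.0))
        oracle = brentq(lambda v: cp.ghk_current(cond, v), -100.0, 100.0)
        assert abs(cp.estimate_reversal(iv).erev - oracle) <= 0.1

    def test_no_sign_change_raises(self):
        v = np.arange(-100.0, 101.0, 10.0)
        iv = cp.IVSeries(v, np.full_like(v, -50.0) - v**2 / 100)  # strongly rectifying, all negative
        with pytest.raises(ValueError, match="no reversal in range"):
            cp.estimate_reversal(iv)

    def test_degree_reduced_for_short_series(self):
        est = cp.estimate_reversal(linear_iv(volts=np.arange(-40.0, 41.0, 10.0)))
        assert est.degree_reduced and est.polynomial_degree == 7
        assert est.erev == pytest.approx(10.0, abs=1e-8)

    def test_window_restricts_fit(self):
        est = cp.estimate_reversal(linear_iv(erev=10.0), window=(-50.0, 60.0))
        assert est.window == (-50.0, 60.0)
        assert est.erev == pytest.approx(10.0, abs=1e-8)

    @given(
        scale=st.floats(0.1, 100.0),
        shift=st.floats(-20.0, 20.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_scaling_invariance_and_translation_equivariance(self, scale, shift):
        """erev is invariant under current scaling, equivariant under V shift."""
        v = np.arange(-100.0, 101.0, 10.0)
        base = cp.gen_iv_ghk(
            cp.GHKCondition(ions=(cp.Ion("Na", 1, 150.0, 100.0, 1.0),)), v
        )
        # tolerance reflects eigenvalue root-finding jitter, far below the
        # 0.1 mV physical agreement the estimator is held to elsewhere
        e0 = cp.estimate_reversal(base).erev
        scaled = cp.IVSeries(v, base.currents * scale)
        assert cp.estimate_reversal(scaled).erev == pytest.approx(e0, abs=1e-3)
        shifted = cp.IVSeries(v + shift, base.currents)
        assert cp.estimate_reversal(shifted).erev == pytest.approx(e0 + shift, abs=1e-3)


class TestComputeConductance:
    def test_single_point_value(self):
        v = np.array([-100.0, -50.0, 50.0, 100.0])
        iv = cp.IVSeries(v, np.array([-500.0, -250.0, 250.0, 500.0]))
        gv = cp.compute_conductance(iv, erev=0.0)
        assert gv.conductance[0] == pytest.approx(5.0)  # -500 pA / -100 mV = 5 nS

    def test_ohmic_iv_gives_constant_conductance(self):
        gv = cp.compute_conductance(linear_iv(erev=10.0, slope=2.0), erev=10.0)
        np.testing.assert_allclose(gv.retained_conductance, 2.0)

    def test_exclusion_band_flags_not_drops(self):
        gv = cp.compute_conductance(linear_iv(erev=0.0), erev=0.0, exclusion_halfwidth=2.5)
        assert len(gv) == 21 and gv.excluded.sum() == 1
        assert bool(gv.excluded[10])  # the 0 mV point

    def test_all_excluded_raises(self):
        iv = linear_iv(erev=0.0)
        with pytest.raises(ValueError, match="exclusion band"):
            cp.compute_conductance(iv, erev=0.0, exclusion_halfwidth=500.0)

    def test_blocker_round_trip_to_machine_precision(self, wildtype_truth, voltage_grid):
        gv_true, iv = cp.gen_gv_blocker(wildtype_truth, voltage_grid)
        gv = cp.compute_conductance(iv, wildtype_truth.vrev)
        keep = ~gv.excluded
        np.testing.assert_allclose(gv.conductance[keep], gv_true.conductance[keep], rtol=1e-14)

    def test_multiplying_back_reconstructs_currents(self, wildtype_truth, voltage_grid):
        _, iv = cp.gen_gv_blocker(wildtype_truth, voltage_grid, cp.NoiseModel(0.05, 11))
        gv = cp.compute_conductance(iv, wildtype_truth.vrev)
        keep = ~gv.excluded
        recon = gv.conductance[keep] * (gv.voltages[keep] - wildtype_truth.vrev)
        np.testing.assert_allclose(recon, iv.currents[keep], rtol=1e-14)


class TestNormalizeGV:
    def test_to_max_gives_unit_maximum(self, wildtype_truth, voltage_grid):
        gv, _ = cp.gen_gv_blocker(wildtype_truth, voltage_grid)
        normed = cp.normalize_gv(gv, TO_MAX)
        assert np.nanmax(normed.conductance) == pytest.approx(1.0)
        assert normed.reference_value is not None

    def test_constant_series_anchor_gives_ones(self):
        v = np.arange(-100.0, 101.0, 10.0)
        gv = cp.GVSeries(v, np.full_like(v, 3.0))
        normed = cp.normalize_gv(gv, TO_ANCHOR_VOLTAGE, anchor=-100.0)
        np.testing.assert_allclose(normed.conductance, 1.0)

    def test_u_shape_minimum_location_preserved(self, wildtype_truth, voltage_grid):
        fine = np.arange(-100.0, 100.5, 0.5)
        argmin_true = fine[np.argmin(wildtype_truth.conductance(fine))]
        gv, _ = cp.gen_gv_blocker(wildtype_truth, fine)
        normed = cp.normalize_gv(gv, TO_MAX)
        argmin_norm = fine[np.argmin(normed.conductance)]
        assert argmin_norm == pytest.approx(argmin_true, abs=0.5)

    def test_zero_reference_raises(self):
        v = np.arange(-20.0, 21.0, 10.0)
        gv = cp.GVSeries(v, np.array([1.0, 1.0, 0.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="zero"):
            cp.normalize_gv(gv, TO_ANCHOR_VOLTAGE, anchor=0.0)


class TestConductanceDifferenceAtZero:
    def _normalized(self, truth, volts):
        gv, _ = cp.gen_gv_blocker(truth, volts)
        return cp.normalize_gv(gv, TO_MAX)

    def test_identical_series_zero_difference(self, wildtype_truth, voltage_grid):
        a = self._normalized(wildtype_truth, voltage_grid)
        assert cp.conductance_difference_at_zero(a, a) == pytest.approx(0.0)

    def test_constructed_thirty_point_drop(self, voltage_grid):
        ref = cp.GVSeries(voltage_grid, np.ones_like(voltage_grid), normalization=TO_MAX)
        var = cp.GVSeries(voltage_grid, np.full_like(voltage_grid, 0.7), normalization=TO_MAX)
        assert cp.conductance_difference_at_zero(var, ref) == pytest.approx(-30.0)

    def test_more_block_gives_negative_difference(self, wildtype_truth, voltage_grid):
        # a higher-affinity (lower Kd) variant blocks more at 0 mV
        variant_truth = cp.BlockerTruth(gmax=1.0, g=5.0, h=-18.5, L=0.7, k=36.5, spm=30.0)
        diff = cp.conductance_difference_at_zero(
            self._normalized(variant_truth, voltage_grid),
            self._normalized(wildtype_truth, voltage_grid),
        )
        assert diff < 0

    def test_incompatible_normalizations_raise(self, wildtype_truth, voltage_grid):
        gv, _ = cp.gen_gv_blocker(wildtype_truth, voltage_grid)
        a = cp.normalize_gv(gv, TO_MAX)
        b = cp.normalize_gv(gv, TO_ANCHOR_VOLTAGE, anchor=-100.0)
        with pytest.raises(ValueError, match="incompatible|normalized"):
            cp.conductance_difference_at_zero(a, b)

    def test_unnormalized_inputs_rejected(self, wildtype_truth, voltage_grid):
        gv, _ = cp.gen_gv_blocker(wildtype_truth, voltage_grid)
        with pytest.raises(ValueError):
            cp.conductance_difference_at_zero(gv, gv)
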