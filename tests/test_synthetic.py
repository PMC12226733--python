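"""Generators: closed-form agreement, determinism, and input validation."""

import numpy as np
import pytest
from scipy.optimize import brentq

import channeliphys as cp
from channeliphys.reference import glua2_reference

from conftest import random_ghk_condition


class TestGHKGenerator:
    def test_symmetric_na_crosses_zero_at_zero(self, symmetric_na, voltage_grid):
        iv = cp.gen_iv_ghk(symmetric_na, voltage_grid)
        assert cp.ghk_current(symmetric_na, 0.0) == pytest.approx(0.0, abs=1e-12)
        # current is negative below 0 and positive above
        assert iv.currents[voltage_grid < 0].max() < 0 < iv.currents[voltage_grid > 0].min()

    def test_equal_permeability_biionic_crosses_zero(self, voltage_grid):
        cond = cp.GHKCondition(
            ions=(cp.Ion("Na", 1, 150.0, 0.0, 1.0), cp.Ion("K", 1, 0.0, 150.0, 1.0))
        )
        assert cp.ghk_current(cond, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_divalent_crossing_matches_bisection_oracle(self):
        # 100 K in / 4 Ca out with pCa/pK = 0.67
        cond = cp.GHKCondition(
            ions=(cp.Ion("K", 1, 100.0, 0.0, 1.0), cp.Ion("Ca", 2, 0.0, 4.0, 0.67))
        )
        oracle = brentq(lambda v: cp.ghk_current(cond, v), -100.0, 100.0)
        volts = np.arange(-100.0, 101.0, 1.0)
        iv = cp.gen_iv_ghk(cond, volts)
        sign_change = volts[np.where(np.diff(np.sign(iv.currents)))[0][0]]
        assert abs(sign_change - oracle) <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_crossing_matches_oracle_random_conditions(self, seed):
        rng = np.random.default_rng(seed)
        cond = random_ghk_condition(rng)
        i_lo, i_hi = cp.ghk_current(cond, -100.0), cp.ghk_current(cond, 100.0)
        if i_lo * i_hi >= 0:
            pytest.skip("no crossing in range for this draw")
        oracle = brentq(lambda v: cp.ghk_current(cond, v), -100.0, 100.0)
        iv = cp.gen_iv_ghk(cond, np.arange(-100.0, 101.0, 10.0))
        est = cp.estimate_reversal(iv)
        assert abs(est.erev - oracle) <= 0.1

    def test_empty_ion_set_rejected(self):
        with pytest.raises(ValueError):
            cp.GHKCondition(ions=())

    def test_needs_permeant_ion_on_each_side(self):
        with pytest.raises(ValueError, match="internal|external"):
            cp.GHKCondition(ions=(cp.Ion("Na", 1, 150.0, 0.0, 1.0),))


class TestBlockerGenerator:
    def test_no_blocker_gives_gmax_everywhere(self, voltage_grid):
        truth = cp.BlockerTruth(gmax=2.5, spm=0.0)
        gv, _ = cp.gen_gv_blocker(truth, voltage_grid)
        np.testing.assert_allclose(gv.conductance, 2.5)

    def test_half_block_when_spm_equals_kd0(self):
        truth = cp.BlockerTruth(gmax=1.0, g=10.0, L=1.4, spm=11.4)
        gv, _ = cp.gen_gv_blocker(truth, [0.0, 10.0, 20.0, 30.0])
        assert gv.conductance[0] == pytest.approx(0.5)

    def test_wildtype_truth_is_u_shaped_with_relief(self, wildtype_truth, voltage_grid):
        gv, _ = cp.gen_gv_blocker(wildtype_truth, voltage_grid)
        i_min = int(np.argmin(gv.conductance))
        assert 0 < i_min < len(voltage_grid) - 1  # interior minimum
        assert gv.conductance[-1] > gv.conductance[i_min]  # relief at depolarized V

    def test_iv_counterpart_uses_driving_force(self, wildtype_truth, voltage_grid):
        gv, iv = cp.gen_gv_blocker(wildtype_truth, voltage_grid)
        np.testing.assert_allclose(iv.currents, gv.conductance * (voltage_grid - wildtype_truth.vrev))

    def test_negative_spm_rejected(self):
        with pytest.raises(ValueError):
            cp.BlockerTruth(spm=-1.0)

    def test_sign_convention_enforced(self):
        with pytest.raises(ValueError):
            cp.BlockerTruth(h=18.5)
        with pytest.raises(ValueError):
            cp.BlockerTruth(k=-36.5)


class TestDoseAndRecoveryGenerators:
    def test_half_response_at_ec50(self):
        df = cp.gen_dose_response(0.11, 1.5, [0.11, 1.0, 2.0, 3.0])
        assert df["response"].iloc[0] == pytest.approx(0.5)

    def test_saturation_limit(self):
        df = cp.gen_dose_response(0.11, 1.5, [1e9, 2e9, 3e9, 4e9])
        np.testing.assert_allclose(df["response"], 1.0, atol=1e-6)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            cp.gen_dose_response(0.11, 1.5, [0.0, 1.0, 2.0, 3.0])

    def test_recovery_closed_form(self):
        df = cp.gen_recovery(184.0, [0.0, 184.0, 1e9], amplitude=-1.0)
        assert df["ratio"].iloc[0] == pytest.approx(0.0)  # fully desensitized
        assert df["ratio"].iloc[1] == pytest.approx(1.0 - np.exp(-1.0))
        assert df["ratio"].iloc[2] == pytest.approx(1.0)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            cp.gen_recovery(0.0, [1.0, 2.0])


class TestDeterminismAndNoise:
    def test_same_seed_bit_identical(self, wildtype_truth, voltage_grid):
        noise = cp.NoiseModel(additive_sd=0.05, seed=7)
        a, _ = cp.gen_gv_blocker(wildtype_truth, voltage_grid, noise)
        b, _ = cp.gen_gv_blocker(wildtype_truth, voltage_grid, noise)
        assert np.array_equal(a.conductance, b.conductance)

    def test_different_seed_differs(self, wildtype_truth, voltage_grid):
        a, _ = cp.gen_gv_blocker(wildtype_truth, voltage_grid, cp.NoiseModel(0.05, 1))
        b, _ = cp.gen_gv_blocker(wildtype_truth, voltage_grid, cp.NoiseModel(0.05, 2))
        assert not np.array_equal(a.conductance, b.conductance)

    def test_noise_free_matches_closed_form_exactly(self, wildtype_truth, voltage_grid):
        gv, _ = cp.gen_gv_blocker(wildtype_truth, voltage_grid)
        np.testing.assert_array_equal(gv.conductance, wildtype_truth.conductance(voltage_grid))

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            cp.NoiseModel(additive_sd=-0.1)


class TestAlignmentFixture:
    def test_round_trip_planted_residues(self):
        records, _ = cp.gen_alignment_fixture({653: "S", 655: "I", 732: "F"}, seed=3)
        q = str(records[1].seq)
        profile = cp.extract_sites(cp.map_to_reference(q), q)
        assert (profile.sidechain[653], profile.sidechain[655], profile.sidechain[732]) == (
            "S", "I", "F",
        )

    def test_position_outside_reference_rejected(self):
        with pytest.raises(ValueError, match="outside reference"):
            cp.gen_alignment_fixture({9999: "A"})

    def test_reference_record_is_bundled_sequence(self):
        records, _ = cp.gen_alignment_fixture({})
        assert str(records[0].seq) == glua2_reference()
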