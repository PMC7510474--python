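"""Unit and property tests of the clearance-network ODE module."""

import numpy as np
import pytest

from mitonadph.errors import ConfigurationError, PreconditionError
from mitonadph.redox_network import (
    SPECIES,
    Condition,
    Geometry,
    KineticParameters,
    RedoxState,
    Trajectory,
    calibrated_surface_to_volume,
    daao_rate_table,
    fit_michaelis_menten,
    fluxes_at,
    rhs,
    simulate,
    stress_flux,
)
from mitonadph.synthetic_data import generate_mm_assay


def bare_params(**overrides):
    """Parameters with every reaction disabled unless overridden."""
    fields = KineticParameters().rate_constant_names()
    zeros = {name: 0.0 for name in fields}
    zeros.update(overrides)
    return KineticParameters(**zeros)


class TestRhs:
    def test_no_substrate_no_daao_flux(self, params, geometry, basal_state):
        state = RedoxState.from_array(basal_state.to_array())
        state.dala_mito = 0.0
        deriv = rhs(state, params, geometry, dala_ext_mm=0.0)
        assert fluxes_at(state, params)["v_daao"] == 0.0
        assert deriv.dala_mito == 0.0

    def test_single_mass_action_term(self, geometry):
        # only Prx oxidation active: d(prx_soh)/dt = k * h2o2 * prx_sh
        p = bare_params(k_prx_ox=1.0)
        state = RedoxState(h2o2=0.01, prx_sh=100.0)
        deriv = rhs(state, p, geometry, 0.0)
        assert deriv.prx_soh == pytest.approx(1.0, rel=1e-12)
        assert deriv.prx_sh == pytest.approx(-1.0, rel=1e-12)
        assert deriv.h2o2 == pytest.approx(-1.0, rel=1e-12)

    def test_zero_at_basal_steady_state(self, params, geometry, basal_state):
        deriv = rhs(basal_state, params, geometry, 0.0).to_array()
        assert np.max(np.abs(deriv)) < 1e-6

    def test_moiety_derivative_sums(self, params, geometry, basal_state):
        """Prx and Trx moiety derivatives vanish; the NADP moiety derivative
        equals exactly the stress flux."""
        state = RedoxState.from_array(basal_state.to_array())
        state.dala_mito = 500.0  # active stress flux
        d = rhs(state, params, geometry, 50.0)
        assert abs(d.prx_sh + d.prx_soh + d.prx_ss + d.prx_so2h) < 1e-12
        assert abs(d.trx_sh + d.trx_ss) < 1e-12
        v_alpha = fluxes_at(state, params)["v_alpha"]
        assert v_alpha > 0
        assert d.nadph + d.nadp == pytest.approx(v_alpha, rel=1e-12)

    def test_negative_concentration_rejected(self, params, geometry):
        state = RedoxState(h2o2=-1.0)
        with pytest.raises(PreconditionError):
            rhs(state, params, geometry, 0.0)

    def test_unknown_rate_constant_rejected(self):
        with pytest.raises(ConfigurationError, match="k_made_up"):
            KineticParameters.from_dict({"k_made_up": 1.0})


class TestStressFlux:
    def test_gate_closed_at_basal(self, params):
        assert stress_flux(params.v_basal_h2o2, params) == 0.0

    def test_literal_mode_product(self):
        p = KineticParameters(alpha=80.9, s_cal=1.0, stress_mode="literal")
        assert stress_flux(4.05, p) == pytest.approx(327.645, rel=1e-12)

    def test_zero_alpha(self):
        p = KineticParameters(alpha=0.0, stress_mode="literal", s_cal=1.0)
        assert stress_flux(100.0, p) == 0.0

    def test_unknown_mode_rejected(self, params):
        with pytest.raises(ConfigurationError):
            stress_flux(1.0, params, mode="bogus")
        with pytest.raises(ConfigurationError):
            KineticParameters(stress_mode="bogus")


class TestSimulate:
    def test_steady_state_persists(self, params, geometry, basal_state):
        traj = simulate(basal_state, params, geometry, Condition(dala_ext_mm=0.0))
        nadph = traj.species("nadph")
        assert np.all(np.abs(nadph / nadph[0] - 1) < 1e-3)

    def test_first_state_is_initial(self, params, geometry, basal_state):
        traj = simulate(basal_state, params, geometry, Condition(dala_ext_mm=15.0))
        np.testing.assert_allclose(traj.states[0], basal_state.to_array(), rtol=1e-9)

    @pytest.mark.parametrize("dose", [0.0, 15.0, 50.0])
    def test_moiety_conservation(self, params, geometry, basal_state, dose):
        traj = simulate(basal_state, params, geometry, Condition(dala_ext_mm=dose))
        prx = (
            traj.species("prx_sh") + traj.species("prx_soh")
            + traj.species("prx_ss") + traj.species("prx_so2h")
        )
        trx = traj.species("trx_sh") + traj.species("trx_ss")
        assert np.max(np.abs(prx / prx[0] - 1)) < 1e-6
        assert np.max(np.abs(trx / trx[0] - 1)) < 1e-6

    def test_nadp_moiety_conserved_without_stress_flux(self, geometry, basal_state, totals, params):
        from dataclasses import replace

        p = replace(params, stress_mode="off")
        traj = simulate(basal_state, p, geometry, Condition(dala_ext_mm=50.0))
        pool = traj.species("nadph") + traj.species("nadp")
        assert np.max(np.abs(pool / pool[0] - 1)) < 1e-6

    @pytest.mark.parametrize("dose", [0.0, 15.0, 50.0])
    def test_non_negative_species(self, params, geometry, basal_state, dose):
        traj = simulate(basal_state, params, geometry, Condition(dala_ext_mm=dose))
        assert traj.states.min() > -1e-9

    def test_monotone_dose_response(self, params, geometry, basal_state):
        """NADPH falls and H2O2 rises monotonically with dose at t = 60 min."""
        nadph, h2o2 = [], []
        for dose in [0, 1, 5, 10, 15, 25, 50]:
            traj = simulate(basal_state, params, geometry, Condition(dala_ext_mm=dose))
            end = traj.state_at(60.0)
            nadph.append(end.nadph)
            h2o2.append(end.h2o2)
        assert np.all(np.diff(nadph) <= 1e-9)
        assert np.all(np.diff(h2o2) >= -1e-12)

    def test_quasi_steady_dala(self, params, geometry, basal_state):
        traj = simulate(basal_state, params, geometry, Condition(dala_ext_mm=15.0))
        table = daao_rate_table(params, geometry, [15.0])
        assert traj.species("dala_mito")[-1] == pytest.approx(
            table["dala_mito_um"].iloc[0], rel=1e-2
        )

    def test_trajectory_times_strictly_increasing(self):
        with pytest.raises(ValueError):
            Trajectory(times_min=[0, 0], states=np.zeros((2, 15)), fluxes=np.zeros((2, 4)))


class TestSingleReactionOracles:
    """Integrated single reactions must match their closed-form solutions."""

    def test_first_order_decay(self, geometry):
        # only condensation active: prx_soh(t) = prx_soh(0) * exp(-k t)
        k = 0.5
        p = bare_params(k_prx_cond=k)
        state = RedoxState(prx_soh=10.0)
        times = np.array([0.0, 0.05, 0.1])  # minutes
        traj = simulate(state, p, geometry, Condition(dala_ext_mm=0.0), times_min=times)
        expected = 10.0 * np.exp(-k * times * 60.0)
        np.testing.assert_allclose(traj.species("prx_soh"), expected, rtol=1e-6)

    def test_bimolecular_reaction(self, geometry):
        # only Prx oxidation: A + B -> with A = h2o2, B = prx_sh, A0 != B0:
        # A(t) = A0 (B0 - A0) / (B0 exp((B0-A0) k t) - A0)
        k, a0, b0 = 0.02, 5.0, 40.0
        p = bare_params(k_prx_ox=k)
        state = RedoxState(h2o2=a0, prx_sh=b0)
        times = np.array([0.0, 0.02, 0.05])
        traj = simulate(state, p, geometry, Condition(dala_ext_mm=0.0), times_min=times)
        ts = times * 60.0
        expected_a = a0 * (b0 - a0) / (b0 * np.exp((b0 - a0) * k * ts) - a0)
        np.testing.assert_allclose(traj.species("h2o2"), expected_a, rtol=1e-6)

    def test_permeation_relaxation(self, geometry):
        # only permeation: dala(t) relaxes exponentially to dala_ext
        p = bare_params(p_dala=6.92e-10)
        k_perm = geometry.k_perm(p.p_dala)
        state = RedoxState()
        times = np.array([0.0, 5.0, 20.0])
        traj = simulate(state, p, geometry, Condition(dala_ext_mm=10.0), times_min=times)
        expected = 1e4 * (1 - np.exp(-k_perm * times * 60.0))
        np.testing.assert_allclose(traj.species("dala_mito"), expected, rtol=1e-6)


class TestDaaoRateTable:
    def test_zero_dose(self, params, geometry):
        row = daao_rate_table(params, geometry, [0.0]).iloc[0]
        assert row["v_daao"] == 0.0
        assert row["v_h2o2_total"] == params.v_basal_h2o2

    def test_reference_flux_at_50_mm(self, params, geometry):
        # the geometric constant is calibrated so this flux is 70.7 uM/s
        row = daao_rate_table(params, geometry, [50.0]).iloc[0]
        assert row["v_daao"] == pytest.approx(70.7, rel=1e-3)

    def test_linearity(self, params, geometry):
        table = daao_rate_table(params, geometry, [1.0, 50.0])
        assert table["v_daao"].iloc[1] == pytest.approx(
            50.0 * table["v_daao"].iloc[0], rel=1e-12
        )

    def test_surface_to_volume_derivation(self, geometry):
        assert calibrated_surface_to_volume() == pytest.approx(
            geometry.surface_to_volume_cm, rel=1e-3
        )


class TestMichaelisMenten:
    def test_noise_free_recovery(self):
        vmax, km = 2.0e-4, 10.4
        s = np.array([0.5, 1, 2, 5, 10, 20, 40])
        v = vmax * s / (km + s)
        vh, kh, resid = fit_michaelis_menten(s, v)
        assert vh == pytest.approx(vmax, rel=1e-6)
        assert kh == pytest.approx(km, rel=1e-6)
        assert resid < 1e-10

    def test_all_zero_rates_flagged(self):
        vh, kh, _ = fit_michaelis_menten([1, 2, 4], [0, 0, 0])
        assert vh == 0.0
        assert np.isnan(kh)

    def test_noisy_recovery_within_15_percent(self):
        table = generate_mm_assay(noise_frac=0.05, n_reps=3, seed=11)
        vh, kh, _ = fit_michaelis_menten(table["substrate_mM"], table["rate"])
        assert vh == pytest.approx(2.0e-4, rel=0.15)
        assert kh == pytest.approx(10.4, rel=0.15)

    def test_degenerate_substrate_rejected(self):
        with pytest.raises(PreconditionError):
            fit_michaelis_menten([5.0, 5.0, 5.0], [1.0, 1.0, 1.0])


class TestStateContainer:
    def test_array_roundtrip(self, basal_state):
        arr = basal_state.to_array()
        again = RedoxState.from_array(arr).to_array()
        np.testing.assert_array_equal(arr, again)
        assert len(SPECIES) == arr.size
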