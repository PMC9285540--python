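"""Flux equations, constraint diagnostics, and mass-balance structure."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tundracn.model_core import (
    DegenerateStateError,
    DriverError,
    DriverState,
    EcosystemState,
    ParameterSet,
    allometric_constraint,
    compute_fluxes,
    state_derivatives,
    stoichiometric_ratios,
)

P0 = ParameterSet()


class TestAllometricConstraint:
    @pytest.mark.parametrize(
        "bc, expected, tol",
        [
            (878.0, 243.75, 5e-3),          # reference calibration value
            (0.0, 0.0, 0.0),                # zero biomass, zero surface
            (100.0, 100 * 1.2231 / 2.1, 1e-9),  # hand evaluation
        ],
    )
    def test_reference_values(self, bc, expected, tol):
        assert allometric_constraint(bc, P0) == pytest.approx(expected, abs=tol)

    def test_saturates_toward_alpha_over_gamma_slope(self):
        # for large BC, S/BC -> alpha/gamma
        big = 1e9
        assert allometric_constraint(big, P0) / big == pytest.approx(
            P0.alpha / P0.gamma, rel=1e-5
        )

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            allometric_constraint(-1.0, P0)


class TestStoichiometricRatios:
    def test_unity_at_reference_state(self):
        psi, phi = stoichiometric_ratios(EcosystemState(), P0)
        assert psi == pytest.approx(1.0, abs=1e-3)
        assert phi == pytest.approx(1.0, abs=1e-3)

    def test_psi_linear_in_plant_carbon(self):
        s1 = EcosystemState()
        s2 = EcosystemState(BC=2 * s1.BC, BN=s1.BN, DC=s1.DC, DN=s1.DN, N=s1.N)
        psi1, _ = stoichiometric_ratios(s1, P0)
        psi2, _ = stoichiometric_ratios(s2, P0)
        assert psi2 == pytest.approx(2 * psi1)

    def test_zero_nitrogen_pool_is_degenerate(self):
        with pytest.raises(DegenerateStateError):
            stoichiometric_ratios(
                EcosystemState(BC=878, BN=0.0, DC=19452, DN=831, N=0.27), P0
            )


class TestVoleFluxes:
    def test_forty_voles_at_calibration_temperature(self):
        f = compute_fluxes(EcosystemState(), DriverState(V=40.0), P0)
        assert f.GC == pytest.approx(14.136, abs=1e-9)
        assert f.GN == pytest.approx(0.7382, abs=1e-4)
        assert f.RV == pytest.approx(4.2144, abs=1e-9)
        assert f.VUN == pytest.approx(0.044, abs=1e-12)
        assert f.LVC == pytest.approx(9.9216, abs=1e-9)
        assert f.LVN == pytest.approx(0.6942, abs=1e-4)

    def test_no_voles_no_vole_fluxes(self):
        f = compute_fluxes(EcosystemState(), DriverState(V=0.0), P0)
        assert f.GC == f.GN == f.RV == f.VUN == f.LVC == f.LVN == 0.0

    def test_warming_reduces_per_capita_offtake(self):
        # 5 degC of warming at 100 voles/ha: (22 + 3512 - 52*5)*100/1e4
        f = compute_fluxes(EcosystemState(), DriverState(T=15.0, V=100.0), P0)
        assert f.GC == pytest.approx(32.74, abs=1e-9)

    def test_vole_offtake_floors_at_zero_under_extreme_warming(self):
        f = compute_fluxes(EcosystemState(), DriverState(T=90.0, V=100.0), P0)
        assert f.GC == 0.0
        assert f.RV == 0.0

    def test_invalid_drivers_rejected(self):
        with pytest.raises(DriverError):
            DriverState(V=-1.0)
        with pytest.raises(DriverError):
            DriverState(Ca=0.0)


state_strategy = st.builds(
    EcosystemState,
    BC=st.floats(10, 5000),
    BN=st.floats(1, 100),
    DC=st.floats(1000, 60000),
    DN=st.floats(50, 3000),
    N=st.floats(0.0, 5.0),
)
driver_strategy = st.builds(
    DriverState,
    Ca=st.floats(100, 1200),
    T=st.floats(0, 25),
    Nin=st.floats(0, 1),
    V=st.floats(0, 200),
)


class TestFluxIdentitiesAndBalance:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(state=state_strategy, drivers=driver_strategy)
    def test_identities_hold_exactly(self, state, drivers):
        f = compute_fluxes(state, drivers, P0)
        assert f.LVC == pytest.approx(f.GC - f.RV, abs=1e-12)
        assert f.LVN == pytest.approx(f.GN - f.VUN, abs=1e-12)
        assert f.QCR == pytest.approx(P0.qDOM * f.QNR, abs=1e-12)
        assert f.GPP == f.Ps
        assert f.NPP == pytest.approx(f.Ps - f.Ra)
        assert f.NEP == pytest.approx(f.Ps - f.Ra - f.Rh - f.RV)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(state=state_strategy, drivers=driver_strategy)
    def test_fluxes_nonnegative(self, state, drivers):
        f = compute_fluxes(state, drivers, P0)
        for name in ("Ps", "Ra", "LitC", "Rh", "GC", "RV", "QCR",
                     "UN", "LitN", "Nmin", "UNm", "GN", "VUN", "QNR", "QDIN"):
            assert getattr(f, name) >= 0.0, name

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(state=state_strategy, drivers=driver_strategy)
    def test_whole_system_mass_balance(self, state, drivers):
        """Consumed C either respires or re-enters soil; N closes on inputs
        minus losses."""
        f = compute_fluxes(state, drivers, P0)
        d = state_derivatives(state, f, drivers)
        c_rhs = f.Ps - f.Ra - f.Rh - f.RV - f.QCR
        n_rhs = drivers.Nin - f.QNR - f.QDIN
        assert d.dBC + d.dDC == pytest.approx(c_rhs, rel=1e-9, abs=1e-9)
        assert d.dBN + d.dDN + d.dN == pytest.approx(n_rhs, rel=1e-9, abs=1e-9)


class TestTemperatureResponse:
    @pytest.mark.parametrize("name", ["Ps", "Ra", "Rh", "UN", "UNm", "Nmin"])
    def test_q10_fluxes_increase_with_warming(self, name):
        f_cold = compute_fluxes(EcosystemState(), DriverState(T=10, V=50), P0)
        f_warm = compute_fluxes(EcosystemState(), DriverState(T=14, V=50), P0)
        assert getattr(f_warm, name) > getattr(f_cold, name)

    @pytest.mark.parametrize("name", ["GC", "RV"])
    def test_vole_metabolism_declines_with_warming(self, name):
        f_cold = compute_fluxes(EcosystemState(), DriverState(T=10, V=50), P0)
        f_warm = compute_fluxes(EcosystemState(), DriverState(T=14, V=50), P0)
        assert getattr(f_warm, name) < getattr(f_cold, name)


class TestStoichiometricFeedbackSigns:
    """Causal signs of the C:N acclimation feedbacks around Psi = Phi = 1.

    Psi is perturbed through BN (leaving S untouched) and Phi through DN;
    finite differences must match the causal-chain structure: rising plant
    C:N down-regulates photosynthesis and litter N while up-regulating plant
    N uptake; rising soil C:N up-regulates immobilization and shrinks net
    mineralization.
    """

    def _fluxes_at(self, BN=20.6, DN=831.0):
        state = EcosystemState(BC=878, BN=BN, DC=19452, DN=DN, N=0.27)
        return compute_fluxes(state, DriverState(), P0)

    def test_signs_with_respect_to_psi(self):
        # smaller BN -> larger Psi
        lo, hi = self._fluxes_at(BN=20.6 * 1.01), self._fluxes_at(BN=20.6 * 0.99)
        assert hi.Ps < lo.Ps          # dPs/dPsi < 0
        assert hi.UN > lo.UN          # dUN/dPsi > 0
        assert hi.LitN < lo.LitN      # dLitN/dPsi < 0

    def test_signs_with_respect_to_phi(self):
        # smaller DN -> larger Phi
        lo, hi = self._fluxes_at(DN=831 * 1.01), self._fluxes_at(DN=831 * 0.99)
        assert hi.UNm > lo.UNm                        # dUNm/dPhi > 0
        assert (hi.Nmin - hi.UNm) < (lo.Nmin - lo.UNm)  # net mineralization drops


class TestStateDerivatives:
    def test_input_only_limit(self):
        """With every process rate zero, only external N input moves a pool."""
        from tundracn.model_core import FluxSet

        zero = FluxSet(*([0.0] * 20))
        d = state_derivatives(EcosystemState(), zero, DriverState(Nin=0.133))
        assert d.dN == pytest.approx(0.133, abs=1e-12)
        assert d.dBC == d.dBN == d.dDC == d.dDN == 0.0

    def test_zero_plant_carbon_is_degenerate(self):
        with pytest.raises(DegenerateStateError):
            compute_fluxes(
                EcosystemState(BC=0, BN=1.0, DC=100.0, DN=10.0, N=0.1),
                DriverState(),
                P0,
            )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ParameterSet(rV=1.5)
        with pytest.raises(ValueError):
            ParameterSet(qB=10.0)  # below forage C:N
        with pytest.raises(ValueError):
            ParameterSet(gC=-1.0)
        with pytest.raises(ValueError):
            EcosystemState(BC=-5)

    def test_steady_state_derivatives_vanish_for_derived_parameters(self, cal_I):
        f = compute_fluxes(EcosystemState(), DriverState(), cal_I.params)
        d = state_derivatives(EcosystemState(), f, DriverState())
        assert d.max_abs() < 1e-9

    def test_math_isfinite_everywhere_reasonable(self):
        f = compute_fluxes(
            EcosystemState(BC=1e-9, BN=1e-9, DC=1e-9, DN=1e-9, N=0.0),
            DriverState(),
            P0,
        )
        assert all(math.isfinite(getattr(f, n)) for n in f.__slots__)
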