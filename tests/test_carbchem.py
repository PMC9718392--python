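"""Carbonate-system speciation, alkalinity and titrant mass balance."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aragsim import (
    ARTIFICIAL_SEAWATER,
    NATURAL_SEAWATER,
    ConstantsSet,
    SeawaterState,
    TitrantDose,
    alkalinity_from_pH_DIC,
    apply_dose,
    co2_invasion_rate,
    pH_from_alkalinity_DIC,
    solve_speciation,
)
from aragsim.carbchem import ConfigurationError

from conftest import CONDITIONS, water_at


class TestSpeciation:
    @pytest.mark.parametrize("pH,dic,omega_expected", CONDITIONS)
    def test_omega_matches_printed_conditions(self, pH, dic, omega_expected):
        """Mean Ω of the two study waters at each set point, within the
        ±0.2 sensitivity of the Ω calculation itself."""
        omegas = [
            solve_speciation(water_at(w, pH, dic)).omega_aragonite
            for w in (NATURAL_SEAWATER, ARTIFICIAL_SEAWATER)
        ]
        mean = sum(omegas) / 2.0
        assert mean == pytest.approx(omega_expected, abs=0.2)

    def test_empty_carbonate_pool(self):
        sp = solve_speciation(SeawaterState(DIC=0.0))
        assert (sp.CO2aq, sp.HCO3, sp.CO3, sp.pCO2, sp.omega_aragonite) == (
            0.0, 0.0, 0.0, 0.0, 0.0,
        )

    def test_omega_is_direct_ion_product(self, constants25):
        """Ω must equal Ca·CO3/Ksp exactly; frozen arithmetic case:
        [CO3]=700 μmol/kg, [Ca]=10 mmol/kg, Ksp=6.48e-7 → Ω=10.80."""
        assert 0.010 * 700e-6 / 6.48e-7 == pytest.approx(10.80, abs=0.005)
        st_ = SeawaterState(pH_NBS=8.4, DIC=4000.0, Ca=10.0)
        sp = solve_speciation(st_, constants25)
        assert sp.omega_aragonite == pytest.approx(
            0.010 * sp.CO3 * 1e-6 / constants25.Ksp_arag, rel=1e-12
        )

    def test_ksp_aragonite_25C_S35(self, constants25):
        assert constants25.Ksp_arag == pytest.approx(6.48e-7, rel=0.005)

    @pytest.mark.parametrize("pH", [7.5, 7.9, 8.3, 8.7, 9.0])
    def test_species_sum_to_dic(self, pH):
        sp = solve_speciation(SeawaterState(pH_NBS=pH, DIC=2500.0))
        assert sp.DIC == pytest.approx(2500.0, rel=1e-4)
        assert min(sp.CO2aq, sp.HCO3, sp.CO3) >= 0.0

    def test_omega_monotone_in_co3_and_ca(self):
        base = SeawaterState(pH_NBS=8.3, DIC=3000.0, Ca=10.0)
        sp = solve_speciation(base)
        more_dic = solve_speciation(dataclasses.replace(base, DIC=3500.0))
        more_ca = solve_speciation(dataclasses.replace(base, Ca=10.5))
        assert more_dic.CO3 > sp.CO3
        assert more_dic.omega_aragonite > sp.omega_aragonite
        assert more_ca.omega_aragonite > sp.omega_aragonite

    def test_water_composition_difference_shifts_omega_weakly(self):
        """Swapping between the natural and artificial stock waters (their
        Ca and salinity both differ slightly) moves Ω by ≤0.2 at the two
        lower set points; Ω is exactly linear in Ca."""
        for pH, dic, omega in CONDITIONS[:2]:
            nat = solve_speciation(water_at(NATURAL_SEAWATER, pH, dic))
            art = solve_speciation(water_at(ARTIFICIAL_SEAWATER, pH, dic))
            assert abs(nat.omega_aragonite - art.omega_aragonite) <= 0.2
        w = water_at(NATURAL_SEAWATER, 8.445, 4000.0)
        hi = solve_speciation(w).omega_aragonite
        lo = solve_speciation(dataclasses.replace(w, Ca=9.9)).omega_aragonite
        assert hi / lo == pytest.approx(10.1 / 9.9, rel=1e-9)

    def test_constant_sets_mutually_consistent(self):
        """Independent K1/K2 formulations agree closely after scale
        conversion (cross-validation of the constants machinery)."""
        a = ConstantsSet.from_conditions(25.0, 34.0, "mehrbach_dm87")
        b = ConstantsSet.from_conditions(25.0, 34.0, "lueker2000")
        assert math.log10(a.K1 / b.K1) == pytest.approx(0.0, abs=0.01)
        assert math.log10(a.K2 / b.K2) == pytest.approx(0.0, abs=0.02)

    def test_unknown_constant_set_rejected(self):
        with pytest.raises(ConfigurationError):
            ConstantsSet.from_conditions(25.0, 35.0, "nonsense")


class TestAlkalinity:
    def test_round_trip_pH(self):
        state = SeawaterState(pH_NBS=8.445, DIC=4000.0, salinity=33.7)
        ta = alkalinity_from_pH_DIC(state)
        pH_back = pH_from_alkalinity_DIC(ta, 4000.0, salinity=33.7)
        assert pH_back == pytest.approx(8.445, abs=1e-4)

    def test_dose_shifts_alkalinity_by_two_equivalents(self):
        state = SeawaterState(volume=0.330, TA=2309.0)
        dosed = apply_dose(state, TitrantDose("Na2CO3", 0.6, 0.5))
        n_umol = 0.6 * 0.5 * 1e3  # μmol
        assert dosed.TA - state.TA == pytest.approx(2 * n_umol / 0.330, rel=1e-12)

    def test_ambient_equilibrated_water_returns_ambient_pco2(self):
        """The stock artificial seawater (TA 2309, DIC 2015) was bubbled
        with ~410–420 μatm air; the solver must recover that pCO2."""
        pH = pH_from_alkalinity_DIC(2309.0, 2015.0, salinity=33.7)
        sp = solve_speciation(
            SeawaterState(pH_NBS=pH, DIC=2015.0, salinity=33.7, Ca=9.9)
        )
        assert 410.0 - 15.0 <= sp.pCO2 <= 420.0 + 15.0


class TestDoses:
    @pytest.mark.parametrize(
        "volume,d_ta,d_dic",
        [(0.318, 1156.0, 578.0), (0.176, 640.0, 320.0)],
    )
    def test_na2co3_budget(self, volume, d_ta, d_dic):
        """Logged mid-lag doses must reproduce the published TA/DIC budgets
        for a 330 mL volume."""
        state = SeawaterState(volume=0.330, DIC=3000.0, TA=3500.0)
        dosed = apply_dose(state, TitrantDose("Na2CO3", 0.6, volume))
        assert dosed.DIC - state.DIC == pytest.approx(d_dic, abs=0.5)
        assert dosed.TA - state.TA == pytest.approx(d_ta, abs=1.0)

    def test_zero_dose_is_identity(self):
        state = SeawaterState()
        assert apply_dose(state, TitrantDose("HCl", 1.0, 0.0)) == state

    def test_cacl2_adds_calcium_only(self):
        state = SeawaterState(volume=0.330, TA=2300.0)
        dosed = apply_dose(state, TitrantDose("CaCl2_SrCl2", 0.6, 1.0))
        assert dosed.Ca - state.Ca == pytest.approx(0.6e-3 * 1e3 / 0.330)
        assert dosed.TA == state.TA and dosed.DIC == state.DIC

    def test_acid_base_move_alkalinity_oppositely(self):
        state = SeawaterState(volume=0.330, TA=2300.0)
        acid = apply_dose(state, TitrantDose("HCl", 1.0, 0.1))
        base = apply_dose(state, TitrantDose("NaOH", 1.0, 0.1))
        d = 1.0 * 0.1 * 1e3 / 0.330
        assert acid.TA == pytest.approx(2300.0 - d)
        assert base.TA == pytest.approx(2300.0 + d)

    def test_unknown_reagent_rejected(self):
        with pytest.raises(ConfigurationError):
            TitrantDose("KCl", 0.6, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        volumes=st.lists(
            st.floats(0.0, 2.0, allow_nan=False), min_size=1, max_size=6
        )
    )
    def test_dic_mass_balance_over_dose_sequences(self, volumes):
        """Final − initial DIC equals Σ moles dosed / mass, exactly."""
        state = SeawaterState(volume=0.330, DIC=3000.0)
        total = 0.0
        for v in volumes:
            state = apply_dose(state, TitrantDose("Na2CO3", 0.6, v))
            total += 0.6 * v * 1e3
        assert state.DIC - 3000.0 == pytest.approx(total / 0.330, rel=1e-9, abs=1e-9)


class TestInvasionRate:
    def test_flux_arithmetic(self):
        assert co2_invasion_rate(100.0, 40.0, 2.0) == pytest.approx(30.0)

    def test_equilibrium_is_zero(self):
        assert co2_invasion_rate(55.0, 55.0, 3.0) == 0.0

    def test_published_low_omega_budget(self):
        """DIC rose 1042 vs 578 μmol/kg predicted; a 26 μmol/kg/h flux
        implies ~17.8 h elapsed — inverse consistency."""
        elapsed = (1042.0 - 578.0) / 26.0
        assert elapsed == pytest.approx(17.85, abs=0.05)
        assert co2_invasion_rate(1042.0, 578.0, elapsed) == pytest.approx(26.0)

    def test_nonpositive_elapsed_rejected(self):
        with pytest.raises(ValueError):
            co2_invasion_rate(10.0, 5.0, 0.0)


class TestStateValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"salinity": 50.0},
            {"DIC": -1.0},
            {"Ca": 0.0},
            {"TA": float("nan")},
        ],
    )
    def test_invalid_states_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SeawaterState(**kwargs)

    def test_mass_defaults_to_volume(self):
        assert SeawaterState(volume=0.33).solution_mass == 0.33
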