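"""Seawater CO2-system speciation and titrant mass balance.

Implements the carbonate-system arithmetic needed to run and interpret
constant-composition (pH-stat) aragonite precipitation experiments:

* equilibrium-constant sets for the seawater CO2 system on the seawater
  pH scale (SWS), with NBS-scale input handled through the activity
  coefficient ``fH``;
* speciation of DIC at fixed ``(pH_NBS, DIC, T, S)`` and the aragonite
  saturation state  Ω = [Ca2+][CO3 2-] / Ksp_aragonite ;
* total alkalinity from (pH, DIC) and the inverse pH solve from (TA, DIC);
* stoichiometric bookkeeping of titrant doses (Na2CO3, CaCl2/SrCl2, HCl,
  NaOH) and the CO2-invasion flux inferred from DIC budgets.

Concentration units follow marine-chemistry convention: DIC and TA in
μmol kg⁻¹, Ca and Mg in mmol kg⁻¹, equilibrium constants in mol kg⁻¹
(Ksp in mol² kg⁻²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

from scipy.optimize import brentq

__all__ = [
    "SeawaterState",
    "ConstantsSet",
    "Speciation",
    "TitrantDose",
    "SpeciationError",
    "ConfigurationError",
    "solve_speciation",
    "apply_dose",
    "alkalinity_from_pH_DIC",
    "pH_from_alkalinity_DIC",
    "co2_invasion_rate",
    "NATURAL_SEAWATER",
    "ARTIFICIAL_SEAWATER",
]


class SpeciationError(RuntimeError):
    """Raised when the carbonate-system solve fails to converge."""


class ConfigurationError(ValueError):
    """Raised for invalid reagents or constant-set selections."""


K1K2Set = Literal["mehrbach_dm87", "lueker2000"]


@dataclass(frozen=True)
class SeawaterState:
    """Composition and conditions of the precipitating solution at a time point.

    Parameters
    ----------
    temperature : float
        °C.
    salinity : float
        Practical salinity.
    pH_NBS : float
        pH on the NBS (NIST buffer) scale, as logged by a glass electrode
        calibrated against NBS buffers.
    DIC : float
        Dissolved inorganic carbon, μmol kg⁻¹.
    TA : float or None
        Total alkalinity, μmol kg⁻¹.  Optional; derivable from (pH, DIC)
        via :func:`alkalinity_from_pH_DIC`.
    Ca, Mg : float
        mmol kg⁻¹.
    volume : float
        Solution volume, L.
    solution_mass : float or None
        kg.  Defaults to the numerical value of ``volume`` (density 1
        convention used by the experimental mass budgets); pass an
        explicit mass to apply a density correction.
    """

    temperature: float = 25.0
    salinity: float = 35.0
    pH_NBS: float = 8.1
    DIC: float = 2000.0
    TA: float | None = None
    Ca: float = 10.0
    Mg: float = 52.0
    volume: float = 0.330
    solution_mass: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.salinity < 45.0:
            raise ValueError(f"salinity {self.salinity} outside (0, 45)")
        if self.DIC < 0.0:
            raise ValueError("DIC must be non-negative")
        if self.TA is not None and not math.isfinite(self.TA):
            raise ValueError("TA must be finite")
        if self.Ca <= 0.0:
            raise ValueError("Ca must be positive")
        if self.solution_mass is None:
            object.__setattr__(self, "solution_mass", self.volume)
        if self.solution_mass <= 0.0:
            raise ValueError("solution_mass must be positive")


#: Table of the two stock waters used for precipitations (25 °C).
NATURAL_SEAWATER = SeawaterState(
    salinity=34.1, pH_NBS=8.165, DIC=1933.0, TA=2208.0, Ca=10.1, Mg=51.0
)
ARTIFICIAL_SEAWATER = SeawaterState(
    salinity=33.7, pH_NBS=8.188, DIC=2015.0, TA=2309.0, Ca=9.9, Mg=53.0
)


@dataclass(frozen=True)
class ConstantsSet:
    """Equilibrium constants at fixed (T, S), surface pressure.

    K1/K2/KB/KW are on the seawater pH scale (SWS, mol kg⁻¹-solution);
    KS is on the free scale; ``fH`` is the apparent H⁺ activity
    coefficient linking the NBS scale to SWS
    ([H⁺]_SWS = 10^(−pH_NBS)/fH, Takahashi et al. GEOSECS convention).
    ``Ksp_arag`` is the stoichiometric aragonite solubility product
    (mol² kg⁻², Mucci 1983, 1 atm).
    """

    temperature: float
    salinity: float
    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float
    KF: float
    BT: float
    ST: float
    FT: float
    fH: float
    sws_to_total: float
    Ksp_arag: float
    k1k2_set: str = "mehrbach_dm87"

    def __post_init__(self) -> None:
        for name in ("K0", "K1", "K2", "KB", "KW", "KS", "KF", "BT", "fH", "Ksp_arag"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"constant {name} must be positive")

    @classmethod
    def from_conditions(
        cls,
        temperature: float = 25.0,
        salinity: float = 35.0,
        k1k2: K1K2Set = "mehrbach_dm87",
    ) -> "ConstantsSet":
        """Evaluate the constant formulations at (T, S).

        ``k1k2`` selects the carbonic-acid dissociation constants:
        ``"mehrbach_dm87"`` (Mehrbach et al. 1973 refit by Dickson &
        Millero 1987, SWS scale; the default) or ``"lueker2000"``
        (Lueker et al. 2000, total scale, converted to SWS).
        """
        T = temperature + 273.15
        S = salinity
        lnT = math.log(T)
        sqS = math.sqrt(S)

        # conservative totals, mol kg-sw
        ST = 0.14 / 96.062 * (S / 1.80655)          # sulfate, Morris & Riley
        FT = 0.000067 / 18.998 * (S / 1.80655)      # fluoride, Riley
        BT = 0.0004157 * S / 35.0                   # boron, Uppström 1974

        # bisulfate, Dickson 1990a (free scale, mol kg-H2O -> mol kg-sw)
        I = 19.924 * S / (1000.0 - 1.005 * S)
        lnKS = (
            -4276.1 / T + 141.328 - 23.093 * lnT
            + (-13856.0 / T + 324.57 - 47.986 * lnT) * math.sqrt(I)
            + (35474.0 / T - 771.54 + 114.723 * lnT) * I
            - 2698.0 / T * I ** 1.5
            + 1776.0 / T * I ** 2
        )
        KS = math.exp(lnKS) * (1.0 - 0.001005 * S)

        # hydrogen fluoride, Perez & Fraga 1987 (total scale)
        KF_tot = math.exp(874.0 / T - 9.68 + 0.111 * sqS)

        sws_to_total = (1.0 + ST / KS) / (1.0 + ST / KS + FT / KF_tot)
        KF = KF_tot / sws_to_total  # -> SWS

        # NBS activity convention, Takahashi et al. 1982
        fH = 1.2948 - 0.002036 * T + (0.0004607 - 0.000001475 * T) * S ** 2

        # CO2 solubility, Weiss 1974, mol kg-1 atm-1
        K0 = math.exp(
            -60.2409 + 93.4517 * 100.0 / T + 23.3585 * math.log(T / 100.0)
            + S * (0.023517 - 0.023656 * T / 100.0 + 0.0047036 * (T / 100.0) ** 2)
        )

        # boric acid, Dickson 1990b (total scale -> SWS)
        lnKB = (
            (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S ** 1.5 - 0.0996 * S ** 2) / T
            + 148.0248 + 137.1942 * sqS + 1.62142 * S
            - (24.4344 + 25.085 * sqS + 0.2474 * S) * lnT
            + 0.053105 * sqS * T
        )
        KB = math.exp(lnKB) / sws_to_total

        # water, Millero 1995 (SWS)
        KW = math.exp(
            148.9802 - 13847.26 / T - 23.6521 * lnT
            + (118.67 / T - 5.977 + 1.0495 * lnT) * sqS
            - 0.01615 * S
        )

        if k1k2 == "mehrbach_dm87":
            pK1 = 3670.7 / T - 62.008 + 9.7944 * lnT - 0.0118 * S + 0.000116 * S ** 2
            pK2 = 1394.7 / T + 4.777 - 0.0184 * S + 0.000118 * S ** 2
            K1, K2 = 10.0 ** -pK1, 10.0 ** -pK2
        elif k1k2 == "lueker2000":
            pK1 = 3633.86 / T - 61.2172 + 9.6777 * lnT - 0.011555 * S + 0.0001152 * S ** 2
            pK2 = 471.78 / T + 25.929 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S ** 2
            K1, K2 = 10.0 ** -pK1 / sws_to_total, 10.0 ** -pK2 / sws_to_total
        else:
            raise ConfigurationError(f"unknown K1/K2 set {k1k2!r}")

        # aragonite solubility, Mucci 1983 (1 atm)
        logKsp = (
            -171.945 - 0.077993 * T + 2903.293 / T + 71.595 * math.log10(T)
            + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqS
            - 0.10018 * S + 0.0059415 * S ** 1.5
        )
        Ksp = 10.0 ** logKsp

        return cls(
            temperature=temperature, salinity=salinity,
            K0=K0, K1=K1, K2=K2, KB=KB, KW=KW, KS=KS, KF=KF,
            BT=BT, ST=ST, FT=FT, fH=fH, sws_to_total=sws_to_total,
            Ksp_arag=Ksp, k1k2_set=k1k2,
        )

    def h_sws_from_pH_NBS(self, pH_NBS: float) -> float:
        """[H⁺] on the seawater scale from an NBS-scale pH reading."""
        return 10.0 ** (-pH_NBS) / self.fH

    def pH_NBS_from_h_sws(self, h_sws: float) -> float:
        return -math.log10(h_sws * self.fH)


@dataclass(frozen=True)
class Speciation:
    """DIC speciation and aragonite saturation state.

    CO2aq/HCO3/CO3 in μmol kg⁻¹, pCO2 in μatm; ``omega_aragonite`` is
    [Ca][CO3]/Ksp (dimensionless).
    """

    CO2aq: float
    HCO3: float
    CO3: float
    pCO2: float
    omega_aragonite: float

    @property
    def DIC(self) -> float:
        return self.CO2aq + self.HCO3 + self.CO3


@dataclass(frozen=True)
class TitrantDose:
    """A single titrant addition: reagent, molarity (mol L⁻¹), volume (mL)."""

    reagent: Literal["Na2CO3", "CaCl2_SrCl2", "HCl", "NaOH"]
    molarity: float
    volume: float

    _REAGENTS = ("Na2CO3", "CaCl2_SrCl2", "HCl", "NaOH")

    def __post_init__(self) -> None:
        if self.reagent not in self._REAGENTS:
            raise ConfigurationError(
                f"unknown reagent {self.reagent!r}; expected one of {self._REAGENTS}"
            )
        if self.molarity <= 0.0:
            raise ValueError("molarity must be positive")
        if self.volume < 0.0:
            raise ValueError("dose volume must be non-negative")

    @property
    def moles(self) -> float:
        """Moles of reagent in the dose (mol)."""
        return self.molarity * self.volume * 1e-3


def _constants_for(state: SeawaterState, constants: ConstantsSet | None) -> ConstantsSet:
    if constants is None:
        return ConstantsSet.from_conditions(state.temperature, state.salinity)
    return constants


def solve_speciation(
    state: SeawaterState, constants: ConstantsSet | None = None
) -> Speciation:
    """Speciate DIC at fixed (pH_NBS, DIC) and compute Ω_aragonite.

    The solve is closed-form at fixed pH: with h = [H⁺]_SWS,

        [CO2*]  = DIC / (1 + K1/h + K1·K2/h²)
        [HCO3⁻] = [CO2*]·K1/h
        [CO3²⁻] = [HCO3⁻]·K2/h

    and Ω = [Ca²⁺][CO3²⁻]/Ksp_aragonite with concentrations in mol kg⁻¹.
    Deterministic for a fixed :class:`ConstantsSet`.
    """
    c = _constants_for(state, constants)
    if not math.isfinite(state.pH_NBS):
        raise SpeciationError(f"non-finite pH_NBS input: {state.pH_NBS}")
    if state.DIC == 0.0:
        return Speciation(0.0, 0.0, 0.0, 0.0, 0.0)
    h = c.h_sws_from_pH_NBS(state.pH_NBS)
    if not (0.0 < h < 1.0):
        raise SpeciationError(
            f"pH_NBS={state.pH_NBS} maps to unphysical [H+]={h:.3g} mol/kg"
        )
    dic = state.DIC * 1e-6
    denom = 1.0 + c.K1 / h + c.K1 * c.K2 / h ** 2
    co2 = dic / denom
    hco3 = co2 * c.K1 / h
    co3 = hco3 * c.K2 / h
    omega = (state.Ca * 1e-3) * co3 / c.Ksp_arag
    pco2 = co2 / c.K0 * 1e6
    return Speciation(co2 * 1e6, hco3 * 1e6, co3 * 1e6, pco2, omega)


def alkalinity_from_pH_DIC(
    state: SeawaterState, constants: ConstantsSet | None = None
) -> float:
    """Total alkalinity (μmol kg⁻¹) implied by the state's (pH_NBS, DIC).

    TA = [HCO3⁻] + 2[CO3²⁻] + [B(OH)4⁻] + [OH⁻] − [H⁺]_free − [HSO4⁻] − [HF].
    Nutrient and organic alkalinity are neglected.
    """
    c = _constants_for(state, constants)
    h = c.h_sws_from_pH_NBS(state.pH_NBS)
    sp = solve_speciation(state, c)
    boh4 = c.BT * c.KB / (c.KB + h)
    oh = c.KW / h
    h_free = h / (1.0 + c.ST / c.KS + c.FT / c.KF)
    hso4 = c.ST * h_free / (h_free + c.KS)
    hf = c.FT * h / (h + c.KF)
    ta = (sp.HCO3 + 2.0 * sp.CO3) * 1e-6 + boh4 + oh - h_free - hso4 - hf
    return ta * 1e6


def pH_from_alkalinity_DIC(
    TA: float,
    DIC: float,
    temperature: float = 25.0,
    salinity: float = 35.0,
    constants: ConstantsSet | None = None,
) -> float:
    """Invert the alkalinity expression: pH_NBS from (TA, DIC) in μmol kg⁻¹."""
    if constants is None:
        constants = ConstantsSet.from_conditions(temperature, salinity)

    def residual(pH: float) -> float:
        st = SeawaterState(
            temperature=temperature, salinity=salinity, pH_NBS=pH, DIC=DIC
        )
        return alkalinity_from_pH_DIC(st, constants) - TA

    try:
        return brentq(residual, 4.0, 11.0, xtol=1e-9)
    except ValueError as exc:  # pragma: no cover - pathological inputs
        raise SpeciationError(
            f"pH solve failed for TA={TA}, DIC={DIC}: {exc}"
        ) from exc


def apply_dose(state: SeawaterState, dose: TitrantDose) -> SeawaterState:
    """Mass-balance update of the solution for one titrant dose.

    Stoichiometry per mole of reagent, with m the solution mass (kg):

    * Na2CO3:      ΔDIC = n/m, ΔTA = 2n/m  (carbonate carries 2 eq)
    * CaCl2_SrCl2: ΔCa = n/m (Sr counted as Ca-equivalent), ΔTA = ΔDIC = 0
    * HCl:         ΔTA = −n/m
    * NaOH:        ΔTA = +n/m

    pH is left unchanged: under pH-stat operation the controller holds it at
    the set point.  Volume change from the dose is neglected (doses are
    ≲1% of the solution volume).
    """
    if dose.volume == 0.0:
        return state
    m = state.solution_mass
    n_umol = dose.moles * 1e6
    ta0 = state.TA if state.TA is not None else None
    if dose.reagent == "Na2CO3":
        return replace(
            state,
            DIC=state.DIC + n_umol / m,
            TA=None if ta0 is None else ta0 + 2.0 * n_umol / m,
        )
    if dose.reagent == "CaCl2_SrCl2":
        return replace(state, Ca=state.Ca + dose.moles * 1e3 / m)
    if dose.reagent == "HCl":
        return replace(state, TA=None if ta0 is None else ta0 - n_umol / m)
    if dose.reagent == "NaOH":
        return replace(state, TA=None if ta0 is None else ta0 + n_umol / m)
    raise ConfigurationError(f"unknown reagent {dose.reagent!r}")  # pragma: no cover


def co2_invasion_rate(
    dic_obs_delta: float, dic_dose_delta: float, elapsed: float
) -> float:
    """CO2-invasion flux (μmol kg⁻¹ h⁻¹) from a DIC budget.

    The observed DIC increase in excess of what the logged Na2CO3 dosing
    accounts for is attributed to invasion of atmospheric CO2 (negative
    values indicate outgassing).

    Parameters
    ----------
    dic_obs_delta, dic_dose_delta : float
        Observed and dose-predicted DIC change over the interval, μmol kg⁻¹.
    elapsed : float
        Interval length, h.  Must be positive.
    """
    if elapsed <= 0.0:
        raise ValueError("elapsed time must be positive")
    return (dic_obs_delta - dic_dose_delta) / elapsed
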