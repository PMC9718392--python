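"""Synthetic experiments with the statistical structure of the laboratory data.

Every stage of the pipeline (forward simulation → rate inversion → Raman
fitting → group statistics) can be exercised without laboratory data by
generating (i) dosing profiles from the epitaxial-growth forward model,
degraded with the imperfections a titrator log shows — the 2 μL dosing
quantum, timing jitter, multiplicative dosing noise, nucleation lags,
CO2-invasion drift and between-replicate rate variability — and (ii)
aragonite Raman spectra with the ν₁ band at ~1084 cm⁻¹, the ν₄ doublet at
701/705 cm⁻¹, lattice-mode humps below 250 cm⁻¹, a linear baseline and
Gaussian counting noise.

All randomness flows from ``seed_rng``; a fixed seed reproduces every
draw bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.special import voigt_profile

from .carbchem import ARTIFICIAL_SEAWATER, NATURAL_SEAWATER, SeawaterState
from .forward import DosingProfile, ExperimentConfig, simulate_profile
from .raman import Spectrum
from .seedgeom import SeedPopulation

__all__ = [
    "ScenarioSpec",
    "NoiseSpec",
    "RamanSpec",
    "generate_profile",
    "generate_spectra",
    "scenario_grid",
    "CONDITIONS",
    "default_rate",
]

#: Experimental conditions: Ω → (pH_NBS, DIC μmol kg⁻¹) at 25 °C.
CONDITIONS: dict[float, tuple[float, float]] = {
    6.9: (8.337, 3000.0),
    11.3: (8.445, 4000.0),
    19.2: (8.564, 5500.0),
    11.2: (8.445, 4000.0),  # aspartic-acid series (same pH/DIC point)
}

_WATERS = {"natural": NATURAL_SEAWATER, "artificial": ARTIFICIAL_SEAWATER}

#: Natural-vs-artificial rate ratio (natural typically ~19% faster).
NATURAL_RATE_FACTOR = 1.19

#: Reference rate: 617 μmol m⁻² h⁻¹ at Ω = 6.9 in natural seawater.
_RATE_K = 617.0 / (6.9 - 1.0) ** 1.7


def default_rate(omega: float, water: Literal["natural", "artificial"]) -> float:
    """Default surface-normalised rate (μmol m⁻² h⁻¹) for a condition.

    Empirical power law R = k(Ω−1)^1.7 anchored at 617 μmol m⁻² h⁻¹ for
    Ω = 6.9 in natural seawater; artificial seawater is slower by the
    typical ~19% natural-water enhancement.
    """
    r = _RATE_K * (omega - 1.0) ** 1.7
    return r if water == "natural" else r / NATURAL_RATE_FACTOR


def _default_lag(omega: float, seed_mg: float, water: str) -> float:
    """Default nucleation lag (s): long at low Ω and low seed mass,
    longer in natural seawater, absent at high Ω."""
    if seed_mg <= 0.0:
        return 0.0
    if omega <= 7.0 and seed_mg <= 100.0:
        base = 4000.0 if seed_mg <= 50.0 else 2000.0
        return base * (1.5 if water == "natural" else 1.0)
    if 10.0 <= omega <= 12.0 and seed_mg <= 50.0 and water == "natural":
        return 1800.0
    return 0.0


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-imperfection model for synthetic dosing profiles.

    ``dose_quantum_uL``: titrator burette increment (cumulative volume is
    floored to multiples of it).  ``timing_jitter_s``: sd of the
    log-timestamp jitter.  ``multiplicative_sd``: relative sd applied to
    each dose increment.  ``rate_rel_sd``: between-replicate relative sd
    of the realised rate (captures the run-to-run variability that makes
    duplicate CVs ~6%).
    """

    dose_quantum_uL: float = 2.0
    timing_jitter_s: float = 2.0
    multiplicative_sd: float = 0.01
    rate_rel_sd: float = 0.06

    def __post_init__(self) -> None:
        if min(self.dose_quantum_uL, self.timing_jitter_s,
               self.multiplicative_sd, self.rate_rel_sd) < 0.0:
            raise ValueError("noise scales must be non-negative")


@dataclass(frozen=True)
class RamanSpec:
    """Generating parameters for synthetic aragonite spectra."""

    fwhm_mean: float = 1.8
    fwhm_sd: float = 0.15
    center_mean: float = 1084.3
    center_sd: float = 0.05
    n_spectra: int = 10
    amplitude: float = 1000.0
    noise_sd_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.fwhm_mean <= 0.0 or self.n_spectra < 1:
            raise ValueError("fwhm_mean must be positive, n_spectra >= 1")
        if min(self.fwhm_sd, self.center_sd, self.noise_sd_frac) < 0.0:
            raise ValueError("spread parameters must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    """One synthetic experimental condition.

    ``aspartic_mM`` enters phenomenologically through ``rate_modifier``
    and the Raman FWHM offset chosen by :func:`scenario_grid`; no
    adsorption mechanism is modelled.
    """

    water: Literal["artificial", "natural"] = "artificial"
    omega: float = 11.3
    seed_mass: float = 200.0          # mg; 0 = unseeded
    true_rate: float | None = None    # μmol m⁻² h⁻¹; None = default_rate(Ω)
    lag: float | None = None          # s; None = condition default
    invasion_flux: float = 0.0        # μmol kg⁻¹ h⁻¹
    target_dose: float = 5.0          # mL of each titrant
    aspartic_mM: float = 0.0
    rate_modifier: float = 1.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    raman: RamanSpec = field(default_factory=RamanSpec)
    seed_rng: int = 0
    # unseeded runs only: user-supplied effective nucleation description
    nucleation_onset_s: float | None = None
    effective_area_m2: float | None = None

    def __post_init__(self) -> None:
        if self.water not in _WATERS:
            raise ValueError(f"unknown water {self.water!r}")
        if self.omega not in CONDITIONS:
            raise ValueError(f"no condition table entry for omega={self.omega}")
        if self.seed_mass < 0.0 or self.aspartic_mM < 0.0:
            raise ValueError("masses and concentrations must be non-negative")
        if self.rate_modifier < 0.0 or self.invasion_flux < 0.0:
            raise ValueError("rate_modifier and invasion_flux must be non-negative")

    # -- resolved quantities --------------------------------------------
    @property
    def solution(self) -> SeawaterState:
        pH, dic = CONDITIONS[self.omega]
        return replace(_WATERS[self.water], pH_NBS=pH, DIC=dic, TA=None)

    @property
    def resolved_rate(self) -> float:
        base = (
            self.true_rate
            if self.true_rate is not None
            else default_rate(self.omega, self.water)
        )
        return base * self.rate_modifier

    @property
    def resolved_lag(self) -> float:
        if self.lag is not None:
            return self.lag
        return _default_lag(self.omega, self.seed_mass, self.water)

    def experiment_config(self, rate: float | None = None) -> ExperimentConfig:
        """Forward-model configuration for this scenario."""
        if self.seed_mass > 0.0:
            seed = SeedPopulation.from_mass_ssa(self.seed_mass * 1e-3)
            lag = self.resolved_lag
        elif self.effective_area_m2 is not None:
            # unseeded: descriptive pseudo-seed carrying the stated area
            seed = SeedPopulation.from_mass_ssa(self.effective_area_m2 / 4.2)
            lag = self.nucleation_onset_s or 0.0
        else:
            raise ValueError(
                "unseeded scenario needs nucleation_onset_s and effective_area_m2"
            )
        return ExperimentConfig(
            seed=seed,
            rate=self.resolved_rate if rate is None else rate,
            lag=lag,
            invasion_flux=self.invasion_flux,
            solution=self.solution,
            target_dose=self.target_dose,
        )


# ---------------------------------------------------------------------------
# dosing profiles

def generate_profile(spec: ScenarioSpec, replicate: int = 0) -> DosingProfile:
    """Synthesise one logged dosing profile for a scenario.

    The noiseless forward profile is computed at a realised rate (drawn
    around the scenario truth with ``rate_rel_sd``), then degraded:
    multiplicative noise on dose increments, cumulative volume floored
    to the dose quantum, Gaussian timestamp jitter (monotonicity
    preserved).  The generating truth is recorded in the metadata.
    """
    rng = np.random.default_rng((spec.seed_rng, replicate))
    noise = spec.noise
    realised_rate = spec.resolved_rate
    if noise.rate_rel_sd > 0.0:
        realised_rate *= float(np.exp(rng.normal(0.0, noise.rate_rel_sd)))
    cfg = spec.experiment_config(rate=realised_rate)
    clean = simulate_profile(cfg)

    t = clean.times
    v = clean.cumulative_volume
    # thin very long runs to a realistic logging density
    if t.size > 2000:
        idx = np.unique(np.linspace(0, t.size - 1, 2000).astype(int))
        t, v = t[idx], v[idx]

    if noise.multiplicative_sd > 0.0:
        incr = np.diff(v, prepend=0.0)
        incr = np.clip(incr * (1.0 + rng.normal(0.0, noise.multiplicative_sd,
                                                incr.size)), 0.0, None)
        v = np.cumsum(incr)
    if noise.dose_quantum_uL > 0.0:
        q = noise.dose_quantum_uL * 1e-3
        v = np.floor(v / q) * q
    if noise.timing_jitter_s > 0.0:
        t = t + rng.normal(0.0, noise.timing_jitter_s, t.size)
        t[0] = 0.0
        t = np.maximum.accumulate(t)

    meta = {
        "synthetic": True,
        "water": spec.water,
        "omega": spec.omega,
        "seed_mass_mg": spec.seed_mass,
        "true_rate_umol_m2_h": spec.resolved_rate,
        "realised_rate_umol_m2_h": realised_rate,
        "lag_s": spec.resolved_lag,
        "invasion_flux_umol_kg_h": spec.invasion_flux,
        "aspartic_mM": spec.aspartic_mM,
        "seed_rng": spec.seed_rng,
        "replicate": replicate,
    }
    return DosingProfile(t, v, meta)


# ---------------------------------------------------------------------------
# Raman spectra

#: Default wavenumber grid (cm⁻¹), matching the acquisition range.
RAMAN_GRID = np.arange(100.0, 1311.0 + 0.5, 1.0)


def _voigt_widths_for_fwhm(fwhm: float) -> tuple[float, float]:
    """(sigma, gamma) whose Voigt FWHM ≈ ``fwhm`` (Olivero–Longbothum).

    The Lorentzian share is fixed at 40% of the total width:
    f ≈ 0.5346·fL + sqrt(0.2166·fL² + fG²).
    """
    fl = 0.4 * fwhm
    fg = math.sqrt(max((fwhm - 0.5346 * fl) ** 2 - 0.2166 * fl ** 2, 1e-12))
    return fg / (2.0 * math.sqrt(2.0 * math.log(2.0))), fl / 2.0


def _voigt_peak(x: np.ndarray, center: float, fwhm: float, height: float) -> np.ndarray:
    sigma, gamma = _voigt_widths_for_fwhm(fwhm)
    prof = voigt_profile(x - center, sigma, gamma)
    return height * prof / voigt_profile(np.zeros(1), sigma, gamma)[0]


def _gauss(x: np.ndarray, center: float, sd: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - center) / sd) ** 2)


def generate_spectra(
    spec: ScenarioSpec, fwhm_offset: float = 0.0
) -> list[Spectrum]:
    """Generate ``spec.raman.n_spectra`` synthetic aragonite spectra.

    Per spectrum the ν₁ centre and FWHM are drawn around the group means;
    ``fwhm_offset`` shifts the group FWHM (used for the high-aspartic
    broadening scenarios).  Each spectrum carries the ν₄ doublet, two
    lattice-mode humps, a linear baseline and Gaussian noise.
    """
    r = spec.raman
    rng = np.random.default_rng((spec.seed_rng, 7919))
    x = RAMAN_GRID
    spectra = []
    for i in range(r.n_spectra):
        center = rng.normal(r.center_mean, r.center_sd)
        fwhm = max(0.3, rng.normal(r.fwhm_mean + fwhm_offset, r.fwhm_sd))
        amp = r.amplitude * float(np.exp(rng.normal(0.0, 0.05)))
        y = _voigt_peak(x, center, fwhm, amp)
        y += _voigt_peak(x, 701.1, 2.0, 0.14 * amp)    # nu4 doublet
        y += _voigt_peak(x, 705.5, 2.0, 0.16 * amp)
        y += _gauss(x, 152.0, 8.0, 0.30 * amp)          # lattice modes
        y += _gauss(x, 206.0, 7.0, 0.45 * amp)
        y += 0.05 * amp + 0.02 * (x - x[0]) / (x[-1] - x[0]) * amp  # baseline
        if r.noise_sd_frac > 0.0:
            y = y + rng.normal(0.0, r.noise_sd_frac * amp, x.size)
        spectra.append(
            Spectrum(
                x.copy(), y,
                label=f"omega{spec.omega}_seed{spec.seed_mass:g}mg_"
                      f"asp{spec.aspartic_mM:g}mM_{i:02d}",
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# condition grid

def scenario_grid(base_seed: int = 0) -> list[ScenarioSpec]:
    """The study's condition grid as scenario specs.

    Seeded runs: Ω ∈ {6.9, 11.3, 19.2} × seed ∈ {50, 100, 200, 400} mg ×
    water ∈ {artificial, natural}.  Unseeded runs exist only at Ω = 6.9
    and 19.2 in artificial seawater (with CO2-invasion drift).  The
    aspartic-acid series runs at Ω = 11.2 with 200 mg seed in both
    waters: promotion (+20% rate) at 1–10 μM, no effect at 100 μM,
    inhibition (−45%) and +1 cm⁻¹ ν₁ broadening at ≥ 1 mM.
    """
    specs: list[ScenarioSpec] = []
    idx = 0

    def _rng_seed() -> int:
        nonlocal idx
        idx += 1
        return (base_seed * 100_003 + idx * 7919) % (2 ** 31 - 1)

    for omega in (6.9, 11.3, 19.2):
        for water in ("artificial", "natural"):
            for seed_mg in (50.0, 100.0, 200.0, 400.0):
                specs.append(
                    ScenarioSpec(
                        water=water, omega=omega, seed_mass=seed_mg,
                        seed_rng=_rng_seed(),
                        # low-Omega 50 mg runs were stopped at 2 mL
                        target_dose=2.0 if (omega == 6.9 and seed_mg == 50.0) else 5.0,
                    )
                )
    for omega, flux in ((6.9, 26.0), (19.2, 31.0)):
        specs.append(
            ScenarioSpec(
                water="artificial", omega=omega, seed_mass=0.0,
                invasion_flux=flux, seed_rng=_rng_seed(),
                nucleation_onset_s=30_000.0 if omega == 6.9 else 8000.0,
                effective_area_m2=0.02,
            )
        )
    for water in ("artificial", "natural"):
        for asp in (0.0, 0.001, 0.01, 0.1, 1.0, 8.7):
            if asp == 0.0:
                mod, broad = 1.0, 0.0
            elif asp <= 0.01:
                mod, broad = 1.2, 0.0
            elif asp < 1.0:
                mod, broad = 1.0, 0.0
            else:
                mod, broad = 0.55, 1.0
            specs.append(
                ScenarioSpec(
                    water=water, omega=11.2, seed_mass=200.0,
                    aspartic_mM=asp, rate_modifier=mod,
                    raman=RamanSpec(fwhm_mean=1.8 + broad),
                    seed_rng=_rng_seed(),
                )
            )
    return specs
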