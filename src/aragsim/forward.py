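"""Forward model of the constant-composition (pH-stat) titration.

The simulator converts a surface-normalised precipitation rate R
(μmol m⁻² h⁻¹) into the cumulative titrant-dosing profile the pH-stat
would record.  Per time step Δt the seed of current area A precipitates
R·A·Δt μmol of CaCO3; the titrator replaces the consumed ions with an
equal volume of each 0.6 M titrant (Na2CO3 and CaCl2/SrCl2), so the
volume increment per titrant is moles/molarity.  The deposit grows the
seed epitaxially, enlarging A, which is why low-seed-mass profiles curve
upward while high-seed-mass profiles stay nearly linear.

CO2 invasion triggers additional dosing without precipitation; a lag
period suppresses growth (nucleation delay) while invasion-driven dosing
continues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .carbchem import SeawaterState
from .seedgeom import CACO3_MOLAR_MASS, SeedPopulation

__all__ = [
    "ExperimentConfig",
    "DosingProfile",
    "NonTerminationError",
    "simulate_profile",
    "profile_shape_index",
    "dose_to_mass",
]


class NonTerminationError(RuntimeError):
    """The simulation step budget ran out before the dose target was reached.

    Carries the partial :class:`DosingProfile` as ``partial_profile``.
    """

    def __init__(self, message: str, partial_profile: "DosingProfile"):
        super().__init__(message)
        self.partial_profile = partial_profile


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one pH-stat precipitation run.

    Parameters
    ----------
    seed : SeedPopulation or None
        Starting seed; ``None`` represents an unseeded run (which the
        forward model refuses to simulate without an explicit effective
        area — unseeded nucleation is not modelled).
    rate : float
        Surface-normalised precipitation rate, μmol m⁻² h⁻¹.
    titrant_molarity : float
        mol L⁻¹ of each titrant (equal volumes are dosed).
    target_dose : float
        Stop once this cumulative volume (mL) of each titrant has dosed.
    time_step : float
        Simulation step, s (1–60 s; smaller seed masses need smaller steps).
    lag : float
        Nucleation lag, s: no growth before ``lag``.
    invasion_flux : float
        CO2-invasion DIC flux, μmol kg⁻¹ h⁻¹; drives dosing without growth.
    solution : SeawaterState
        The precipitating solution (mass used for the invasion term).
    seed_addition_delay : float
        s; time taken to add the seed at t=0, below which lags are
        experimentally unidentifiable.
    max_steps : int
        Step budget before :class:`NonTerminationError` is raised.
    """

    seed: SeedPopulation | None
    rate: float
    titrant_molarity: float = 0.6
    target_dose: float = 5.0
    time_step: float = 10.0
    lag: float = 0.0
    invasion_flux: float = 0.0
    solution: SeawaterState = field(default_factory=SeawaterState)
    seed_addition_delay: float = 90.0
    max_steps: int = 2_000_000

    def __post_init__(self) -> None:
        if self.rate < 0.0:
            raise ValueError("rate must be non-negative")
        if not 1.0 <= self.time_step <= 60.0:
            raise ValueError("time_step must lie in [1, 60] s")
        if self.target_dose <= 0.0:
            raise ValueError("target_dose must be positive")
        if self.lag < 0.0 or self.invasion_flux < 0.0:
            raise ValueError("lag and invasion_flux must be non-negative")


@dataclass
class DosingProfile:
    """Cumulative titrant volume (mL per titrant) versus time (s).

    Starts at (0, 0); both series are monotone non-decreasing.
    ``metadata`` records provenance (config, seed mass, water type,
    generating truth for synthetic data).
    """

    times: np.ndarray
    cumulative_volume: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_volume = np.asarray(self.cumulative_volume, dtype=float)
        if self.times.shape != self.cumulative_volume.shape:
            raise ValueError("times and cumulative_volume must have equal length")
        if self.times.size < 1:
            raise ValueError("profile must contain at least one point")
        if np.any(np.diff(self.times) < 0.0):
            raise ValueError("times must be non-decreasing")
        if np.any(np.diff(self.cumulative_volume) < -1e-12):
            raise ValueError("cumulative volume must be non-decreasing")
        if self.cumulative_volume[0] < 0.0:
            raise ValueError("cumulative volume must be non-negative")

    def __len__(self) -> int:
        return self.times.size

    @property
    def max_volume(self) -> float:
        return float(self.cumulative_volume[-1])

    @property
    def duration(self) -> float:
        """Total duration, s."""
        return float(self.times[-1])

    def time_at_volume(self, volume: float) -> float:
        """First time (s) at which the cumulative volume reaches ``volume`` mL."""
        if volume > self.max_volume:
            raise ValueError(
                f"profile reaches only {self.max_volume:.3f} mL (< {volume} mL)"
            )
        idx = int(np.searchsorted(self.cumulative_volume, volume, side="left"))
        if idx == 0:
            return float(self.times[0])
        v0, v1 = self.cumulative_volume[idx - 1], self.cumulative_volume[idx]
        t0, t1 = self.times[idx - 1], self.times[idx]
        if v1 == v0:
            return float(t1)
        return float(t0 + (volume - v0) * (t1 - t0) / (v1 - v0))

    def volume_at_time(self, t: np.ndarray | float) -> np.ndarray | float:
        """Cumulative volume (mL) at time(s) ``t`` by linear interpolation."""
        return np.interp(t, self.times, self.cumulative_volume)

    def shifted(self, lag: float) -> "DosingProfile":
        """Profile delayed by ``lag`` s (prepending the flat segment)."""
        if lag <= 0.0:
            return self
        times = np.concatenate(([0.0], self.times + lag))
        vol = np.concatenate(([self.cumulative_volume[0]], self.cumulative_volume))
        meta = dict(self.metadata)
        meta["applied_lag_s"] = lag
        return DosingProfile(times, vol, meta)

    # -- plain-text round trip ------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write 2-column CSV (time_s, cumulative_mL) + JSON metadata sidecar."""
        path = Path(path)
        arr = np.column_stack([self.times, self.cumulative_volume])
        np.savetxt(
            path, arr, fmt="%.6f", delimiter=",", header="time_s,cumulative_mL",
            comments="",
        )
        if self.metadata:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DosingProfile":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta: dict[str, Any] = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(arr[:, 0], arr[:, 1], meta)


def _invasion_dose_rate_mL_s(config: ExperimentConfig) -> float:
    """Invasion-driven dosing rate per titrant, mL s⁻¹.

    CO2 invasion lowers pH and the controller doses BOTH titrants as a
    pair; the DIC flux is mapped to Na2CO3-equivalent moles split 50/50
    across the pair (recorded convention):
        dV/dt = F·m / (2·M) with F in μmol kg⁻¹ h⁻¹, m in kg, M in mol L⁻¹.
    """
    if config.invasion_flux == 0.0:
        return 0.0
    umol_per_h = config.invasion_flux * config.solution.solution_mass
    mL_per_h = umol_per_h / (2.0 * config.titrant_molarity * 1000.0)
    return mL_per_h / 3600.0


def simulate_profile(config: ExperimentConfig) -> DosingProfile:
    """Run the time-stepped forward model; returns the dosing profile.

    Per step: moles = rate × area × Δt (zero before the lag elapses);
    volume increment per titrant = moles/molarity; the seed grows
    epitaxially by the precipitated moles.  Invasion-driven dosing adds
    volume without growth.  Stops when the cumulative volume reaches
    ``target_dose``; raises :class:`NonTerminationError` (with the
    partial profile attached) if the step budget runs out first.
    """
    if config.seed is None:
        raise ValueError(
            "unseeded simulation requires an explicit effective-area model; "
            "provide a SeedPopulation"
        )
    pop = config.seed
    dt = config.time_step
    dt_h = dt / 3600.0
    umol_per_mL = config.titrant_molarity * 1000.0
    inv_rate = _invasion_dose_rate_mL_s(config)

    # growth state kept as plain floats for speed; cubes scale self-similarly
    # so area(t) = area0 * (mass/mass0)^(2/3)
    mass0 = pop.mass
    area0 = pop.total_area
    mass = mass0
    grown_umol_total = 0.0

    times = [0.0]
    volumes = [0.0]
    t = 0.0
    vol = 0.0
    g_per_umol = CACO3_MOLAR_MASS * 1e-6

    for _ in range(config.max_steps):
        t += dt
        if t > config.lag:
            # fraction of this step past the lag boundary
            frac = min(1.0, (t - config.lag) / dt)
            area = area0 * (mass / mass0) ** (2.0 / 3.0)
            grown = config.rate * area * dt_h * frac  # μmol
        else:
            grown = 0.0
        vol += grown / umol_per_mL
        vol += inv_rate * dt
        mass += grown * g_per_umol
        grown_umol_total += grown
        times.append(t)
        volumes.append(vol)
        if vol >= config.target_dose:
            break
    else:
        partial = DosingProfile(
            np.array(times), np.array(volumes),
            {"terminated": False, "steps": config.max_steps},
        )
        raise NonTerminationError(
            f"dose target {config.target_dose} mL not reached after "
            f"{config.max_steps} steps (rate={config.rate}, "
            f"invasion_flux={config.invasion_flux})",
            partial,
        )

    meta = {
        "terminated": True,
        "rate_umol_m2_h": config.rate,
        "seed_mass_g": mass0,
        "seed_area_m2": area0,
        "final_mass_g": mass,
        "grown_umol": grown_umol_total,
        "titrant_molarity_M": config.titrant_molarity,
        "target_dose_mL": config.target_dose,
        "time_step_s": dt,
        "lag_s": config.lag,
        "invasion_flux_umol_kg_h": config.invasion_flux,
        "invasion_split_convention": "50/50 across the titrant pair",
    }
    return DosingProfile(np.array(times), np.array(volumes), meta)


def grown_population(config: ExperimentConfig, profile: DosingProfile) -> SeedPopulation:
    """Seed population after the run described by ``profile``.

    Growth moles = dosed moles minus the invasion-attributed dosing.
    """
    if config.seed is None:
        raise ValueError("no seed in config")
    grown = profile.metadata.get("grown_umol")
    if grown is None:
        dosed_umol = profile.max_volume * config.titrant_molarity * 1000.0
        inv_umol = (
            _invasion_dose_rate_mL_s(config) * profile.duration
            * config.titrant_molarity * 1000.0
        )
        grown = max(0.0, dosed_umol - inv_umol)
    from .seedgeom import grow_epitaxial

    return grow_epitaxial(config.seed, grown)


def profile_shape_index(profile: DosingProfile) -> float:
    """Curvature of a dosing profile: 1 − r² of a straight-line fit.

    0 for a perfectly linear profile; larger values mean more curvature
    (low seed mass / strong area growth).  Requires ≥ 10 points.
    """
    if len(profile) < 10:
        raise ValueError("profile_shape_index requires at least 10 points")
    t = profile.times
    v = profile.cumulative_volume
    vbar = v.mean()
    ss_tot = float(np.sum((v - vbar) ** 2))
    if ss_tot == 0.0:
        return 0.0
    slope, intercept = np.polyfit(t, v, 1)
    ss_res = float(np.sum((v - (slope * t + intercept)) ** 2))
    return max(0.0, ss_res / ss_tot)


def dose_to_mass(volume: float, molarity: float = 0.6) -> float:
    """CaCO3 mass (mg) precipitated for ``volume`` mL of each titrant dosed.

    mass = V·M·100.09  (mL × mol L⁻¹ = mmol; × molar mass = mg).
    """
    if volume < 0.0:
        raise ValueError("volume must be non-negative")
    return volume * molarity * CACO3_MOLAR_MASS
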