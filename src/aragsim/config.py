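"""Run configuration: schema-validated YAML/JSON, unknown keys rejected."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthdata import NoiseSpec, RamanSpec, ScenarioSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NoiseConfig(_Strict):
    dose_quantum_uL: float = 2.0
    timing_jitter_s: float = 2.0
    multiplicative_sd: float = 0.01
    rate_rel_sd: float = 0.04

    def to_spec(self) -> NoiseSpec:
        return NoiseSpec(**self.model_dump())


class RamanGroupConfig(_Strict):
    fwhm_mean: float = 1.8
    fwhm_sd: float = 0.15
    center_mean: float = 1084.3
    center_sd: float = 0.05
    n_spectra: int = 10
    noise_sd_frac: float = 0.01

    def to_spec(self) -> RamanSpec:
        return RamanSpec(**self.model_dump())


class FitConfig(_Strict):
    window_mL: Optional[tuple[float, float]] = None
    with_lag: bool = True
    rate_bounds: tuple[float, float] = (1.0, 1e4)


class ApparatusConfig(_Strict):
    beaker_diameter_mm: float = 73.0
    fill_depth_cm: float = 8.2
    cylinders: list[tuple[float, float, int]] = Field(
        default_factory=lambda: [(12.0, 6.0, 1), (15.0, 7.5, 1), (2.0, 7.5, 2)]
    )


class RunConfig(_Strict):
    """Flat per-run configuration driving :func:`aragsim.pipeline.run_pipeline`."""

    run_name: str = "run"
    seed: int = 0
    out_dir: str = "aragsim_out"
    water: Literal["artificial", "natural"] = "artificial"
    omega: float = 11.3
    seed_mass_mg: float = 200.0
    target_dose_mL: float = 5.0
    true_rate: Optional[float] = None
    lag_s: Optional[float] = None
    invasion_flux: float = 0.0
    n_replicates: int = 2
    constants_set: Literal["mehrbach_dm87", "lueker2000"] = "mehrbach_dm87"
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    raman_groups: dict[str, RamanGroupConfig] = Field(default_factory=dict)
    fit: FitConfig = Field(default_factory=FitConfig)
    apparatus: ApparatusConfig = Field(default_factory=ApparatusConfig)
    verbosity: int = 1

    # -- serialisation ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data or {})

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(
            json.loads(self.model_dump_json()), sort_keys=True
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    def content_hash(self) -> str:
        """sha256 of the canonical JSON serialisation (provenance)."""
        canon = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def scenario(self) -> ScenarioSpec:
        return ScenarioSpec(
            water=self.water,
            omega=self.omega,
            seed_mass=self.seed_mass_mg,
            true_rate=self.true_rate,
            lag=self.lag_s,
            invasion_flux=self.invasion_flux,
            target_dose=self.target_dose_mL,
            noise=self.noise.to_spec(),
            seed_rng=self.seed,
        )
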