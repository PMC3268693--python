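"""Run configuration: schema-validated YAML/JSON config files.

Unknown keys are rejected so typos fail loudly.  The config maps directly
onto the domain objects: beam + crystal feed the dose model, the
characterization section feeds protocol generation, and the simulation
section defines the synthetic ground truth and noise regime.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .dose import BeamParameters, BeamProfile, Composition, CrystalDescription, default_composition
from .protocol import CharacterizationInput
from .sim import DamageTruth, WilsonModel

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BeamConfig(_Strict):
    flux: float = 6.2e11
    energy_keV: float = 12.76
    fwhm_h_um: float = 45.0
    fwhm_v_um: float = 35.0
    profile: Literal["gaussian", "uniform"] = "gaussian"

    def to_beam(self) -> BeamParameters:
        return BeamParameters(
            flux=self.flux,
            energy=self.energy_keV,
            fwhm_h=self.fwhm_h_um,
            fwhm_v=self.fwhm_v_um,
            profile=BeamProfile(self.profile),
        )


class CompositionConfig(_Strict):
    solvent_fraction: float = 0.47
    sulfur_per_residue: float = 0.05
    solvent_sulfur_mM: float = 300.0
    extra_elements_mM: dict[str, float] = Field(default_factory=dict)

    def to_composition(self) -> Composition:
        return Composition.from_crystal(
            solvent_fraction=self.solvent_fraction,
            sulfur_per_residue=self.sulfur_per_residue,
            solvent_sulfur_mM=self.solvent_sulfur_mM,
            extra_elements_mM=self.extra_elements_mM,
        )


class CrystalConfig(_Strict):
    size_um: tuple[float, float, float] = (300.0, 50.0, 50.0)
    composition: Literal["default"] | CompositionConfig = "default"

    def to_crystal(self) -> CrystalDescription:
        comp = (
            default_composition()
            if self.composition == "default"
            else self.composition.to_composition()
        )
        return CrystalDescription(*self.size_um, composition=comp)


class CharacterizationConfig(_Strict):
    B0: float = 15.0
    scale0: float = 1.0
    d_min: float = 2.0
    n_shells: int = 10
    gain_per_mgy: float = 2500.0
    mosaicity: float = 0.5
    min_exposure_s: float = 0.02
    max_rotation_speed: float = 10.0
    transmission_min: float = 1e-3
    transmission_max: float = 1.0
    center_angle: float = 0.0
    rotation_range: float = 4.0
    assumed_beta: float = 1.0
    background_var: float = 0.0

    def to_wilson(self) -> WilsonModel:
        return WilsonModel.from_resolution(
            B0=self.B0, scale0=self.scale0, d_min=self.d_min, n_shells=self.n_shells
        )

    def to_characterization(self, dose_rate: float) -> CharacterizationInput:
        return CharacterizationInput(
            dose_rate=dose_rate,
            wilson=self.to_wilson(),
            gain_per_mgy=self.gain_per_mgy,
            mosaicity=self.mosaicity,
            min_exposure_s=self.min_exposure_s,
            max_rotation_speed=self.max_rotation_speed,
            transmission_range=(self.transmission_min, self.transmission_max),
            center_angle=self.center_angle,
            rotation_range=self.rotation_range,
            assumed_beta=self.assumed_beta,
            background_var=self.background_var,
        )


class SimulationConfig(_Strict):
    beta_true: float = 1.0
    scale_drift: float = 0.0
    n_per_shell: int = 100
    target_snr: float = 5.0
    background_var: float = 0.0
    noiseless: bool = False

    def to_truth(self) -> DamageTruth:
        return DamageTruth(beta_true=self.beta_true, scale_drift=self.scale_drift)


class FitConfig(_Strict):
    n_shells: int = 10
    weighted: bool = True


class RunConfig(_Strict):
    seed: int = 0
    beam: BeamConfig = Field(default_factory=BeamConfig)
    crystal: CrystalConfig = Field(default_factory=CrystalConfig)
    characterization: CharacterizationConfig = Field(default_factory=CharacterizationConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    fit: FitConfig = Field(default_factory=FitConfig)

    @field_validator("seed")
    @classmethod
    def _seed_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be >= 0")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
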