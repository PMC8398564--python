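"""YAML configuration schemas and conversion to domain objects.

Units are embedded in key names (``dose_mg``, ``infusion_min``, ...) so a
config file is self-documenting.  Validation is handled by pydantic; every
CLI entry point loads its inputs through these models.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .drugs import DrugSubstance
from .transit import DeviceGeometry, DisintegrationModel, Formulation, Protocol


class DrugConfig(BaseModel):
    name: str
    base_pkas: list[float] = Field(default_factory=list)
    intrinsic_solubility_mg_ml: float = Field(gt=0)
    molar_mass_g_mol: float = Field(gt=0)
    chloride_ksp_M2: Optional[float] = Field(default=None, gt=0)
    permeation_coefficient_cm_min: float = Field(default=0.0, ge=0)
    precipitation_rate_per_min: float = Field(default=0.0, ge=0)

    def to_domain(self) -> DrugSubstance:
        return DrugSubstance(
            name=self.name,
            base_pkas=tuple(sorted(self.base_pkas, reverse=True)),
            intrinsic_solubility=self.intrinsic_solubility_mg_ml,
            molar_mass=self.molar_mass_g_mol,
            chloride_ksp=self.chloride_ksp_M2,
            permeation_coefficient=self.permeation_coefficient_cm_min,
            precipitation_rate=self.precipitation_rate_per_min,
        )


class DisintegrationConfig(BaseModel):
    tau_100rpm_min: dict[str, float]
    rpm_exponent: dict[str, float] = Field(default_factory=dict)

    def to_domain(self) -> DisintegrationModel:
        return DisintegrationModel(
            tau_ref=self.tau_100rpm_min, rpm_exponent=self.rpm_exponent
        )


class FormulationConfig(BaseModel):
    label: str
    dose_mg: float = Field(gt=0)
    disintegration: DisintegrationConfig
    k_ref_per_min: float = Field(gt=0)
    k_rpm_exponent: float = 0.0
    role: Literal["reference", "test"] = "test"

    def to_domain(self) -> Formulation:
        return Formulation(
            label=self.label,
            dose=self.dose_mg,
            disintegration=self.disintegration.to_domain(),
            k_ref=self.k_ref_per_min,
            k_rpm_exponent=self.k_rpm_exponent,
            role=self.role,
        )


class ProtocolConfig(BaseModel):
    initial_gastric_ph: float = 1.6
    infusion_min: float = Field(default=10.0, gt=0)
    paddle_rpm: float = Field(default=100.0, gt=0)
    water_disintegration: bool = False
    gastric_hold_min: float = Field(default=1.0, ge=0)
    run_length_min: float = Field(default=120.0, gt=0)
    sampling_times_min: Optional[list[float]] = None
    sample_volume_ml: float = Field(default=0.0, ge=0)

    def to_domain(self) -> Protocol:
        kwargs = self.model_dump(exclude={"sampling_times_min"})
        if self.sampling_times_min is not None:
            kwargs["sampling_times"] = tuple(self.sampling_times_min)
        return Protocol(**kwargs)


class GeometryConfig(BaseModel):
    gastric_volume_ml: float = 40.0
    final_volume_ml: float = 100.0
    infusate_volume_ml: float = 60.0
    receiver_final_volume_ml: float = 30.0
    filter_area_max_cm2: float = 6.60
    water_phase_volume_ml: float = 37.5

    def to_domain(self) -> DeviceGeometry:
        return DeviceGeometry(
            gastric_volume=self.gastric_volume_ml,
            final_volume=self.final_volume_ml,
            infusate_volume=self.infusate_volume_ml,
            receiver_final_volume=self.receiver_final_volume_ml,
            filter_area_max=self.filter_area_max_cm2,
            water_phase_volume=self.water_phase_volume_ml,
        )


_MODELS = {
    "drug": DrugConfig,
    "formulation": FormulationConfig,
    "protocol": ProtocolConfig,
    "geometry": GeometryConfig,
}


def load_config(path: str | Path, kind: str):
    """Load and validate one YAML config, returning the domain object."""
    if kind not in _MODELS:
        raise KeyError(f"unknown config kind {kind!r}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ValueError(f"{path}: empty config")
    model = _MODELS[kind].model_validate(raw)
    return model.to_domain()
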