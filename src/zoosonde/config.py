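"""Pipeline configuration: schema-validated, YAML-loadable.

Defaults are the survey-processing settings of the method: 3 pings x
1 m cells integrated at -80 dB, a -119 dB fish gate on the dB sum,
2/7/25 dB difference windows with a -65 dB upper threshold, fluid-sphere
contrasts g = 1.02 / h = 1.058 at 1508 m/s, 0.001 nmi ESUs, a 0.05
degree kriging grid, and an 18 degree solar-altitude transition band.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator

from .classify import ClassifierConfig
from .scattering import FluidSphereParams, sound_speed
from .zooscan import AllometricModel

__all__ = ["PipelineConfig"]


class CellConfig(BaseModel):
    pings_per_cell: int = Field(3, ge=1)
    meters_per_cell: float = Field(1.0, gt=0)
    integration_threshold_db: float = -80.0


class ClassifierSettings(BaseModel):
    fish_sum_threshold_db: float = -119.0
    delta_other_max_db: float = 2.0
    delta_krill_max_db: float = 7.0
    delta_copepod_max_db: float = 25.0
    upper_mvbs_threshold_db: float = -65.0
    rescue_window: int = 3
    fit_fish_threshold: bool = False

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.delta_other_max_db < self.delta_krill_max_db < self.delta_copepod_max_db):
            raise ValueError("delta windows must satisfy other < krill < copepod")
        return self

    def to_classifier(self, fitted_threshold: float | None = None) -> ClassifierConfig:
        return ClassifierConfig(
            fish_sum_threshold_db=(
                fitted_threshold if fitted_threshold is not None else self.fish_sum_threshold_db
            ),
            delta_other_max_db=self.delta_other_max_db,
            delta_krill_max_db=self.delta_krill_max_db,
            delta_copepod_max_db=self.delta_copepod_max_db,
            upper_mvbs_threshold_db=self.upper_mvbs_threshold_db,
            rescue_window=self.rescue_window,
        )


class ScatteringConfig(BaseModel):
    g: float = 1.02
    h: float = 1.058
    sound_speed_ms: float | None = 1508.0
    temperature_c: float | None = None
    salinity_psu: float | None = None
    depth_m: float = 50.0
    f_low_khz: float = 38.0
    f_high_khz: float = 120.0
    band_delta_db: tuple[float, float] = (7.0, 19.7)  # (low, high)

    @model_validator(mode="after")
    def _speed_source(self):
        if self.sound_speed_ms is None and (
            self.temperature_c is None or self.salinity_psu is None
        ):
            raise ValueError("give sound_speed_ms or temperature_c + salinity_psu")
        if self.band_delta_db[0] >= self.band_delta_db[1]:
            raise ValueError("band_delta_db must be (low, high)")
        return self

    def to_params(self) -> FluidSphereParams:
        c = self.sound_speed_ms
        if c is None:
            c = sound_speed(self.temperature_c, self.salinity_psu, self.depth_m)
        return FluidSphereParams(
            g=self.g, h=self.h, c=c, f_low_khz=self.f_low_khz, f_high_khz=self.f_high_khz
        )


class InversionConfig(BaseModel):
    frequency_khz: float = 120.0
    esu_length_nmi: float = Field(0.001, gt=0)
    dm_mean_ug: float = Field(217.0, gt=0)
    dm_intercept: float = Field(45.25, gt=0)
    dm_exponent: float = Field(1.59, gt=0)
    esr_net_min_mm: float = 0.5

    def allometry(self) -> AllometricModel:
        return AllometricModel(self.dm_intercept, self.dm_exponent)


class KrigingConfig(BaseModel):
    grid_step_deg: float = Field(0.05, gt=0)
    model: str = "spherical"
    n_neighbors: int = Field(16, ge=1)
    n_bins: int = Field(12, ge=4)


class PipelineConfig(BaseModel):
    cells: CellConfig = Field(default_factory=CellConfig)
    classifier: ClassifierSettings = Field(default_factory=ClassifierSettings)
    scattering: ScatteringConfig = Field(default_factory=ScatteringConfig)
    inversion: InversionConfig = Field(default_factory=InversionConfig)
    kriging: KrigingConfig = Field(default_factory=KrigingConfig)
    diel_band_deg: float = 18.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
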