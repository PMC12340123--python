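"""Schema-validated run configuration.

A single JSON document drives every CLI stage; unknown fields are rejected so
typos fail loudly, and every run writes its fully resolved configuration next
to its outputs for reproducibility.  Defaults match the reference operating
point: 80/81 tones over 63–88 MHz inside the 61–91 MHz device band, 50 MSa/s,
1 ms frames.
"""

from __future__ import annotations

import json

from pydantic import BaseModel, ConfigDict, Field

from .comb_design import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_DC_GUARD,
    DEFAULT_DEVICE_BAND,
    build_comb,
    build_spectral_map,
)
from .fileio import atomic_write_text
from .forward_sim import AcquisitionConfig
from .metrics import OpticsConfig


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CombConfig(_Model):
    start_hz: float
    spacing_hz: float
    offset_hz: float = 0.0


class DesignConfig(_Model):
    device_band_low_hz: float = DEFAULT_DEVICE_BAND[0]
    device_band_high_hz: float = DEFAULT_DEVICE_BAND[1]
    comb_band_low_hz: float = 63e6
    x_band_high_hz: float = 87.6e6
    y_band_high_hz: float = 88e6
    x: CombConfig = Field(default_factory=lambda: CombConfig(start_hz=63e6, spacing_hz=311e3))
    y: CombConfig = Field(
        default_factory=lambda: CombConfig(start_hz=63e6, spacing_hz=310e3, offset_hz=141e3)
    )
    f0_hz: float = 0.0
    grid_hz: float = DEFAULT_BIN_WIDTH
    dc_guard_hz: float = DEFAULT_DC_GUARD

    def build_map(self, bin_width: float | None = None):
        device = (self.device_band_low_hz, self.device_band_high_hz)
        comb_x = build_comb(
            self.x.start_hz, self.x_band_high_hz, self.x.spacing_hz,
            offset=self.x.offset_hz, grid=self.grid_hz, axis="x", device_band=device,
        )
        comb_y = build_comb(
            self.y.start_hz, self.y_band_high_hz, self.y.spacing_hz,
            offset=self.y.offset_hz, grid=self.grid_hz, axis="y", device_band=device,
        )
        return build_spectral_map(
            comb_x, comb_y, f0=self.f0_hz,
            bin_width=self.grid_hz if bin_width is None else bin_width,
        )


class AcquisitionModel(_Model):
    sampling_rate_hz: float = 50e6
    frame_duration_s: float = 1e-3
    n_frames: int = 1
    reference_amplitude: float = 100.0
    signal_amplitude: float = 1.0
    residual_1d_amplitude: float = 0.1
    noise_sigma: float = 0.0
    shot_noise: bool = False
    bit_depth: int = 0
    full_scale: float = 1.0
    seed: int = 0
    include_cross_terms: bool = True

    def to_acquisition(self, n_frames: int | None = None) -> AcquisitionConfig:
        return AcquisitionConfig(
            sampling_rate=self.sampling_rate_hz,
            frame_duration=self.frame_duration_s,
            n_frames=self.n_frames if n_frames is None else n_frames,
            E_R=self.reference_amplitude,
            E_S=self.signal_amplitude,
            E_1D=self.residual_1d_amplitude,
            noise_sigma=self.noise_sigma,
            shot_noise=self.shot_noise,
            bit_depth=self.bit_depth,
            full_scale=self.full_scale,
            rng_seed=self.seed,
        )


class OpticsModel(_Model):
    wavelength_m: float = 1030e-9
    objective_focal_m: float = 7.5e-3
    acoustic_velocity_m_s: float = 650.0
    beam_diameter_m: float = 5e-3
    comb_span_hz: float = 25e6
    tones_per_axis: int = 80

    def to_optics(self) -> OpticsConfig:
        return OpticsConfig(
            wavelength=self.wavelength_m,
            objective_focal=self.objective_focal_m,
            acoustic_velocity=self.acoustic_velocity_m_s,
            beam_diameter=self.beam_diameter_m,
            comb_span=self.comb_span_hz,
            tones_per_axis=self.tones_per_axis,
        )


class RunConfig(_Model):
    design: DesignConfig = Field(default_factory=DesignConfig)
    acquisition: AcquisitionModel = Field(default_factory=AcquisitionModel)
    optics: OpticsModel = Field(default_factory=OpticsModel)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def write_resolved(self, path) -> None:
        atomic_write_text(path, self.model_dump_json(indent=1))
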