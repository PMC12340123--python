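"""Synthetic complex-field scenes: resolution bars, phase droplets, dynamics.

These generators stand in for the physical targets a complex-field microscope
is pointed at — a three-bar resolution element (amplitude contrast), oil/water
droplets (transparent pure-phase objects), and a diffusing mixing boundary —
so every pipeline stage is testable without experimental data.  All
generators are deterministic under their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

from .forward_sim import ComplexField


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    return np.pi - np.mod(np.pi - phase, 2 * np.pi)


@dataclass
class SceneSequence:
    """An ordered set of complex-field frames with timestamps."""

    frames: list
    timestamps: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.frames) != self.timestamps.size:
            raise ValueError("frames and timestamps lengths differ")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must share one shape")

    def __len__(self) -> int:
        return len(self.frames)


def bar_target(
    nx: int,
    ny: int,
    bar_width_px: int,
    orientation: str = "horizontal",
    contrast: float = 1.0,
) -> ComplexField:
    """A three-bar resolution element (bar chart style): three dark bars of
    width = gap = ``bar_width_px`` and length 5× the width, centered on a
    unit-amplitude background.  Bars have amplitude ``1 − contrast``; phase is
    zero everywhere.

    ``orientation="horizontal"`` lays the bars' long axis along x (stacked in
    y, so a vertical profile crosses three dips); ``"vertical"`` is the
    transpose.
    """
    if bar_width_px < 1:
        raise ValueError("bar_width_px must be >= 1")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must be in [0, 1]")
    if orientation not in ("horizontal", "vertical"):
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    w = bar_width_px
    block = 5 * w  # 3 bars + 2 gaps across; bar length 5w along
    if block > nx or block > ny:
        raise ValueError(f"bar pattern ({block}x{block} px) larger than frame ({nx}x{ny})")

    amp = np.ones((ny, nx))
    y0 = (ny - block) // 2
    x0 = (nx - block) // 2
    for k in range(3):
        if orientation == "horizontal":
            r = y0 + 2 * k * w
            amp[r : r + w, x0 : x0 + block] = 1.0 - contrast
        else:
            c = x0 + 2 * k * w
            amp[y0 : y0 + block, c : c + w] = 1.0 - contrast
    return ComplexField(amp.astype(complex))


def phase_droplet_scene(
    nx: int,
    ny: int,
    droplets: Sequence[tuple[tuple[float, float], float, float]],
) -> ComplexField:
    """Transparent droplets as pure-phase objects on a unit-amplitude field.

    Each droplet ``((cx, cy), radius_px, peak_phase_rad)`` adds a
    spherical-cap phase profile ``peak·sqrt(max(0, 1 − r²/R²))`` (a spherical
    droplet of uniform refractive-index contrast); overlapping droplets sum,
    then the total is wrapped to (−π, π].
    """
    phase = np.zeros((ny, nx))
    yy, xx = np.mgrid[0:ny, 0:nx]
    for (cx, cy), radius, peak in droplets:
        if radius < 1:
            raise ValueError("droplet radius must be >= 1 px")
        r2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / radius**2
        phase += peak * np.sqrt(np.maximum(0.0, 1.0 - r2))
    return ComplexField.from_amp_phase(np.ones((ny, nx)), _wrap(phase))


def mixing_interface(
    nx: int,
    ny: int,
    phase_step: float = np.pi / 2,
    boundary_x: float | None = None,
    width_px: float = 2.0,
) -> ComplexField:
    """Two miscible solutions meeting at a lateral boundary: a pure-phase
    error-function ramp of height ``phase_step`` across ``x = boundary_x``,
    with ``width_px`` the diffusion width of the interface."""
    if boundary_x is None:
        boundary_x = nx / 2
    xx = np.arange(nx, dtype=float)
    ramp = 0.5 * phase_step * (1.0 + erf((xx - boundary_x) / max(width_px, 1e-9)))
    phase = np.broadcast_to(ramp, (ny, nx))
    return ComplexField.from_amp_phase(np.ones((ny, nx)), _wrap(phase))


def mixing_sequence(
    nx: int,
    ny: int,
    n_frames: int,
    frame_duration: float,
    phase_step: float = np.pi / 2,
    initial_width_px: float = 1.0,
    diffusion_px2_per_frame: float = 1.0,
) -> SceneSequence:
    """Mixing-boundary dynamics: the interface width grows diffusively as
    ``sqrt(w0² + D·k)`` with frame index k, blurring the phase contrast."""
    frames = [
        mixing_interface(
            nx, ny, phase_step=phase_step,
            width_px=float(np.sqrt(initial_width_px**2 + diffusion_px2_per_frame * k)),
        )
        for k in range(n_frames)
    ]
    return SceneSequence(
        frames=frames,
        timestamps=np.arange(n_frames) * frame_duration,
        metadata={
            "generator": "mixing_sequence",
            "phase_step_rad": phase_step,
            "initial_width_px": initial_width_px,
            "diffusion_px2_per_frame": diffusion_px2_per_frame,
        },
    )


def dynamic_sequence(
    base_generator: Callable[[], ComplexField],
    velocity_px_per_frame: tuple[float, float],
    n_frames: int,
    frame_duration: float,
    seed: int = 0,
) -> SceneSequence:
    """Translate the generated object by ``velocity`` (vx, vy) pixels per frame
    with periodic wrap-around; deterministic under ``seed``.

    The cumulative shift is rounded to whole pixels per frame, so after
    ``nx / vx`` frames the scene returns exactly to its start.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)  # reserved for stochastic generators
    del rng
    base = base_generator()
    vx, vy = velocity_px_per_frame
    frames = []
    for k in range(n_frames):
        sx = int(round(vx * k))
        sy = int(round(vy * k))
        frames.append(ComplexField(np.roll(base.data, shift=(sy, sx), axis=(0, 1))))
    return SceneSequence(
        frames=frames,
        timestamps=np.arange(n_frames) * frame_duration,
        metadata={
            "generator": "dynamic_sequence",
            "velocity_px_per_frame": [vx, vy],
            "seed": seed,
        },
    )
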