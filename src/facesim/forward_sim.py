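"""Forward model: from a complex-field object to the single-pixel detector trace.

The detector sees the squared magnitude of the coherent sum of the reference
carrier, the per-pixel frequency-shifted sub-beams weighted by the object, and
(optionally) the residual one-dimensional diffraction of the first deflector.
Everything is synthesized at baseband: the optical carrier (hundreds of THz)
drops out of the intensity, leaving only beat frequencies, which is exactly
what the photodetector reports.

Two synthesis paths are provided and must agree to floating-point precision:

``direct``
    evaluates ``I(t) = |E_R + E_S Σ O e^{i2π·beat·t}|² + |E_1D Σ e^{i2π f_x t}|²``.
    For grid-locked designs the fields are built by placing coefficients on
    exact DFT bins and inverse-FFT-ing, which is exact and fast even for the
    full 80×81 grid; off-grid tones fall back to chunked complex exponentials.
    The residual-1D branch is added incoherently (no reference×1D or
    signal×1D beats: those differences lie at the RF drive frequencies, far
    beyond the detection band).

``expanded``
    evaluates the term-by-term cosine expansion — DC terms, heterodyne signal
    beats ``2 E_S E_R A cos(2π·beat·t + φ)``, object–object cross beats
    ``2 E_S² A_i A_j cos(2πΔf t + φ_i − φ_j)`` and 1D–1D beats.  Cost grows
    with the square of the pixel count; it is the small-grid oracle for the
    direct path, not a production route.

Noise and digitization are applied separately by
:func:`apply_noise_and_digitize`, so noiseless traces stay exactly
reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .comb_design import SpectralMap
from .fileio import atomic_write_bytes, atomic_write_text

log = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi


@dataclass
class ComplexField:
    """A complex-valued object ``O = A·exp(iφ)`` on an ``(ny, nx)`` pixel grid.

    Stored as a single complex array; ``amplitude`` (>= 0) and ``phase``
    (wrapped to (−π, π]) are derived views, so the invariants hold by
    construction.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("field must be 2-D (ny, nx)")

    @classmethod
    def from_amp_phase(cls, amplitude, phase) -> "ComplexField":
        amplitude = np.asarray(amplitude, dtype=float)
        phase = np.asarray(phase, dtype=float)
        if amplitude.shape != phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if np.any(amplitude < 0):
            raise ValueError("amplitude must be nonnegative")
        return cls(amplitude * np.exp(1j * phase))

    @classmethod
    def flat(cls, nx: int, ny: int, amplitude: float = 1.0) -> "ComplexField":
        """A featureless unit scene, the input for null calibration."""
        return cls(np.full((ny, nx), complex(amplitude)))

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Detector/digitizer chain parameters.

    ``E_R`` is the reference-carrier amplitude (much stronger than the
    per-tone signal amplitude ``E_S``); ``E_1D`` scales the residual 1D
    diffraction comb (0 disables it).  ``bit_depth = 0`` means an ideal float
    detector; otherwise samples are scaled by ``full_scale`` and rounded to
    signed integer codes.  Noise is deterministic under ``rng_seed``.
    """

    sampling_rate: float = 50e6
    frame_duration: float = 1e-3
    n_frames: int = 1
    E_R: float = 100.0
    E_S: float = 1.0
    E_1D: float = 0.1
    noise_sigma: float = 0.0
    shot_noise: bool = False
    bit_depth: int = 0
    full_scale: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.frame_duration <= 0 or self.n_frames < 1:
            raise ValueError("sampling_rate, frame_duration and n_frames must be positive")
        if min(self.E_R, self.E_S, self.E_1D) < 0 or self.noise_sigma < 0:
            raise ValueError("amplitudes and noise_sigma must be nonnegative")
        if self.bit_depth < 0 or (self.bit_depth > 0 and self.full_scale <= 0):
            raise ValueError("invalid digitizer settings")

    @property
    def frame_samples(self) -> int:
        return int(round(self.sampling_rate * self.frame_duration))


@dataclass
class DetectorTrace:
    """Real-valued single-pixel time series at a fixed sampling rate."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("trace must be 1-D")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


def _is_grid_locked(freqs: np.ndarray, frame_duration: float, tol: float = 1e-6) -> bool:
    cycles = freqs * frame_duration
    return bool(np.all(np.abs(cycles - np.round(cycles)) < tol))


def _field_from_bins(coeffs: np.ndarray, bins: np.ndarray, n: int) -> np.ndarray:
    """Evaluate ``Σ c_k exp(i 2π bins_k j / n)`` for j = 0..n-1 via inverse FFT."""
    spec = np.zeros(n, dtype=complex)
    np.add.at(spec, np.mod(bins, n), coeffs)
    return np.fft.ifft(spec) * n


def _field_chunked(coeffs: np.ndarray, freqs: np.ndarray, t: np.ndarray) -> np.ndarray:
    out = np.zeros(t.size, dtype=complex)
    chunk = max(1, int(2e6 // max(t.size, 1)) or 1)
    for i in range(0, coeffs.size, chunk):
        out += coeffs[i : i + chunk] @ np.exp(
            1j * _TWO_PI * freqs[i : i + chunk, None] * t[None, :]
        )
    return out


def synthesize_trace(
    obj: ComplexField,
    smap: SpectralMap,
    acq: AcquisitionConfig,
    mode: str = "direct",
    include_cross_terms: bool = True,
    gain: np.ndarray | None = None,
) -> DetectorTrace:
    """Synthesize the noiseless detector intensity for a static object.

    Parameters
    ----------
    mode : {"direct", "expanded"}
        ``direct`` squares the summed complex fields (the reference
        implementation); ``expanded`` sums the cosine expansion term by term
        (small grids only).
    include_cross_terms : bool
        When False the object–object and 1D–1D beats are omitted, leaving
        only the DC terms and the heterodyne signal beats: the linearized
        heterodyne regime.
    gain : complex array, optional
        Per-pixel complex system gain (tone-to-tone amplitude/phase
        variation); its effect is removable by null calibration.

    Noise and digitization are *not* applied here.
    """
    if obj.shape != smap.shape:
        raise ValueError(f"object shape {obj.shape} != map shape {smap.shape}")
    max_beat = float(np.max(np.abs(smap.beat)))
    if acq.sampling_rate <= 2 * max_beat:
        raise ValueError(
            f"sampling rate {acq.sampling_rate:.6g} Sa/s below Nyquist of the "
            f"largest beat ({max_beat:.6g} Hz)"
        )
    o = obj.data.copy()
    if gain is not None:
        gain = np.asarray(gain, dtype=complex)
        if gain.shape != o.shape:
            raise ValueError("gain table shape mismatch")
        o = o * gain

    n_frame = acq.frame_samples
    n_total = n_frame * acq.n_frames
    beats = smap.beat.ravel()
    fx = smap.comb_x.tones

    if mode == "direct":
        locked = _is_grid_locked(beats, acq.frame_duration) and _is_grid_locked(
            fx, acq.frame_duration
        )
        if locked:
            coeffs = acq.E_S * o.ravel()
            bins = np.round(beats * acq.frame_duration).astype(np.int64)
            if include_cross_terms:
                e_sig = _field_from_bins(
                    np.concatenate(([acq.E_R], coeffs)),
                    np.concatenate(([0], bins)),
                    n_frame,
                )
                intensity = np.abs(e_sig) ** 2
            else:
                het = _field_from_bins(acq.E_R * coeffs, bins, n_frame)
                dc = acq.E_R**2 + acq.E_S**2 * float(np.sum(np.abs(o) ** 2))
                intensity = dc + 2.0 * het.real
            if acq.E_1D > 0:
                bins1 = np.round(-fx * acq.frame_duration).astype(np.int64)
                if include_cross_terms:
                    e1 = _field_from_bins(np.full(fx.size, acq.E_1D, dtype=complex), bins1, n_frame)
                    intensity = intensity + np.abs(e1) ** 2
                else:
                    intensity = intensity + fx.size * acq.E_1D**2
            samples = np.tile(intensity, acq.n_frames)
        else:
            log.info("off-grid tones: using chunked exponential synthesis")
            t = np.arange(n_total) / acq.sampling_rate
            e_sig = acq.E_R + _field_chunked(acq.E_S * o.ravel(), beats, t)
            if include_cross_terms:
                samples = np.abs(e_sig) ** 2
            else:
                het = _field_chunked(acq.E_R * acq.E_S * o.ravel(), beats, t)
                samples = (
                    acq.E_R**2 + acq.E_S**2 * float(np.sum(np.abs(o) ** 2)) + 2.0 * het.real
                )
            if acq.E_1D > 0:
                e1 = _field_chunked(np.full(fx.size, acq.E_1D, dtype=complex), -fx, t)
                if include_cross_terms:
                    samples = samples + np.abs(e1) ** 2
                else:
                    samples = samples + fx.size * acq.E_1D**2
    elif mode == "expanded":
        t = np.arange(n_total) / acq.sampling_rate
        amp = np.abs(o.ravel())
        ph = np.angle(o.ravel())
        dc = acq.E_R**2 + acq.E_S**2 * float(np.sum(amp**2))
        if acq.E_1D > 0:
            dc += fx.size * acq.E_1D**2
        samples = np.full(n_total, dc)
        # heterodyne signal beats
        for i in range(amp.size):
            samples += (2.0 * acq.E_S * acq.E_R * amp[i]) * np.cos(
                _TWO_PI * beats[i] * t + ph[i]
            )
        if include_cross_terms:
            iu, ju = np.triu_indices(amp.size, k=1)
            coeff = 2.0 * acq.E_S**2 * amp[iu] * amp[ju]
            dfreq = beats[iu] - beats[ju]
            dph = ph[iu] - ph[ju]
            chunk = max(1, int(5e6 // max(n_total, 1)) or 1)
            for s in range(0, iu.size, chunk):
                sl = slice(s, s + chunk)
                samples += coeff[sl] @ np.cos(
                    _TWO_PI * dfreq[sl, None] * t[None, :] + dph[sl, None]
                )
            if acq.E_1D > 0:
                i1, j1 = np.triu_indices(fx.size, k=1)
                d1 = fx[i1] - fx[j1]
                for s in range(0, i1.size, chunk):
                    sl = slice(s, s + chunk)
                    samples += (2.0 * acq.E_1D**2) * np.sum(
                        np.cos(_TWO_PI * d1[sl, None] * t[None, :]), axis=0
                    )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return DetectorTrace(samples=np.asarray(samples, dtype=float), sampling_rate=acq.sampling_rate)


def apply_noise_and_digitize(trace: DetectorTrace, acq: AcquisitionConfig) -> DetectorTrace:
    """Detector/digitizer realism: additive Gaussian noise, optional shot noise,
    optional integer quantization.

    Shot noise is modelled as zero-mean Gaussian with per-sample standard
    deviation ``sqrt(max(sample, 0))`` (the Gaussian limit of Poisson photon
    statistics at the analog output).  With ``bit_depth = b > 0`` samples are
    divided by ``full_scale`` and rounded to signed ``b``-bit codes; a
    saturation fraction above 1% is logged as a warning, not raised.
    Deterministic under ``acq.rng_seed``.
    """
    samples = np.asarray(trace.samples, dtype=float)
    rng = np.random.default_rng(acq.rng_seed)
    out = samples.copy()
    if acq.shot_noise:
        out = out + rng.standard_normal(out.size) * np.sqrt(np.maximum(samples, 0.0))
    if acq.noise_sigma > 0:
        out = out + rng.normal(0.0, acq.noise_sigma, out.size)
    if acq.bit_depth > 0:
        half = 2 ** (acq.bit_depth - 1)
        codes = np.round(out / acq.full_scale * half)
        saturated = np.count_nonzero((codes < -half) | (codes > half - 1))
        frac = saturated / codes.size
        if frac > 0.01:
            log.warning("digitizer saturation on %.2f%% of samples", 100 * frac)
        out = np.clip(codes, -half, half - 1).astype(np.int32)
    return replace(trace, samples=out)


def apply_phase_screen(obj: ComplexField, seed: int, strength: float) -> ComplexField:
    """Multiply the object by a static thin random phase screen.

    Each pixel gains ``exp(i·strength·u)`` with ``u ~ Uniform(−π, π]`` i.i.d.
    under ``seed``; amplitude is unchanged.  Because detection is a coherent
    per-tone sum, reconstructing through the screen and null-calibrating
    against the *same* screen recovers the unscreened object exactly (in the
    linear heterodyne regime).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-np.pi, np.pi, size=obj.shape)
    return ComplexField(obj.data * np.exp(1j * strength * u))


# ---------------------------------------------------------------------------
# Trace interchange format: raw little-endian binary + JSON sidecar header.

def write_trace(trace: DetectorTrace, path, meta: dict | None = None) -> None:
    """Write raw samples (int16 for digitized, float32 otherwise) plus a
    ``<path>.json`` sidecar with the acquisition metadata."""
    path = str(path)
    samples = np.asarray(trace.samples)
    if np.issubdtype(samples.dtype, np.integer):
        dtype = "<i2" if samples.min() >= -(2**15) and samples.max() < 2**15 else "<i4"
    else:
        dtype = "<f4"
    raw = samples.astype(dtype).tobytes()
    header = {
        "dtype": dtype,
        "n_samples": int(samples.size),
        "sampling_rate_hz": trace.sampling_rate,
        "start_time_s": trace.start_time,
    }
    if meta:
        header.update(meta)
    atomic_write_bytes(path, raw)
    atomic_write_text(path + ".json", json.dumps(header, indent=1))


def read_trace(path) -> tuple[DetectorTrace, dict]:
    """Read a trace written by :func:`write_trace`; returns (trace, header)."""
    path = str(path)
    try:
        with open(path + ".json") as fh:
            header = json.load(fh)
        dtype = header["dtype"]
        n = int(header["n_samples"])
        rate = float(header["sampling_rate_hz"])
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"missing or corrupt trace sidecar for {path}: {exc}") from exc
    raw = np.fromfile(path, dtype=np.dtype(dtype))
    if raw.size != n:
        raise ValueError(f"trace {path}: expected {n} samples, found {raw.size}")
    samples = raw if dtype.startswith("<i") else raw.astype(float)
    trace = DetectorTrace(
        samples=samples,
        sampling_rate=rate,
        start_time=float(header.get("start_time_s", 0.0)),
    )
    return trace, header
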