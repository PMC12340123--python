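"""Complex-field recovery from a detector trace by FFT demodulation.

Each pixel's complex value sits in one spectral bin at its known |beat|
frequency: the heterodyne term of the detected intensity is
``2 E_S E_R A cos(2π·beat·t + φ)``, so the one-sided spectrum (normalized as
DFT/length) reads ``E_S E_R A e^{iφ}`` at that bin — a direct, non-iterative
reconstruction.  Pixels whose signed beat is negative appear as the conjugate
twin and are conjugated on extraction.  Per-pixel system response (tone
amplitudes, phases, path lengths) is divided out with a calibration table
measured on a featureless flat scene ("null calibration").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .comb_design import SpectralMap
from .forward_sim import ComplexField, DetectorTrace

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Spectrum:
    """One-sided complex spectrum of a trace.

    Normalization: ``values = rfft(trace) / len(trace)``, so a pure on-grid
    cosine of amplitude C yields ``|values| = C/2`` at its bin and a constant
    trace c yields ``values[0] = c``.
    """

    values: np.ndarray
    bin_width: float

    @property
    def n_bins(self) -> int:
        return self.values.size


def fft_spectrum(trace: DetectorTrace, window: str = "rect") -> Spectrum:
    """One-sided spectrum of a trace.

    ``window="rect"`` is the default and is leakage-free for grid-locked
    designs.  ``window="hann"`` is offered for off-grid (e.g. externally
    recorded) traces; the amplitude scaling is corrected by the window's
    coherent gain so on-bin amplitudes remain comparable.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    if window == "rect":
        values = np.fft.rfft(x) / x.size
    elif window == "hann":
        w = hann(x.size, sym=False)
        values = np.fft.rfft(x * w) / (x.size * np.mean(w))
    else:
        raise ValueError(f"unknown window {window!r}")
    return Spectrum(values=values, bin_width=trace.sampling_rate / x.size)


@dataclass(frozen=True)
class CalibrationTable:
    """Per-pixel complex correction factors from a null (flat-scene) acquisition."""

    factors: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        factors = np.asarray(self.factors, dtype=complex)
        object.__setattr__(self, "factors", factors)
        if np.any(np.abs(factors) == 0):
            raise ValueError("calibration table contains zero factors")


def extract_field(
    spectrum: Spectrum,
    smap: SpectralMap,
    calib: CalibrationTable | None = None,
) -> ComplexField:
    """Read each pixel's spectral bin, conjugate negative-beat pixels, apply
    calibration.

    With a grid-locked design every |beat| lands on an exact bin; otherwise the
    nearest bin (within half a bin width) is used and logged.  Without
    calibration the result is proportional to ``E_S E_R O``.
    """
    frac = np.abs(smap.beat) / spectrum.bin_width
    idx = np.round(frac).astype(np.int64)
    dev = np.max(np.abs(frac - idx))
    if dev > 0.5 + 1e-9:
        raise ValueError("a beat frequency is more than half a bin from any FFT bin")
    if dev > 1e-6:
        log.info("off-grid beats: nearest-bin lookup, max deviation %.3g bins", dev)
    if idx.max() >= spectrum.n_bins:
        raise ValueError(
            f"beat bin {idx.max()} beyond the spectrum Nyquist ({spectrum.n_bins - 1} bins)"
        )
    vals = spectrum.values[idx]
    vals = np.where(smap.conjugate_flag, np.conj(vals), vals)
    if calib is not None:
        if calib.factors.shape != vals.shape:
            raise ValueError("calibration table shape does not match the map")
        vals = vals / calib.factors
    return ComplexField(vals)


def null_calibrate(
    flat_trace: DetectorTrace,
    smap: SpectralMap,
    window: str = "rect",
    eps: float = 1e-6,
    source: str = "null",
) -> CalibrationTable:
    """Build the calibration table from a flat (unit-amplitude, zero-phase)
    scene acquisition.

    The factors are the raw extracted complex values; extraction with this
    table maps the flat scene to exactly 1 everywhere.  Pixels whose factor
    magnitude falls below ``eps`` times the maximum are dead and raise.
    """
    raw = extract_field(fft_spectrum(flat_trace, window=window), smap)
    mags = np.abs(raw.data)
    dead = np.argwhere(mags < eps * mags.max())
    if dead.size:
        pixels = [(int(n), int(m)) for m, n in dead]  # (x index, y index)
        raise ValueError(f"dead pixels in null calibration (|factor| ~ 0): {pixels}")
    return CalibrationTable(factors=raw.data, source=source)


def stream_frames(
    long_trace: DetectorTrace,
    smap: SpectralMap,
    calib: CalibrationTable | None,
    frame_duration: float,
    window: str = "rect",
):
    """Split a long trace into consecutive non-overlapping frames and
    reconstruct each independently.

    Returns a :class:`facesim.scenes.SceneSequence` whose timestamps are the
    frame start times.  A trailing partial frame is discarded (logged).
    """
    from .scenes import SceneSequence  # local import: scenes builds on forward_sim

    n_frame = int(round(frame_duration * long_trace.sampling_rate))
    total = len(long_trace)
    if n_frame < 2 or total < n_frame:
        raise ValueError("trace shorter than one frame")
    n_frames = total // n_frame
    dropped = total - n_frames * n_frame
    if dropped:
        log.warning("discarding trailing partial frame (%d samples)", dropped)
    fields = []
    timestamps = []
    samples = np.asarray(long_trace.samples)
    for i in range(n_frames):
        seg = DetectorTrace(
            samples=samples[i * n_frame : (i + 1) * n_frame],
            sampling_rate=long_trace.sampling_rate,
            start_time=long_trace.start_time + i * frame_duration,
        )
        fields.append(extract_field(fft_spectrum(seg, window=window), smap, calib))
        timestamps.append(seg.start_time)
    return SceneSequence(
        frames=fields,
        timestamps=np.asarray(timestamps),
        metadata={"generator": "stream_frames", "frame_duration_s": frame_duration,
                  "dropped_samples": dropped},
    )
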