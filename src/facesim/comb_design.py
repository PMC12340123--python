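"""Design of the two orthogonal RF frequency combs and the pixel-to-beat-frequency map.

In FACE (frequency-comb acousto-optic coherent encoding) each image pixel
``(n, m)`` is illuminated by a sub-beam whose optical frequency is shifted by
two crossed acousto-optic deflectors, one driven by an x-axis comb and one by a
y-axis comb.  Relative to the unmodulated reference carrier ``f0`` the pixel
oscillates at the *beat frequency*

    beat(n, m) = f_y(y_m) - f_x(x_n)

On a square-law single-pixel detector every pixel therefore appears at
``|beat|`` in the intensity spectrum.  Image recovery is only possible when the
map ``(n, m) -> |beat|`` is one-to-one, clear of DC, below the digitizer
Nyquist frequency, and clear of the beat tones produced by the residual
one-dimensional diffraction of the first deflector.  This module constructs
combs, builds the pixel map, and verifies those conditions exhaustively.

All frequencies are in Hz.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .fileio import atomic_write_text

log = logging.getLogger(__name__)

#: Allowed RF drive band of the deflectors used for the default design.
DEFAULT_DEVICE_BAND = (61e6, 91e6)

#: Default guard between the smallest |beat| and the DC synthesis term.
DEFAULT_DC_GUARD = 50e3

#: Default analysis bin width (1 / frame duration for 1 ms frames).
DEFAULT_BIN_WIDTH = 1e3

_REL_TOL = 1e-9


@dataclass(frozen=True)
class FrequencyComb:
    """A one-dimensional RF tone comb driving one deflector axis.

    Parameters
    ----------
    axis : {"x", "y"}
    tones : strictly increasing tone frequencies, Hz.
    band_low, band_high : device-allowed drive band, Hz.
    spacing : nominal tooth spacing, Hz.
    offset : sub-spacing shift applied to the whole comb, Hz.
    """

    axis: str
    tones: np.ndarray
    band_low: float
    band_high: float
    spacing: float
    offset: float

    def __post_init__(self) -> None:
        tones = np.asarray(self.tones, dtype=float)
        object.__setattr__(self, "tones", tones)
        if self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")
        if tones.size < 1:
            raise ValueError("comb must contain at least one tone")
        if tones.size > 1 and not np.all(np.diff(tones) > 0):
            raise ValueError("tones must be strictly increasing")
        tol = _REL_TOL * max(abs(self.band_high), 1.0)
        if tones[0] < self.band_low - tol or tones[-1] > self.band_high + tol:
            raise ValueError(
                f"tones [{tones[0]:.6g}, {tones[-1]:.6g}] Hz exceed device band "
                f"[{self.band_low:.6g}, {self.band_high:.6g}] Hz"
            )

    @property
    def n_tones(self) -> int:
        return int(self.tones.size)

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "tones_hz": [float(t) for t in self.tones],
            "band_low_hz": self.band_low,
            "band_high_hz": self.band_high,
            "spacing_hz": self.spacing,
            "offset_hz": self.offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrequencyComb":
        return cls(
            axis=d["axis"],
            tones=np.asarray(d["tones_hz"], dtype=float),
            band_low=float(d["band_low_hz"]),
            band_high=float(d["band_high_hz"]),
            spacing=float(d["spacing_hz"]),
            offset=float(d["offset_hz"]),
        )


def build_comb(
    band_start: float,
    band_end: float,
    spacing: float,
    offset: float = 0.0,
    grid: float = 0.0,
    axis: str = "x",
    device_band: tuple[float, float] | None = None,
) -> FrequencyComb:
    """Place tones ``band_start + offset + k*spacing`` for k = 0, 1, ... ≤ band_end.

    ``grid`` > 0 enables grid-locking: the comb start, spacing and offset must
    all be integer multiples of ``grid`` so that every tone (and hence every
    beat) falls on an exact analysis bin.  ``grid = 0`` disables the check.

    Raises
    ------
    ValueError
        If no tone fits the band, if grid-locking is violated, or if a tone
        falls outside the device band.
    """
    if band_end < band_start:
        raise ValueError("band_end must be >= band_start")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if grid < 0:
        raise ValueError("grid must be >= 0")
    if grid > 0:
        for name, value in (("band_start", band_start), ("spacing", spacing), ("offset", offset)):
            ratio = value / grid
            if abs(ratio - round(ratio)) > 1e-6:
                raise ValueError(
                    f"grid-locking requires {name} to be an integer multiple of "
                    f"{grid:.6g} Hz (got {value:.6g} Hz)"
                )

    first = band_start + offset
    if first > band_end * (1 + _REL_TOL):
        raise ValueError("no tone fits the requested band (offset pushes the comb out)")
    n = int(np.floor((band_end - first) / spacing + _REL_TOL * (band_end / spacing + 1))) + 1
    tones = first + spacing * np.arange(n)
    lo, hi = device_band if device_band is not None else (band_start, band_end)
    return FrequencyComb(
        axis=axis, tones=tones, band_low=lo, band_high=hi, spacing=spacing, offset=offset
    )


@dataclass(frozen=True)
class SpectralMap:
    """Pixel-to-beat-frequency assignment of a two-comb design.

    ``beat`` has shape ``(ny, nx)`` with ``beat[m, n] = f_y[m] - f_x[n]``
    (the reference carrier drops out of the difference).  Pixels with negative
    beat carry their information in the conjugate spectral bin and are flagged
    for conjugation at extraction.
    """

    comb_x: FrequencyComb
    comb_y: FrequencyComb
    f0: float
    beat: np.ndarray = field(repr=False)
    conjugate_flag: np.ndarray = field(repr=False)
    bin_width: float = DEFAULT_BIN_WIDTH

    @property
    def nx(self) -> int:
        return self.comb_x.n_tones

    @property
    def ny(self) -> int:
        return self.comb_y.n_tones

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def to_dict(self) -> dict:
        return {
            "comb_x": self.comb_x.to_dict(),
            "comb_y": self.comb_y.to_dict(),
            "f0_hz": self.f0,
            "bin_width_hz": self.bin_width,
            "beat_hz": [[float(b) for b in row] for row in self.beat],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralMap":
        smap = build_spectral_map(
            FrequencyComb.from_dict(d["comb_x"]),
            FrequencyComb.from_dict(d["comb_y"]),
            f0=float(d["f0_hz"]),
            bin_width=float(d["bin_width_hz"]),
        )
        if "beat_hz" in d:
            stored = np.asarray(d["beat_hz"], dtype=float)
            if stored.shape != smap.beat.shape or not np.allclose(stored, smap.beat):
                raise ValueError("stored beat table is inconsistent with the combs")
        return smap


def build_spectral_map(
    comb_x: FrequencyComb,
    comb_y: FrequencyComb,
    f0: float = 0.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> SpectralMap:
    """Assign ``beat[m, n] = f_y[m] - f_x[n]`` for every pixel.

    No uniqueness check is performed here; run :func:`verify_unique_mapping`
    on the result before trusting the design.
    """
    if comb_x.n_tones < 1 or comb_y.n_tones < 1:
        raise ValueError("both combs must be nonempty")
    beat = comb_y.tones[:, None] - comb_x.tones[None, :]
    return SpectralMap(
        comb_x=comb_x,
        comb_y=comb_y,
        f0=f0,
        beat=beat,
        conjugate_flag=beat < 0,
        bin_width=bin_width,
    )


@dataclass(frozen=True)
class DesignReport:
    """Result of the exhaustive aliasing check of a spectral map.

    ``collisions`` lists pixel pairs whose |beat| values are closer than one
    analysis bin (this includes mirror collisions beat_i = -beat_j).
    ``residual_1d_separation`` is the minimum distance between any signal
    |beat| and any pairwise beat of the x-comb alone, i.e. the tones produced
    by residual one-dimensional diffraction.
    """

    passed: bool
    collisions: list
    dc_margin: float
    nyquist_margin: float
    residual_1d_separation: float
    bin_width: float
    dc_guard: float
    acq_nyquist: float

    def to_dict(self) -> dict:
        return {
            "passed": bool(self.passed),
            "collisions": [
                {
                    "pixel_a": list(a),
                    "pixel_b": list(b),
                    "beat_a_hz": ba,
                    "beat_b_hz": bb,
                }
                for (a, b, ba, bb) in self.collisions
            ],
            "dc_margin_hz": self.dc_margin,
            "nyquist_margin_hz": self.nyquist_margin,
            "residual_1d_separation_hz": self.residual_1d_separation,
            "bin_width_hz": self.bin_width,
            "dc_guard_hz": self.dc_guard,
            "acq_nyquist_hz": self.acq_nyquist,
        }


def verify_unique_mapping(
    smap: SpectralMap,
    acq_nyquist: float,
    dc_guard: float = DEFAULT_DC_GUARD,
) -> DesignReport:
    """Check the map for spectral aliasing; failures are reported, never raised.

    Conditions (all must hold for ``passed``):

    1. all |beat| values pairwise distinct by at least ``bin_width`` — this
       covers both same-sign collisions and mirror (twin sideband) collisions;
    2. min |beat| >= ``dc_guard`` (separation from the DC synthesis term);
    3. max |beat| < ``acq_nyquist``;
    4. every |beat| at least ``bin_width`` away from every residual
       1D-diffraction beat |f_x(n) - f_x(n')|.

    The pairwise check is done on the sorted |beat| sequence (adjacent gaps),
    which is exactly equivalent to comparing all pairs.
    """
    if smap.bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ny, nx = smap.shape
    abs_beat = np.abs(smap.beat).ravel()
    order = np.argsort(abs_beat, kind="stable")
    sorted_beats = abs_beat[order]

    collisions = []
    gaps = np.diff(sorted_beats)
    for i in np.nonzero(gaps < smap.bin_width)[0]:
        pa, pb = order[i], order[i + 1]
        # flat index -> (n, m) = (x index, y index)
        a = (int(pa % nx), int(pa // nx))
        b = (int(pb % nx), int(pb // nx))
        collisions.append((a, b, float(smap.beat.ravel()[pa]), float(smap.beat.ravel()[pb])))

    dc_margin = float(sorted_beats[0])
    nyquist_margin = float(acq_nyquist - sorted_beats[-1])

    if nx >= 2:
        fx = smap.comb_x.tones
        d1 = np.abs(fx[:, None] - fx[None, :])[np.triu_indices(nx, k=1)]
        d1 = np.unique(d1)
        # distance from each |beat| to the nearest 1D beat
        idx = np.searchsorted(d1, sorted_beats)
        dist = np.full(sorted_beats.shape, np.inf)
        left = idx > 0
        dist[left] = sorted_beats[left] - d1[idx[left] - 1]
        right = idx < d1.size
        dist[right] = np.minimum(dist[right], d1[idx[right]] - sorted_beats[right])
        residual_1d_separation = float(np.min(np.abs(dist)))
    else:
        residual_1d_separation = float("inf")

    passed = (
        not collisions
        and dc_margin >= dc_guard
        and nyquist_margin > 0
        and residual_1d_separation >= smap.bin_width
    )
    return DesignReport(
        passed=passed,
        collisions=collisions,
        dc_margin=dc_margin,
        nyquist_margin=nyquist_margin,
        residual_1d_separation=residual_1d_separation,
        bin_width=smap.bin_width,
        dc_guard=dc_guard,
        acq_nyquist=acq_nyquist,
    )


def default_design(
    bin_width: float = DEFAULT_BIN_WIDTH,
    acq_nyquist: float = 25e6,
    dc_guard: float = DEFAULT_DC_GUARD,
    verify: bool = True,
) -> SpectralMap:
    """The default 80 x 81 pixel encoding.

    x-comb: 80 tones, 63 MHz + k * 311 kHz (top tone 87.569 MHz);
    y-comb: 81 tones, 63 MHz + 141 kHz + k * 310 kHz (top tone 87.941 MHz);
    both confined to the 61-91 MHz device band and locked to a 1 kHz grid
    (leakage-free for 1 ms frames).  The coprime spacings (311/310) plus the
    141 kHz shift make every |beat| unique (the closest approach to DC is the
    diagonal beat family 141 - k kHz, bottoming out at 62 kHz), keep every
    |beat| at least 61 kHz away from the residual-1D beat comb (multiples of
    311 kHz), and put the largest beat (24.941 MHz) under the 25 MHz Nyquist
    of a 50 MSa/s digitizer.

    The design is re-verified on construction (``verify=True``); a failure
    raises rather than returning a silently aliased map.
    """
    # band_end 87.6 MHz caps the x comb at exactly 80 tones (an 81st tone at
    # 87.880 MHz would otherwise still fit under 88 MHz)
    comb_x = build_comb(
        63e6, 87.6e6, 311e3, offset=0.0, grid=bin_width, axis="x", device_band=DEFAULT_DEVICE_BAND
    )
    comb_y = build_comb(
        63e6, 88e6, 310e3, offset=141e3, grid=bin_width, axis="y", device_band=DEFAULT_DEVICE_BAND
    )
    smap = build_spectral_map(comb_x, comb_y, f0=0.0, bin_width=bin_width)
    if verify:
        report = verify_unique_mapping(smap, acq_nyquist=acq_nyquist, dc_guard=dc_guard)
        if not report.passed:
            raise RuntimeError(
                f"default design failed verification: {len(report.collisions)} collisions, "
                f"dc_margin={report.dc_margin:.6g} Hz, "
                f"nyquist_margin={report.nyquist_margin:.6g} Hz, "
                f"residual_1d_separation={report.residual_1d_separation:.6g} Hz"
            )
    return smap


def save_design(smap: SpectralMap, path, report: DesignReport | None = None) -> None:
    """Serialize a design (combs, f0, beat table, optional report) as JSON."""
    doc = smap.to_dict()
    if report is not None:
        doc["report"] = report.to_dict()
    atomic_write_text(path, json.dumps(doc, indent=1))


def load_design(path) -> SpectralMap:
    with open(path) as fh:
        return SpectralMap.from_dict(json.load(fh))
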