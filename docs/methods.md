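# Methods

## Signal model

A FACE (frequency-comb acousto-optic coherent encoding) microscope assigns
every pixel of an N × M frame a unique optical frequency by cascading two
acousto-optic deflectors driven by RF combs `f_x(x_n)` (N tones) and
`f_y(y_m)` (M tones). With the sign convention of 2-D Bragg diffraction
(first deflector downshifts, second upshifts), pixel (n, m) is shifted by
`f_y(y_m) − f_x(x_n)` relative to the unmodulated reference carrier — its
**beat frequency**. On the square-law detector the intensity is

```
I(t) = |E_R + E_S Σ_{n,m} O(x_n,y_m) e^{i2π·beat(n,m)·t}|²
       + |E_1D Σ_n e^{i2π f_x(x_n) t}|²
```

with `O = A e^{iφ}` the complex object, `E_R` the reference amplitude,
`E_S` the (nominally equal) per-tone signal amplitude and `E_1D` the
amplitude of the residual one-dimensional diffraction that passes only the
first deflector. Everything is synthesized at baseband: the optical carrier
(~291 THz at 1030 nm) drops out of the intensity, so only beat frequencies
(≤ 25 MHz here) are ever represented — exactly what the digitizer records.

Expanding the square gives four term families: DC
(`E_R² + E_S²ΣA² + N·E_1D²`), the heterodyne signal beats
`2E_S E_R A cos(2π·beat·t + φ)` that carry the image, object–object cross
beats `2E_S² A_i A_j cos(2πΔf t + φ_i − φ_j)`, and 1D–1D beats. Two points
deserve note:

* The cross-beat cosine must carry the *phase difference* `φ_i − φ_j`; a
  form with `Re(O_i O_j*)` multiplying a plain cosine discards the
  quadrature component and would not reproduce the squared magnitude for
  complex objects. The implementation uses the full form, and the test
  suite holds the term-by-term expansion to the direct `|Σ fields|²`
  evaluation at < 10⁻¹⁰ relative error.
* The residual-1D branch is added **incoherently** (no `E_R×E_1D` or
  `E_S×E_1D` beats): those difference frequencies sit at the RF drive
  frequencies (63–88 MHz), far beyond the detection band, and the branch is
  polarization-separated in the physical instrument. Its tones are assigned
  zero phase; any fixed choice is absorbed by calibration and, in a passing
  design, never overlaps a signal bin.

### Synthesis paths

For grid-locked designs every tone sits on an exact DFT bin of one frame, so
the fields are synthesized by placing complex coefficients on those bins and
inverse-FFT-ing — exact to floating point and O(L log L) per frame
regardless of pixel count (the 80 × 81 frame takes milliseconds). Off-grid
tones fall back to chunked complex exponentials. The term-by-term
"expanded" mode costs O(P²) in the pixel count P and exists as the
small-grid oracle for the direct path, not as a production route.

## Comb design and aliasing verification

Reconstruction reads `|beat|` bins of a *real* trace, so the map
(n, m) → |beat| must be injective at the analysis bin width, and that single
condition also excludes twin/mirror overlap (`beat_i = −beat_j` implies
equal magnitudes). The verifier additionally requires the smallest |beat|
to clear a DC guard (default 50 kHz), the largest to stay under the
digitizer Nyquist, and every |beat| to stay at least one bin away from every
1D beat `|f_x(n) − f_x(n')|`. The check sorts the 6 480 |beat| values and
inspects adjacent gaps — exactly equivalent to comparing all ~2 × 10⁷
pairs, and an all-pairs brute-force oracle backs it in the tests. Failures
are reported with the offending pixel pairs, never silently perturbed.

**Default design.** 80 x-tones at 63 MHz + k·311 kHz and 81 y-tones at
63.141 MHz + k·310 kHz, all inside the 61–91 MHz device band and confined
to 63–88 MHz, locked to the 1 kHz grid of a 1 ms frame at 50 MSa/s. The
near-coprime spacings and the 141 kHz shift were chosen by exhaustive search
over grid-locked (Δf_x, Δf_y, offset) triples: the binding constraint is the
diagonal beat family `offset − k·(Δf_x − Δf_y)`, which for any two full
combs packed into a 25 MHz span steps by only a few kHz and walks toward DC
unless the spacing difference and offset are tuned jointly. The adopted
design achieves min |beat| = 62 kHz, all |beat| values distinct on the 1 kHz
grid, 61 kHz separation from the residual-1D comb, and a 24.941 MHz maximum
beat (59 kHz under Nyquist). It is re-verified every time it is
constructed. An encoding with closely related structure (313/309 kHz
spacings, 77 kHz shift) fails the DC-guard condition — its diagonal family
reaches 1 kHz — which is why the verifier, not the designer's intent, is
the authority.

## Reconstruction and calibration

Spectra are normalized as `rfft(trace)/L`, so an on-grid cosine of amplitude
C reads C/2 at its bin and the heterodyne bin reads `E_S E_R O` directly.
Negative-beat pixels are conjugated at extraction (their information sits in
the conjugate sideband). The rectangular window is the default — exact for
grid-locked designs; a Hann window (amplitude corrected by the coherent
gain) is offered for externally recorded, off-grid traces, at the usual cost
of inter-bin leakage. Frames are non-overlapping and independent; a
trailing partial frame is dropped and logged. Phase is reported wrapped to
(−π, π]; no unwrapping is performed.

**Null calibration** stores the raw extracted complex values of a flat
(unit, zero-phase) scene and divides them out of subsequent extractions.
This removes per-tone gain/phase variation, the `E_S E_R` scale, and any
static multiplicative screen present in *both* acquisitions — the mechanism
behind imaging through a thin scatterer. The cancellation is exact in the
linear heterodyne term; object–object cross beats differ between the flat
and structured scenes, leaving the usual `~E_S/(2E_R)` bias, so the
screen-recovery property is stated (and tested) in the linearized regime.
Calibration factors below 10⁻⁶ of the maximum indicate dead pixels and fail
loudly with their positions.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| sampling rate | 50 MSa/s | digitizer operating point; Nyquist 25 MHz bounds the beat band |
| frame duration | 1 ms | 1 kHz frame rate; sets the 1 kHz FFT bin width and frequency grid |
| E_R / E_S | 100 | "much stronger" reference; keeps cross-term bias ~E_S/2E_R at 0.5% while using dynamic range plausibly. Configurable; the tests sweep {10, 100, 1000} |
| E_1D / E_S | 0.1 | residual-diffraction level is instrument-specific and unpublished; a 1% intensity leak is a plausible placeholder and any value is tolerated by a passing design |
| DC guard | 50 kHz | keeps signal bins clear of low-frequency detector drift around the DC synthesis term |
| bit depth / full scale | 0 (ideal float); 16-bit when enabled | matches a 16-bit acquisition card; full scale chosen so the noiseless peak sits near half range |
| shot noise | Gaussian, std √signal | Gaussian limit of Poisson statistics at the analog output; exact Poisson out of scope |
| acoustic velocity V | 650 m/s | slow-shear TeO₂ value for this deflector class — an **assumption**, labelled as such wherever reported; pitch and FoV scale as 1/V |
| droplet phase profile | spherical cap, peak π/2 | a spherical droplet of uniform index contrast; peak chosen to avoid wrap ambiguity |

Geometry: one comb step `ΔF/(tones−1)` deflects by `δθ = λΔf/V`; at the
objective focal plane this is a pixel pitch `Δx = f_obj·δθ` (3.76 μm at the
defaults) and a field of view `(tones−1)·Δx ≈ 297 μm`. The deflector
time-bandwidth product `N = (D/V)·ΔF ≈ 192` confirms ≥ 80 resolvable spots
per axis. The USAF-1951 line width `1000/(2·2^(g+(e−1)/6))` μm and the
space–bandwidth–time product `FPS × N × M (× channels)` follow the standard
definitions; SBP-T is quoted at 2 significant figures, with the channel
factor (2 for complex-field systems) always stated.

## What the synthetic scenes do and do not show

The generators produce the *structure* of real targets — bar charts with
exactly three resolvable dips, pure-phase droplets, diffusing mixing
boundaries, uniform translation — with known ground truth, which is what
lets round trips be checked to machine precision. They do not model
speckle, partial coherence, defocus, flow-induced motion blur within a
frame, or the refractive-index physics of real fluids; passing tests
therefore demonstrate the correctness of the encoding/decoding chain and
its noise behaviour, not the image quality attainable on a bench. For the
same reason the contrast-to-noise ratio reported by the acceptance script is
a property of the simulated noise level, not a reproduction of measured
instrument CNR.

## Numerical choices and edge cases

* Comb construction places tones `start + offset + k·spacing` while they fit
  the band, with a 10⁻⁹ relative tolerance so exact band endpoints are kept;
  grid-locking requires start, spacing and offset to be integer multiples of
  the bin width.
* Beat-to-bin lookup tolerates half a bin of mismatch (nearest bin, logged);
  more is an error, as is any bin beyond Nyquist.
* Digitizer saturation is counted and logged as a warning above 1%, never
  raised — clipped traces are still reconstructable data.
* All randomness (noise, phase screens, scene seeds) flows through explicit
  integer seeds; identical configuration and seed give bit-identical traces.
* Frame streaming discards a trailing partial frame rather than zero-padding
  it, so every reported frame integrates the same duration.
* File writes are write-then-rename; a crashed run cannot leave a truncated
  design, trace or image.

## Problem sizes

The test suite runs Monte-Carlo and oracle checks on an 8 × 9 pixel toy
design at 1 MSa/s (where O(P²) term expansion and all-pairs verification are
cheap) and the exactness, streaming, cross-term and screen-cancellation
checks on the full 80 × 81 design at 50 MSa/s; the acceptance script uses
the full design throughout, including a 1 s (5 × 10⁷ sample) stream. One
notable small-design artefact: the toy map happens to have *no* cross beat
aliasing onto a signal bin, so its cross-term bias is machine precision at
any reference ratio — the monotone 1/E_R error trend is therefore
demonstrated on the full design, where aliasing does occur.

## Known limitations

* Hardware is out of scope: RF drivers, Bragg-angle/polarization optics,
  relay aberrations, GPU real-time latency.
* The scattering medium is a static, thin, detection-side multiplicative
  phase screen; volumetric or time-varying scattering breaks the
  calibration-cancellation argument.
* Shot noise is Gaussian-approximated; at very low light the Poisson
  discreteness is not captured.
* The published instrument's exact comb spacings and shifts are not public;
  the default here is a verified-compliant stand-in with the same tone
  counts, band and grid, not a reproduction.
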