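import numpy as np
import pytest

import facesim as fs

TOY_RATE = 1e6  # Sa/s
TOY_FRAME = 1e-3  # s


def make_toy_map() -> fs.SpectralMap:
    """Small 8x9 collision-free signed design at 1 MSa/s.

    x comb: 100 + 41k kHz (8 tones); y comb: 156 + 43k kHz (9 tones).
    All |beat| distinct on the 1 kHz grid, min |beat| 15 kHz, max 400 kHz,
    21 negative-beat pixels (exercises the conjugation rule), residual-1D
    separation 10 kHz.
    """
    cx = fs.build_comb(100e3, 100e3 + 7 * 41e3, 41e3, grid=1e3, axis="x")
    cy = fs.build_comb(156e3, 156e3 + 8 * 43e3, 43e3, grid=1e3, axis="y")
    return fs.build_spectral_map(cx, cy, bin_width=1e3)


@pytest.fixture(scope="session")
def toy_map() -> fs.SpectralMap:
    smap = make_toy_map()
    report = fs.verify_unique_mapping(smap, acq_nyquist=TOY_RATE / 2, dc_guard=10e3)
    assert report.passed, "toy design must be collision-free"
    return smap


@pytest.fixture(scope="session")
def default_map() -> fs.SpectralMap:
    return fs.default_design()


@pytest.fixture
def toy_acq() -> fs.AcquisitionConfig:
    return fs.AcquisitionConfig(
        sampling_rate=TOY_RATE, frame_duration=TOY_FRAME, E_R=100.0, E_S=1.0, E_1D=0.1
    )


def random_object(shape, seed=0, amin=0.2) -> fs.ComplexField:
    rng = np.random.default_rng(seed)
    return fs.ComplexField.from_amp_phase(
        rng.uniform(amin, 1.0, shape), rng.uniform(-np.pi, np.pi, shape)
    )


@pytest.fixture
def toy_object(toy_map) -> fs.ComplexField:
    return random_object(toy_map.shape, seed=7)
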