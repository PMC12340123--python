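"""FFT demodulation, bin extraction, null calibration, frame streaming."""

import dataclasses

import numpy as np
import pytest

import facesim as fs

from conftest import random_object


def synth(obj, smap, acq, **kw):
    return fs.synthesize_trace(obj, smap, acq, **kw)


class TestFftSpectrum:
    def test_constant_trace_is_pure_dc(self):
        trace = fs.DetectorTrace(np.full(1000, 3.25), sampling_rate=1e6)
        spec = fs.fft_spectrum(trace)
        assert spec.values[0] == pytest.approx(3.25)
        assert np.all(np.abs(spec.values[1:]) < 1e-12)

    def test_on_grid_cosine_reads_half_amplitude(self):
        # 77 kHz tone, 50,000 samples at 50 MSa/s -> bin 77 of a 1 kHz grid
        t = np.arange(50_000) / 50e6
        trace = fs.DetectorTrace(np.cos(2 * np.pi * 77e3 * t), sampling_rate=50e6)
        spec = fs.fft_spectrum(trace)
        assert spec.bin_width == pytest.approx(1e3)
        assert abs(spec.values[77]) == pytest.approx(0.5, abs=1e-12)
        others = np.abs(np.delete(spec.values, 77))
        assert np.all(others < 1e-12)

    def test_parseval_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4096)
        spec = fs.fft_spectrum(fs.DetectorTrace(x, sampling_rate=1e6))
        v = spec.values
        # even length: DC and Nyquist bins are unpaired
        spectral = abs(v[0]) ** 2 + 2 * np.sum(np.abs(v[1:-1]) ** 2) + abs(v[-1]) ** 2
        assert spectral == pytest.approx(np.mean(x**2), rel=1e-10)

    def test_hann_window_preserves_on_bin_amplitude(self):
        t = np.arange(10_000) / 1e6
        trace = fs.DetectorTrace(np.cos(2 * np.pi * 5e3 * t), sampling_rate=1e6)
        spec = fs.fft_spectrum(trace, window="hann")
        assert abs(spec.values[50]) == pytest.approx(0.5, rel=1e-3)


class TestExtractField:
    def test_single_pixel_phase_recovered_with_cross_terms(self):
        cx = fs.build_comb(100e3, 100e3, 1e3, axis="x")
        cy = fs.build_comb(177e3, 177e3, 1e3, axis="y")
        smap = fs.build_spectral_map(cx, cy)
        obj = fs.ComplexField.from_amp_phase([[1.0]], [[np.pi / 3]])
        acq = fs.AcquisitionConfig(sampling_rate=1e6, E_R=100.0, E_S=1.0, E_1D=0.0)
        raw = fs.extract_field(fs.fft_spectrum(synth(obj, smap, acq)), smap)
        assert np.angle(raw.data[0, 0]) == pytest.approx(np.pi / 3, abs=1e-2)
        calib = fs.null_calibrate(synth(fs.ComplexField.flat(1, 1), smap, acq), smap)
        rec = fs.extract_field(fs.fft_spectrum(synth(obj, smap, acq)), smap, calib)
        assert abs(rec.data[0, 0]) == pytest.approx(1.0, abs=1e-2)

    def test_self_calibration_maps_flat_scene_to_unity(self, toy_map, toy_acq):
        flat = fs.ComplexField.flat(toy_map.nx, toy_map.ny)
        trace = synth(flat, toy_map, toy_acq)
        calib = fs.null_calibrate(trace, toy_map)
        rec = fs.extract_field(fs.fft_spectrum(trace), toy_map, calib)
        assert np.max(np.abs(rec.data - 1.0)) < 1e-10

    def test_roundtrip_with_cross_terms_high_reference(self, toy_map, toy_object):
        acq = fs.AcquisitionConfig(
            sampling_rate=1e6, frame_duration=1e-3, E_R=1000.0, E_S=1.0, E_1D=0.0
        )
        calib = fs.null_calibrate(
            synth(fs.ComplexField.flat(toy_map.nx, toy_map.ny), toy_map, acq), toy_map
        )
        rec = fs.extract_field(fs.fft_spectrum(synth(toy_object, toy_map, acq)), toy_map, calib)
        rel = np.abs(rec.data - toy_object.data) / np.abs(toy_object.data)
        assert np.max(rel) < 1e-3

    def test_cross_term_bias_shrinks_with_reference_power(self, default_map):
        # the small toy design happens to have no cross beat aliasing onto a
        # signal bin (its cross-term bias is machine precision at any E_R);
        # the full 80x81 map does alias and shows the 1/E_R trend
        obj = random_object(default_map.shape, seed=15)
        flat = fs.ComplexField.flat(default_map.nx, default_map.ny)
        errors = []
        for e_r in (10.0, 100.0, 1000.0):
            acq = fs.AcquisitionConfig(E_R=e_r, E_S=1.0, E_1D=0.1)
            calib = fs.null_calibrate(synth(flat, default_map, acq), default_map)
            rec = fs.extract_field(
                fs.fft_spectrum(synth(obj, default_map, acq)), default_map, calib
            )
            errors.append(float(np.mean(np.abs(rec.data - obj.data))))
        assert errors[0] > errors[1] > errors[2]

    def test_pure_phase_object_keeps_uniform_amplitude(self, toy_map):
        rng = np.random.default_rng(3)
        obj = fs.ComplexField.from_amp_phase(
            np.ones(toy_map.shape), rng.uniform(-np.pi, np.pi, toy_map.shape)
        )
        acq = fs.AcquisitionConfig(
            sampling_rate=1e6, frame_duration=1e-3, E_R=1000.0, E_S=1.0, E_1D=0.0
        )
        calib = fs.null_calibrate(
            synth(fs.ComplexField.flat(toy_map.nx, toy_map.ny), toy_map, acq), toy_map
        )
        rec = fs.extract_field(fs.fft_spectrum(synth(obj, toy_map, acq)), toy_map, calib)
        # amplitude and phase channels are independent: amplitude stays uniform
        # within the cross-term bound ~ n_pix * E_S / (2 E_R)
        assert np.max(np.abs(rec.amplitude - 1.0)) < 0.05
        assert np.max(np.abs(np.angle(rec.data * np.conj(obj.data)))) < 0.05

    def test_beat_beyond_nyquist_rejected(self, toy_map):
        short = fs.DetectorTrace(np.zeros(100), sampling_rate=100e3)  # Nyquist 50 kHz
        spec = fs.fft_spectrum(short)
        with pytest.raises(ValueError, match="Nyquist"):
            fs.extract_field(spec, toy_map)

    def test_calibration_shape_mismatch_rejected(self, toy_map, toy_acq):
        trace = synth(fs.ComplexField.flat(toy_map.nx, toy_map.ny), toy_map, toy_acq)
        bad = fs.CalibrationTable(factors=np.ones((2, 2), dtype=complex))
        with pytest.raises(ValueError, match="shape"):
            fs.extract_field(fs.fft_spectrum(trace), toy_map, bad)


class TestNullCalibrate:
    def test_gain_table_cancels_in_calibrated_extraction(self, toy_map, toy_object):
        rng = np.random.default_rng(9)
        gain = rng.uniform(0.5, 1.5, toy_map.shape) * np.exp(
            1j * rng.uniform(-np.pi, np.pi, toy_map.shape)
        )
        acq = fs.AcquisitionConfig(sampling_rate=1e6, frame_duration=1e-3, E_R=100.0, E_1D=0.0)
        flat = fs.ComplexField.flat(toy_map.nx, toy_map.ny)
        calib = fs.null_calibrate(
            synth(flat, toy_map, acq, include_cross_terms=False, gain=gain), toy_map
        )
        # factors proportional to the gain table
        ratio = calib.factors / gain
        assert np.max(np.abs(ratio - ratio[0, 0])) < 1e-8
        rec = fs.extract_field(
            fs.fft_spectrum(synth(toy_object, toy_map, acq, include_cross_terms=False, gain=gain)),
            toy_map,
            calib,
        )
        assert np.max(np.abs(rec.data - toy_object.data)) < 1e-8

    def test_uniform_system_gives_equal_factors(self, toy_map, toy_acq):
        flat = fs.ComplexField.flat(toy_map.nx, toy_map.ny)
        calib = fs.null_calibrate(
            synth(flat, toy_map, toy_acq, include_cross_terms=False), toy_map
        )
        assert np.max(np.abs(calib.factors - calib.factors[0, 0])) < 1e-10 * np.abs(
            calib.factors[0, 0]
        )

    def test_dead_pixel_reported_by_position(self, toy_map, toy_acq):
        gain = np.ones(toy_map.shape, dtype=complex)
        gain[4, 2] = 0.0
        flat = fs.ComplexField.flat(toy_map.nx, toy_map.ny)
        trace = synth(flat, toy_map, toy_acq, include_cross_terms=False, gain=gain)
        with pytest.raises(ValueError, match=r"\(2, 4\)"):
            fs.null_calibrate(trace, toy_map)


class TestStreamFrames:
    def test_static_object_reconstructs_identically_across_frames(
        self, toy_map, toy_object, toy_acq
    ):
        acq = dataclasses.replace(toy_acq, n_frames=10)
        flat = fs.ComplexField.flat(toy_map.nx, toy_map.ny)
        calib = fs.null_calibrate(synth(flat, toy_map, toy_acq), toy_map)
        long_trace = synth(toy_object, toy_map, acq)
        seq = fs.stream_frames(long_trace, toy_map, calib, frame_duration=1e-3)
        assert len(seq) == 10
        first = seq.frames[0].data
        for frame in seq.frames[1:]:
            assert np.max(np.abs(frame.data - first)) < 1e-10

    def test_partial_trailing_frame_discarded(self, toy_map, toy_object, toy_acq):
        trace = synth(toy_object, toy_map, toy_acq)
        n = len(trace)
        trace15 = fs.DetectorTrace(
            np.concatenate([trace.samples, trace.samples[: n // 2]]),
            sampling_rate=trace.sampling_rate,
        )
        seq = fs.stream_frames(trace15, toy_map, None, frame_duration=1e-3)
        assert len(seq) == 1
        assert seq.metadata["dropped_samples"] == n // 2

    def test_trace_shorter_than_frame_rejected(self, toy_map):
        tiny = fs.DetectorTrace(np.zeros(10), sampling_rate=1e6)
        with pytest.raises(ValueError, match="shorter"):
            fs.stream_frames(tiny, toy_map, None, frame_duration=1e-3)

    def test_timestamps_step_by_frame_duration(self, toy_map, toy_object, toy_acq):
        acq = dataclasses.replace(toy_acq, n_frames=4)
        trace = synth(toy_object, toy_map, acq)
        seq = fs.stream_frames(trace, toy_map, None, frame_duration=1e-3)
        assert np.allclose(np.diff(seq.timestamps), 1e-3)


class TestEndToEndDynamics:
    def test_reconstructed_droplet_tracks_generator_motion(self, default_map):
        droplet = lambda: fs.phase_droplet_scene(
            default_map.nx, default_map.ny, [((20.0, 40.0), 8.0, np.pi / 2)]
        )
        seq = fs.dynamic_sequence(droplet, (1.0, 0.0), n_frames=10, frame_duration=1e-3)
        acq = fs.AcquisitionConfig(E_R=100.0, E_S=1.0, E_1D=0.0)
        flat = fs.ComplexField.flat(default_map.nx, default_map.ny)
        calib = fs.null_calibrate(
            fs.synthesize_trace(flat, default_map, acq, include_cross_terms=False), default_map
        )
        xs = []
        xx = np.arange(default_map.nx)
        for frame in seq.frames:
            trace = fs.synthesize_trace(
                frame, default_map, acq, include_cross_terms=False
            )
            rec = fs.extract_field(fs.fft_spectrum(trace), default_map, calib)
            w = np.maximum(rec.phase, 0.0)
            xs.append(float(np.sum(w * xx[None, :]) / np.sum(w)))
        steps = np.diff(xs)
        assert np.all(np.abs(steps - 1.0) < 0.5)
        assert abs(xs[-1] - xs[0] - 9.0) < 0.5
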