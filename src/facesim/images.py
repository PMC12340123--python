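"""Image and scene-sequence file I/O: 32-bit float TIFF plus JSON metadata."""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import tifffile

from .fileio import atomic_write_bytes, atomic_write_text
from .forward_sim import ComplexField
from .scenes import SceneSequence


def _tiff_bytes(array: np.ndarray) -> bytes:
    buf = io.BytesIO()
    tifffile.imwrite(buf, np.asarray(array, dtype=np.float32), photometric="minisblack")
    return buf.getvalue()


def write_field_tiffs(field: ComplexField, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>_amplitude.tif`` and ``<prefix>_phase.tif`` (float32)."""
    prefix = Path(prefix)
    amp_path = prefix.parent / (prefix.name + "_amplitude.tif")
    ph_path = prefix.parent / (prefix.name + "_phase.tif")
    atomic_write_bytes(amp_path, _tiff_bytes(field.amplitude))
    atomic_write_bytes(ph_path, _tiff_bytes(field.phase))
    return amp_path, ph_path


def write_field_csv(field: ComplexField, path) -> None:
    """Dump the complex field as CSV rows of ``re,im`` (row-major pixels)."""
    buf = io.StringIO()
    flat = field.data.ravel()
    np.savetxt(buf, np.column_stack([flat.real, flat.imag]), delimiter=",")
    atomic_write_text(path, buf.getvalue())


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_sequence(seq: SceneSequence, directory) -> None:
    """Write a scene sequence as ``amplitude.tif`` / ``phase.tif`` multi-page
    stacks plus a ``scene.json`` with timestamps and generator metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    amp = np.stack([f.amplitude for f in seq.frames]).astype(np.float32)
    ph = np.stack([f.phase for f in seq.frames]).astype(np.float32)
    atomic_write_bytes(directory / "amplitude.tif", _tiff_bytes(amp))
    atomic_write_bytes(directory / "phase.tif", _tiff_bytes(ph))
    meta = {
        "timestamps_s": [float(t) for t in seq.timestamps],
        "metadata": seq.metadata,
        "n_frames": len(seq),
        "shape": list(seq.frames[0].shape),
    }
    atomic_write_text(directory / "scene.json", json.dumps(meta, indent=1))


def read_sequence(directory) -> SceneSequence:
    directory = Path(directory)
    with open(directory / "scene.json") as fh:
        meta = json.load(fh)
    amp = tifffile.imread(str(directory / "amplitude.tif"))
    ph = tifffile.imread(str(directory / "phase.tif"))
    if amp.ndim == 2:
        amp, ph = amp[None], ph[None]
    frames = [ComplexField.from_amp_phase(a, p) for a, p in zip(amp, ph)]
    return SceneSequence(
        frames=frames,
        timestamps=np.asarray(meta["timestamps_s"]),
        metadata=meta.get("metadata", {}),
    )
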