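"""Atomic file-write helpers shared by all output paths.

Every writer in the package goes through write-then-rename so a crashed run
never leaves a truncated design, trace, or image on disk.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path


def _atomic_write(path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_bytes(path, data: bytes) -> None:
    _atomic_write(path, data)


def atomic_write_text(path, text: str) -> None:
    _atomic_write(path, text.encode("utf-8"))
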