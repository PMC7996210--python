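"""Deterministic single-file checkpoints of named arrays.

Checkpoints are ordinary ``.npz`` containers (a zip of ``.npy`` members,
readable with ``numpy.load``), but written with fixed zip timestamps so the
same network state always produces byte-identical files — run artifacts can
be compared by checksum.
"""

from __future__ import annotations

import io
import zipfile
from pathlib import Path

import numpy as np

__all__ = ["save_checkpoint", "load_checkpoint"]

_EPOCH = (1980, 1, 1, 0, 0, 0)  # earliest zip timestamp


def save_checkpoint(path, **arrays: np.ndarray) -> None:
    """Write named arrays to ``path`` as a reproducible npz container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, np.asarray(arrays[name]))
            zf.writestr(zipfile.ZipInfo(f"{name}.npy", date_time=_EPOCH), buf.getvalue())


def load_checkpoint(path) -> dict[str, np.ndarray]:
    """Read a checkpoint back into a dict of arrays."""
    with np.load(path) as data:
        return {name: data[name] for name in data.files}
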