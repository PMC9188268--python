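"""WAV and delimited-table I/O helpers (RIFF float32, 16 kHz default)."""

from __future__ import annotations

import numpy as np
from scipy.io import wavfile


def read_wav(path: str) -> tuple[int, np.ndarray]:
    """Read a WAV file; returns (fs, channels x samples float64 in [-1, 1])."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        data = data / 128.0 - 1.0
    data = data.astype(float)
    if data.ndim == 1:
        data = data[None, :]
    else:
        data = data.T
    return fs, data


def write_wav(path: str, data: np.ndarray, fs: int = 16000) -> None:
    data = np.atleast_2d(np.asarray(data, np.float32))
    wavfile.write(path, fs, data.T if data.shape[0] > 1 else data[0])


def write_matrix(path: str, matrix: np.ndarray, header: list[str] | None = None,
                 delimiter: str = "\t") -> None:
    head = delimiter.join(header) if header else ""
    np.savetxt(path, np.asarray(matrix), delimiter=delimiter, header=head,
               comments="")


def read_matrix(path: str, delimiter: str = "\t",
                skip_header: int = 0) -> np.ndarray:
    return np.genfromtxt(path, delimiter=delimiter, skip_header=skip_header)
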