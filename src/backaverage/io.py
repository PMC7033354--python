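"""Reading and writing the plain-text interchange formats.

The native input format is a headerless whitespace-separated text file:
one sample per row, one channel per column, every row the same width.
The file carries no sampling rate, so ``fs`` must always be supplied by
the caller.  Decimal commas are not supported.

Tabular outputs (burst markers, averaged traces) are plain CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .detect import MarkerSet
    from .epoch import AverageResult

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "Recording",
    "ChannelPair",
    "load_recording",
    "write_recording",
    "select_channels",
    "write_markers",
    "read_markers",
    "write_average",
]


class FormatError(ValueError):
    """Raised when an input text file is not a rectangular numeric matrix."""


@dataclass
class Recording:
    """A multi-channel sampled signal.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        One row per sample, one column per channel, arbitrary units.
    fs : float
        Sampling rate in Hz.  Never inferred from the file.
    source : str
        Free-text provenance label (file path, "synthetic", ...).
    """

    data: np.ndarray
    fs: float
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("Recording requires a 2-D matrix with at least one sample and one channel")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording contains NaN or Inf; clean dropouts upstream")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def channel_count(self) -> int:
        return self.data.shape[1]


@dataclass
class ChannelPair:
    """The EMG and EEG channels extracted from a :class:`Recording`.

    ``emg_col``/``eeg_col`` keep the 1-based source column indices for
    provenance; the vectors themselves are plain 1-D arrays.
    """

    emg: np.ndarray
    eeg: np.ndarray
    fs: float
    emg_col: int = 0
    eeg_col: int = 0

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float).ravel()
        self.eeg = np.asarray(self.eeg, dtype=float).ravel()
        if self.emg.shape != self.eeg.shape:
            raise ValueError("EMG and EEG channels must have identical length")

    @property
    def n_samples(self) -> int:
        return self.emg.size


def _diagnose_text(path: Path) -> None:
    """Second-pass scan of a file that failed fast loading.

    Locates the first ragged row or non-numeric token and raises a
    :class:`FormatError` naming the 1-based line (and column) at fault.
    """
    width = None
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue  # blank (trailing) lines are ignored
            n_rows += 1
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise FormatError(
                    f"{path}: ragged row at line {lineno}: "
                    f"expected {width} columns, found {len(tokens)}"
                )
            for col, tok in enumerate(tokens, start=1):
                try:
                    float(tok)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric token {tok!r} at line {lineno}, column {col}"
                    ) from None
    if n_rows == 0:
        raise FormatError(f"{path}: file is empty")


def load_recording(path: str | Path, fs: float) -> Recording:
    """Load a headerless whitespace-separated multi-channel text file.

    Any run of spaces and/or tabs is a delimiter; blank trailing lines are
    ignored.  Ragged rows, non-numeric tokens, NaN/Inf values and empty
    files raise :class:`FormatError` with the offending location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    try:
        data = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError:
        _diagnose_text(path)  # raises FormatError with line/column
        raise  # pragma: no cover - diagnosis always raises
    if data.size == 0:
        raise FormatError(f"{path}: file is empty")
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise FormatError(
            f"{path}: non-finite value at line {bad[0] + 1}, column {bad[1] + 1}"
        )
    rec = Recording(data=data, fs=fs, source=str(path))
    logger.info("loaded %s: %d samples x %d channels at %g Hz",
                path, rec.n_samples, rec.channel_count, fs)
    return rec


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` in the native text format.

    Values are printed with ``%.17g`` so a load/write/load cycle is the
    identity on the numeric matrix.
    """
    np.savetxt(path, rec.data, fmt="%.17g", delimiter=" ")


def select_channels(rec: Recording, emg_col: int, eeg_col: int) -> ChannelPair:
    """Pick the EMG and EEG columns (1-based, as clinicians count them)."""
    for name, col in (("emg_col", emg_col), ("eeg_col", eeg_col)):
        if not 1 <= col <= rec.channel_count:
            raise IndexError(
                f"{name}={col} out of range: recording has {rec.channel_count} channels"
            )
    if emg_col == eeg_col:
        raise ValueError(f"emg_col and eeg_col are both {emg_col}; they must differ")
    return ChannelPair(
        emg=rec.data[:, emg_col - 1].copy(),
        eeg=rec.data[:, eeg_col - 1].copy(),
        fs=rec.fs,
        emg_col=emg_col,
        eeg_col=eeg_col,
    )


def write_markers(markers: "MarkerSet", fs: float, path: str | Path) -> None:
    """Write burst-onset markers as CSV with columns ``index,time_s``."""
    idx = np.asarray(markers.indices, dtype=int)
    if idx.size > 1 and np.any(np.diff(idx) <= 0):
        raise ValueError("markers must be sorted strictly ascending")
    df = pd.DataFrame({"index": idx, "time_s": idx / fs})
    df.to_csv(path, index=False)


def read_markers(path: str | Path, fs: float, provenance: str = "manual") -> "MarkerSet":
    """Read a marker CSV back into a :class:`~backaverage.detect.MarkerSet`."""
    from .detect import MarkerSet

    df = pd.read_csv(path)
    if "index" not in df.columns:
        raise FormatError(f"{path}: marker CSV must have an 'index' column")
    return MarkerSet(indices=df["index"].to_numpy(dtype=int), fs=fs,
                     provenance=provenance)


def write_average(avg: "AverageResult", path: str | Path) -> None:
    """Write an averaged trace as CSV with columns ``time_s,eeg_mean,emg_mean``."""
    df = pd.DataFrame({
        "time_s": avg.time_s,
        "eeg_mean": avg.eeg_mean,
        "emg_mean": avg.emg_mean,
    })
    df.to_csv(path, index=False)
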