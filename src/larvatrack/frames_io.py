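"""Reading frame sequences and writing per-second results tables.

Recordings are consumed at a fixed sampling rate (1 frame per second by
default, matching the assay's analysis rate).  Input is either a directory
of lexicographically ordered image frames (the canonical, codec-free path)
or a video container decoded through imageio.  Frames are converted to
grayscale by unweighted channel averaging and rescaled to [0, 1].

Iteration is streaming: frames are decoded one at a time, so memory use is
bounded by a constant number of frames regardless of recording length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRecordingError, FormatError, InputError

__all__ = [
    "FrameGrid",
    "Recording",
    "RESULTS_COLUMNS",
    "load_recording",
    "write_results",
    "read_results",
]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg", ".pgm"}

#: Fixed schema of the per-(dish, frame-pair) results table.
RESULTS_COLUMNS = [
    "source_id",
    "dish_id",
    "frame_index",
    "time_s",
    "n_fish_moved",
    "distance_px",
    "pixel_count",
    "penny_present",
]

_RESULTS_DTYPES = {
    "source_id": str,
    "dish_id": str,
    "frame_index": np.int64,
    "time_s": np.float64,
    "n_fish_moved": np.int64,
    "distance_px": np.float64,
    "pixel_count": np.int64,
    "penny_present": bool,
}


@dataclass(frozen=True)
class FrameGrid:
    """One grayscale frame: intensities in [0, 1] plus its sampled index and time."""

    pixels: np.ndarray
    frame_index: int
    time_s: float

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Convert a decoded image to a float grid in [0, 1].

    Color images use the unweighted mean of the channels; integer dtypes are
    rescaled by their full range.
    """
    a = np.asarray(arr)
    if a.ndim == 3:
        a = a.astype(np.float64).mean(axis=2)
    elif a.ndim != 2:
        raise FormatError(f"expected a 2-D or 3-D image, got shape {a.shape}")
    if np.issubdtype(np.asarray(arr).dtype, np.integer):
        info = np.iinfo(np.asarray(arr).dtype)
        a = a.astype(np.float64) / float(info.max)
    else:
        a = np.clip(a.astype(np.float64), 0.0, 1.0)
    return a


class Recording:
    """An ordered sequence of sampled frames sharing one geometry.

    Frames are decoded lazily on iteration; only the source handles (paths or
    in-memory arrays) are retained, which keeps whole-recording memory use
    independent of duration.
    """

    def __init__(
        self,
        loaders: Sequence[Callable[[], np.ndarray]],
        sample_rate_hz: float = 1.0,
        source_id: str = "",
    ):
        if sample_rate_hz <= 0:
            raise InputError(f"sample_rate_hz must be positive, got {sample_rate_hz}")
        if len(loaders) < 2:
            raise EmptyRecordingError(
                f"recording needs at least 2 sampled frames, got {len(loaders)}"
            )
        self._loaders = list(loaders)
        self.sample_rate_hz = float(sample_rate_hz)
        self.source_id = source_id
        self._shape: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self._loaders)

    def frame(self, index: int) -> FrameGrid:
        pixels = to_grayscale(self._loaders[index]())
        self._check_shape(pixels, index)
        return FrameGrid(pixels=pixels, frame_index=index, time_s=index / self.sample_rate_hz)

    def iter_frames(self) -> Iterator[FrameGrid]:
        for i in range(len(self)):
            yield self.frame(i)

    def load_all(self) -> list[FrameGrid]:
        return list(self.iter_frames())

    def _check_shape(self, pixels: np.ndarray, index: int) -> None:
        if self._shape is None:
            self._shape = pixels.shape
        elif pixels.shape != self._shape:
            raise FormatError(
                f"frame {index} has shape {pixels.shape}, expected {self._shape}"
            )

    @classmethod
    def from_arrays(
        cls, arrays: Sequence[np.ndarray], sample_rate_hz: float = 1.0, source_id: str = ""
    ) -> "Recording":
        return cls([(lambda a=a: a) for a in arrays], sample_rate_hz, source_id)


def subsample_indices(n_native: int, native_fps: float, sample_rate_hz: float) -> list[int]:
    """Native frame index nearest each 1/sample_rate tick (ties toward the earlier frame)."""
    if native_fps <= 0 or sample_rate_hz <= 0:
        raise InputError("frame rates must be positive")
    step = native_fps / sample_rate_hz
    out: list[int] = []
    k = 0
    while True:
        idx = math.ceil(k * step - 0.5)  # round half down
        if idx >= n_native:
            break
        out.append(idx)
        k += 1
    return out


def _load_from_directory(
    path: Path, sample_rate_hz: float, native_fps: float | None, source_id: str
) -> Recording:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if len(files) < 2:
        raise EmptyRecordingError(
            f"{path} contains {len(files)} readable image frame(s); need at least 2"
        )
    fps = native_fps if native_fps is not None else sample_rate_hz
    picked = [files[i] for i in subsample_indices(len(files), fps, sample_rate_hz)]
    if len(picked) < 2:
        raise EmptyRecordingError(
            f"subsampling {len(files)} frames at {sample_rate_hz} Hz leaves {len(picked)} frame(s)"
        )

    def make_loader(p: Path) -> Callable[[], np.ndarray]:
        def load() -> np.ndarray:
            import imageio.v3 as iio

            return iio.imread(p)

        return load

    return Recording([make_loader(p) for p in picked], sample_rate_hz, source_id)


def _load_from_video(
    path: Path, sample_rate_hz: float, native_fps: float | None, source_id: str
) -> Recording:
    import imageio.v3 as iio

    try:
        if native_fps is None:
            meta = iio.immeta(path)
            native_fps = meta.get("fps")
        if not native_fps:
            raise InputError(
                f"native frame rate of {path} not resolvable from metadata; pass native_fps"
            )
        frames = [np.asarray(f) for f in iio.imiter(path)]
    except InputError:
        raise
    except Exception as exc:  # decoder missing or container unreadable
        raise InputError(f"cannot decode video container {path}: {exc}") from exc
    keep = subsample_indices(len(frames), float(native_fps), sample_rate_hz)
    picked = [frames[i] for i in keep]
    if len(picked) < 2:
        raise EmptyRecordingError(f"{path}: fewer than 2 frames after sampling")
    return Recording.from_arrays(picked, sample_rate_hz, source_id)


def load_recording(
    path: str | Path,
    sample_rate_hz: float = 1.0,
    native_fps: float | None = None,
    source_id: str | None = None,
) -> Recording:
    """Load a frame directory or video container, subsampled to ``sample_rate_hz``.

    For directories, ``native_fps`` defaults to ``sample_rate_hz`` (the frames
    are assumed to already be at the analysis rate); for video containers it is
    read from metadata unless given.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"input path does not exist: {p}")
    sid = source_id if source_id is not None else p.name
    if p.is_dir():
        return _load_from_directory(p, sample_rate_hz, native_fps, sid)
    return _load_from_video(p, sample_rate_hz, native_fps, sid)


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as RFC-4180 CSV with the fixed column order."""
    missing = [c for c in RESULTS_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"results table missing columns: {missing}")
    out = table[RESULTS_COLUMNS].copy()
    path = Path(path)
    try:
        out.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise InputError(f"cannot write results CSV to {path}: {exc}") from exc
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results` (lossless round trip)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"results CSV does not exist: {path}")
    df = pd.read_csv(path)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} missing columns: {missing}")
    df = df[RESULTS_COLUMNS]
    for col, dtype in _RESULTS_DTYPES.items():
        df[col] = df[col].astype(dtype)
    return df


def empty_results() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=_RESULTS_DTYPES[c]) for c in RESULTS_COLUMNS})
    return df
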