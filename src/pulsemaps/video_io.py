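"""Frame-stack input/output and dropped-frame repair.

Video clips are handled as in-memory stacks of 2-D intensity frames with a
nominal sampling rate (typically 25 Hz for vital-sign imaging cameras) and
optional per-frame acquisition timestamps.  Two on-disk formats are
supported: multi-page TIFF (the primary exchange format, with clip metadata
stored in the image description tag) and raw little-endian unsigned-integer
frame files accompanied by a plain-text sidecar header.

Acquisition glitches show up as dropped frames; :func:`interpolate_dropped_frames`
restores a uniformly sampled stack by linear interpolation between the
surviving neighbouring frames, never touching frames that were actually
acquired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "FrameSequence",
    "read_frames",
    "write_frames",
    "interpolate_dropped_frames",
    "export_map_txt",
]

#: modality tags accepted for a clip
MODALITIES = ("PPGI-VIS", "PPGI-NIR", "IRT-LWIR", "synthetic")


@dataclass
class FrameSequence:
    """A time-indexed stack of 2-D intensity frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``; intensities are kept as
        real values at native bit depth (no rescaling on I/O).
    fs
        Nominal sampling rate in Hz.
    timestamps
        Optional per-frame acquisition times in seconds, strictly increasing.
    bit_depth
        Native ADC bit depth of the source (7-16 for the cameras targeted).
    modality
        One of :data:`MODALITIES`.
    """

    frames: np.ndarray
    fs: float
    timestamps: np.ndarray | None = None
    bit_depth: int = 16
    modality: str = "synthetic"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if self.frames.shape[0] < 1:
            raise ValueError("frame count must be >= 1")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.frames.shape[0],):
                raise ValueError("one timestamp per frame required")
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Clip duration in seconds (frame count over nominal rate)."""
        return self.n_frames / self.fs


def _storage_dtype(frames: np.ndarray, bit_depth: int) -> np.dtype:
    """Pick a lossless storage dtype: unsigned int when the data allows, else float64."""
    if np.issubdtype(frames.dtype, np.integer) or (
        np.all(np.isfinite(frames))
        and np.all(frames >= 0)
        and np.all(frames == np.round(frames))
        and frames.size
        and frames.max(initial=0) < 2 ** max(bit_depth, 1)
    ):
        return np.dtype("<u1") if bit_depth <= 8 else np.dtype("<u2")
    return np.dtype("<f8")


def write_frames(seq: FrameSequence, path: str | Path, format: str | None = None) -> Path:
    """Write a clip to disk (multi-page TIFF or raw + sidecar header).

    The format is inferred from the file suffix when not given
    (``.tif``/``.tiff`` -> TIFF, ``.raw`` -> raw).  Round-trips through
    :func:`read_frames` are bit-identical.
    """
    path = Path(path)
    fmt = format or ("raw" if path.suffix == ".raw" else "tiff")
    meta = {
        "fs": seq.fs,
        "bit_depth": seq.bit_depth,
        "modality": seq.modality,
        "timestamps": None if seq.timestamps is None else [float(t) for t in seq.timestamps],
    }
    if fmt == "tiff":
        dtype = _storage_dtype(seq.frames, seq.bit_depth)
        tifffile.imwrite(path, seq.frames.astype(dtype), photometric="minisblack",
                         description=json.dumps(meta))
    elif fmt == "raw":
        dtype = _storage_dtype(seq.frames, seq.bit_depth)
        if dtype.kind != "u":
            raise ValueError("raw format stores unsigned integers; data is not integer-valued")
        seq.frames.astype(dtype).tofile(path)
        header = {
            "rows": seq.frame_shape[0],
            "cols": seq.frame_shape[1],
            "n_frames": seq.n_frames,
            "dtype": dtype.str,
            "endianness": "little",
            **meta,
        }
        Path(str(path) + ".hdr").write_text(yaml.safe_dump(header))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_frames(path: str | Path, format: str | None = None) -> FrameSequence:
    """Read a clip from disk, preserving native values (no rescaling)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or ("raw" if path.suffix == ".raw" else "tiff")
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].description
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    elif fmt == "raw":
        hdr_path = Path(str(path) + ".hdr")
        if not hdr_path.exists():
            raise IOError(f"missing sidecar header: {hdr_path}")
        meta = yaml.safe_load(hdr_path.read_text())
        shape = (meta["n_frames"], meta["rows"], meta["cols"])
        frames = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        if frames.size != int(np.prod(shape)):
            raise ValueError("raw file size does not match header dimensions")
        frames = frames.reshape(shape)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("frame stack has inconsistent dimensions")
    ts = meta.get("timestamps")
    return FrameSequence(
        frames=np.asarray(frames, dtype=np.float64),
        fs=float(meta.get("fs", 25.0)),
        timestamps=None if ts is None else np.asarray(ts, dtype=float),
        bit_depth=int(meta.get("bit_depth", 16)),
        modality=str(meta.get("modality", "synthetic")),
    )


def interpolate_dropped_frames(
    seq: FrameSequence,
    nominal_fs: float,
    drop_indices: "list[int] | None" = None,
) -> FrameSequence:
    """Fill dropped frames by linear interpolation between surviving neighbours.

    A drop is detected wherever the inter-frame interval exceeds 1.5 nominal
    periods (the conventional midpoint rule); every detected gap is filled so
    the output is uniformly sampled at ``nominal_fs``.  Alternatively an
    explicit ``drop_indices`` list (positions on the uniform output grid that
    were lost) can be supplied for counter-based acquisition.

    Originally acquired frames are passed through bit-identically.  Gaps at
    the sequence boundary cannot be interpolated one-sided and raise.
    """
    frames = seq.frames
    if drop_indices is not None:
        n_out = seq.n_frames + len(drop_indices)
        drop_set = set(int(i) for i in drop_indices)
        if len(drop_set) != len(drop_indices):
            raise ValueError("duplicate drop indices")
        if any(i < 0 or i >= n_out for i in drop_set):
            raise ValueError("drop index out of range")
        if 0 in drop_set or (n_out - 1) in drop_set:
            raise ValueError("gap at sequence boundary cannot be interpolated")
        present = np.array(sorted(set(range(n_out)) - drop_set))
    elif seq.timestamps is not None:
        t = seq.timestamps
        period = 1.0 / nominal_fs
        dt = np.diff(t)
        # gaps: interval > 1.5 periods; grid index of each acquired frame
        present = np.round((t - t[0]) * nominal_fs).astype(int)
        if np.any(np.diff(present) < 1):
            raise ValueError("timestamps collide on the nominal sampling grid")
        # only widen where the midpoint rule fires; nominal jitter keeps di == 1
        di = np.diff(present)
        bad = (di > 1) & ~(dt > 1.5 * period)
        if np.any(bad):
            raise ValueError("non-uniform timestamps without a detectable gap")
        n_out = int(present[-1]) + 1
    else:
        raise ValueError("dropped-frame repair needs timestamps or an explicit drop list")

    out = np.empty((n_out,) + frames.shape[1:], dtype=np.result_type(frames.dtype, np.float64))
    out[present] = frames
    missing = np.setdiff1d(np.arange(n_out), present)
    if missing.size:
        left_pos = np.searchsorted(present, missing) - 1
        for m, lp in zip(missing, left_pos):
            lo, hi = present[lp], present[lp + 1]
            w = (m - lo) / (hi - lo)
            out[m] = (1.0 - w) * frames[lp] + w * frames[lp + 1]
    return FrameSequence(
        frames=out,
        fs=nominal_fs,
        timestamps=None,
        bit_depth=seq.bit_depth,
        modality=seq.modality,
    )


def export_map_txt(values: np.ndarray, path: str | Path) -> Path:
    """Export a 2-D map as a plain-text matrix (one row per line)."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("expected a 2-D map")
    np.savetxt(path, values)
    return Path(path)
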