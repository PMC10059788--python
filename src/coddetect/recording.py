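"""Multichannel inertial recordings: container, CSV I/O and decimation.

A recording holds the three fused-sensor channels the change-of-inertia
algorithm consumes: horizontal acceleration in the Earth frame (``earth_x``
east, ``earth_y`` north, both in G) and the subject's heading (``euler_x``,
degrees clockwise from due north). Channels are sampled synchronously at a
known rate and are assumed pre-aligned across devices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SensorRecording", "read_recording", "write_recording", "downsample"]

#: Standard gravity in m/s^2 (definition of the G unit used throughout).
G_MS2 = 9.80665

_CHANNELS = ("earth_x", "earth_y", "euler_x")


def _wrap_heading(deg: np.ndarray) -> np.ndarray:
    """Reduce heading angles modulo 360 into [0, 360)."""
    wrapped = np.mod(deg, 360.0)
    # np.mod can return 360.0 for tiny negative inputs due to rounding
    wrapped[wrapped >= 360.0] = 0.0
    return wrapped


@dataclass
class SensorRecording:
    """Synchronized Earth-frame acceleration and heading channels.

    Parameters
    ----------
    fs_hz : float
        Sampling frequency in Hz, > 0.
    earth_x, earth_y : array-like
        Horizontal acceleration in G; Earth frame, east / north components.
    euler_x : array-like
        Heading in degrees relative to due north, wrapped into [0, 360).
    device_id : str
        Free-text device label (e.g. ``"IMMU1"``).
    """

    fs_hz: float
    earth_x: np.ndarray
    earth_y: np.ndarray
    euler_x: np.ndarray
    device_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.fs_hz) or self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        self.earth_x = np.asarray(self.earth_x, dtype=float)
        self.earth_y = np.asarray(self.earth_y, dtype=float)
        self.euler_x = _wrap_heading(np.asarray(self.euler_x, dtype=float))
        n = len(self.earth_x)
        if n < 1:
            raise ValueError("recording must contain at least one sample")
        if len(self.earth_y) != n or len(self.euler_x) != n:
            raise ValueError(
                "channel lengths differ: "
                f"earth_x={n}, earth_y={len(self.earth_y)}, euler_x={len(self.euler_x)}"
            )

    def __len__(self) -> int:
        return len(self.earth_x)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(len(self)) / self.fs_hz


def read_recording(path, fs_hz: float, device_id: str | None = None) -> SensorRecording:
    """Read a recording from a delimited text file.

    The file must have a header row naming at least ``earth_x``, ``earth_y``
    and ``euler_x`` columns; ``time_s`` and ``device_id`` columns are accepted
    and ignored for the channel data (``device_id`` seeds the label when no
    explicit one is given). Headings are wrapped into [0, 360) at ingest.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    channels = {}
    for name in _CHANNELS:
        numeric = pd.to_numeric(df[name], errors="coerce")
        bad = numeric.index[numeric.isna() & df[name].notna()]
        if len(bad) > 0:
            # +2: one for the header row, one for 1-based numbering
            raise ValueError(
                f"{path}: non-numeric value in column {name!r} at line {bad[0] + 2}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna())[0])
            raise ValueError(f"{path}: missing value in column {name!r} at line {row + 2}")
        channels[name] = numeric.to_numpy()
    if device_id is None:
        if "device_id" in df.columns and len(df) > 0:
            device_id = str(df["device_id"].iloc[0])
        else:
            device_id = ""
    return SensorRecording(fs_hz=fs_hz, device_id=device_id, **channels)


def write_recording(recording: SensorRecording, path) -> None:
    """Write a recording as CSV (comma separator, ``.`` decimal, header row).

    Values are written with full ``repr`` precision so that
    ``read_recording(write_recording(r))`` round-trips exactly.
    """
    df = pd.DataFrame(
        {
            "time_s": recording.time_s,
            "earth_x": recording.earth_x,
            "earth_y": recording.earth_y,
            "euler_x": recording.euler_x,
        }
    )
    if recording.device_id:
        df["device_id"] = recording.device_id
    # %.17g guarantees binary round-trip for float64
    df.to_csv(path, index=False, float_format="%.17g")


def downsample(recording: SensorRecording, target_fs_hz: float) -> SensorRecording:
    """Decimate a recording to a lower sampling frequency.

    Plain sample selection: every k-th sample when the ratio is an integer,
    nearest-sample selection otherwise. No anti-alias filter is applied —
    the detection pipeline's smoothing stage provides the low-pass behaviour
    — and heading values are never averaged, so the 0/360 seam is safe.
    """
    if not np.isfinite(target_fs_hz) or target_fs_hz <= 0:
        raise ValueError(f"target_fs_hz must be positive, got {target_fs_hz}")
    if target_fs_hz > recording.fs_hz:
        raise ValueError(
            f"target_fs_hz ({target_fs_hz}) exceeds source frequency ({recording.fs_hz})"
        )
    if target_fs_hz == recording.fs_hz:
        return recording
    ratio = recording.fs_hz / target_fs_hz
    if abs(ratio - round(ratio)) < 1e-9:
        idx = np.arange(0, len(recording), int(round(ratio)))
    else:
        n_out = int(np.floor(len(recording) * target_fs_hz / recording.fs_hz))
        idx = np.minimum(np.round(np.arange(n_out) * ratio).astype(int), len(recording) - 1)
    return SensorRecording(
        fs_hz=target_fs_hz,
        earth_x=recording.earth_x[idx],
        earth_y=recording.earth_y[idx],
        euler_x=recording.euler_x[idx],
        device_id=recording.device_id,
    )
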