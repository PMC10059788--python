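"""Change-of-direction detection from Earth-frame horizontal acceleration.

The pipeline mirrors how body-worn inertial units are used to count turning
actions on the pitch: the Earth-frame horizontal acceleration channels are
smoothed with a percentage-based moving-average filter, re-projected into the
runner's own antero-posterior / medio-lateral axes using the fused heading
channel, and reduced to a per-sample horizontal modulus. Local maxima of the
modulus that reach a minimum intensity peak (PmI, in G) are counted as
changes of inertia (COI) — individual loaded foot-ground contacts — and
temporally clustered COIs are unified into a single change-of-direction
(COD) action, since one turn typically spans several braking and propulsive
steps.

Two parameters steer sensitivity: the smoothing percentage (the averaging
window as a fraction of one second of samples) and the PmI threshold. Low
settings leave step-level noise above threshold and over-count; high
settings can erase genuine turns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import SensorRecording

__all__ = [
    "DetectionConfig",
    "COIEvent",
    "CODEvent",
    "smooth_linear",
    "smooth_heading",
    "reproject",
    "horizontal_modulus",
    "detect_cois",
    "unify_cods",
    "detect_cods",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the detector.

    Parameters
    ----------
    smoothing_pct : float
        Moving-average window as a percentage of one second of samples
        (30 at 100 Hz -> 30-sample window). Grid values: 20, 30, 40.
    pmi_g : float
        Minimum intensity peak in G a modulus maximum must reach to count
        as a COI. Grid values: 0.8, 0.9, 1.0.
    min_peak_separation_s : float
        Two COI peaks closer than this keep only the larger (ties: earlier).
    merge_gap_s : float
        Consecutive COIs separated by at most this gap join one COD.
    """

    smoothing_pct: float
    pmi_g: float
    min_peak_separation_s: float = 0.10
    merge_gap_s: float = 0.50

    def __post_init__(self) -> None:
        if not (np.isfinite(self.smoothing_pct) and 0 < self.smoothing_pct <= 100):
            raise ValueError(f"smoothing_pct must be in (0, 100], got {self.smoothing_pct}")
        if not (np.isfinite(self.pmi_g) and self.pmi_g > 0):
            raise ValueError(f"pmi_g must be positive, got {self.pmi_g}")
        if self.min_peak_separation_s < 0 or self.merge_gap_s < 0:
            raise ValueError("time parameters must be non-negative")


@dataclass(frozen=True)
class COIEvent:
    """A change of inertia: one supra-threshold horizontal-acceleration peak."""

    time_s: float
    peak_g: float


@dataclass(frozen=True)
class CODEvent:
    """A change of direction: one or more COIs unified into a single action."""

    start_s: float
    end_s: float
    n_cois: int
    peak_g: float

    @property
    def mid_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def window_samples(smoothing_pct: float, fs_hz: float) -> int:
    """Averaging window length in samples: ``max(1, round(pct/100 * fs))``."""
    return max(1, int(round(smoothing_pct / 100.0 * fs_hz)))


def _sliding_mean(values: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average of half-width ``w // 2``.

    The window shrinks symmetrically near the edges so no data is fabricated
    at the trial boundaries (which are quiescent in the protocols this
    detector targets).
    """
    n = len(values)
    half = w // 2
    if half == 0 or n == 1:
        return values.astype(float, copy=True)
    i = np.arange(n)
    m = np.minimum(half, np.minimum(i, n - 1 - i))
    cs = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    lo, hi = i - m, i + m + 1
    return (cs[hi] - cs[lo]) / (hi - lo)


def smooth_linear(values, smoothing_pct: float, fs_hz: float) -> np.ndarray:
    """Percentage-based moving average for linear (acceleration) channels."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot smooth an empty sequence")
    if not 0 < smoothing_pct <= 100:
        raise ValueError(f"smoothing_pct must be in (0, 100], got {smoothing_pct}")
    return _sliding_mean(values, window_samples(smoothing_pct, fs_hz))


def smooth_heading(headings_deg, smoothing_pct: float, fs_hz: float) -> np.ndarray:
    """Same window rule as :func:`smooth_linear`, but with the circular mean.

    Headings are angles: a window spanning {359, 1} must average to 0, not
    180, so each window averages the unit vectors and takes ``atan2`` of the
    result. Output is wrapped into [0, 360).
    """
    h = np.radians(np.asarray(headings_deg, dtype=float))
    if h.size == 0:
        raise ValueError("cannot smooth an empty sequence")
    sin_m = smooth_linear(np.sin(h), smoothing_pct, fs_hz)
    cos_m = smooth_linear(np.cos(h), smoothing_pct, fs_hz)
    out = np.degrees(np.arctan2(sin_m, cos_m))
    out = np.mod(out, 360.0)
    out[out >= 360.0] = 0.0
    return out


def reproject(earth_x, earth_y, heading_deg) -> tuple[np.ndarray, np.ndarray]:
    """Rotate Earth-frame horizontal acceleration into the runner's frame.

    Convention: ``earth_y`` points north, ``earth_x`` east, and the heading
    is measured clockwise from north. Antero-posterior (AP) is positive
    forward; medio-lateral (ML) is positive to the runner's right.

    Returns ``(a_ml, a_ap)``.
    """
    ex = np.asarray(earth_x, dtype=float)
    ey = np.asarray(earth_y, dtype=float)
    h = np.radians(np.asarray(heading_deg, dtype=float))
    if not (len(ex) == len(ey) == len(h)):
        raise ValueError(
            f"length mismatch: earth_x={len(ex)}, earth_y={len(ey)}, heading={len(h)}"
        )
    a_ap = ey * np.cos(h) + ex * np.sin(h)
    a_ml = -ey * np.sin(h) + ex * np.cos(h)
    return a_ml, a_ap


def horizontal_modulus(a_ml, a_ap) -> np.ndarray:
    """Per-sample Euclidean norm of the body-frame horizontal acceleration."""
    a_ml = np.asarray(a_ml, dtype=float)
    a_ap = np.asarray(a_ap, dtype=float)
    if len(a_ml) != len(a_ap):
        raise ValueError(f"length mismatch: a_ml={len(a_ml)}, a_ap={len(a_ap)}")
    return np.hypot(a_ml, a_ap)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a plateau yields its center index."""
    n = len(x)
    if n < 3:
        return np.array([], dtype=int)
    peaks = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def detect_cois(
    modulus,
    pmi_g: float,
    fs_hz: float,
    min_peak_separation_s: float = 0.10,
) -> list[COIEvent]:
    """Detect changes of inertia: modulus maxima reaching the PmI threshold.

    Of any two surviving peaks closer than ``min_peak_separation_s`` only the
    larger is kept; equal peaks keep the earlier. Events are returned sorted
    by time.
    """
    x = np.asarray(modulus, dtype=float)
    if np.any(x < 0):
        raise ValueError("modulus values must be non-negative")
    idx = _local_maxima(x)
    idx = idx[x[idx] >= pmi_g]
    if len(idx) == 0:
        return []
    # greedy suppression, highest peak first; ties broken toward earlier times
    order = sorted(range(len(idx)), key=lambda k: (-x[idx[k]], idx[k]))
    min_gap = min_peak_separation_s * fs_hz
    kept: list[int] = []
    for k in order:
        if all(abs(idx[k] - idx[j]) >= min_gap - 1e-9 for j in kept):
            kept.append(k)
    kept_idx = np.sort(idx[np.asarray(kept, dtype=int)])
    return [COIEvent(time_s=i / fs_hz, peak_g=float(x[i])) for i in kept_idx]


def unify_cods(cois: list[COIEvent], merge_gap_s: float = 0.50) -> list[CODEvent]:
    """Greedy left-to-right unification of COIs into COD actions.

    Consecutive COIs whose inter-event gap is at most ``merge_gap_s`` belong
    to the same COD; the COD spans its member COIs and carries their count
    and maximum peak.
    """
    if any(b.time_s < a.time_s for a, b in zip(cois, cois[1:])):
        raise ValueError("COI events must be sorted by time")
    cods: list[CODEvent] = []
    group: list[COIEvent] = []
    for coi in cois:
        if group and coi.time_s - group[-1].time_s > merge_gap_s:
            cods.append(_close_group(group))
            group = []
        group.append(coi)
    if group:
        cods.append(_close_group(group))
    return cods


def _close_group(group: list[COIEvent]) -> CODEvent:
    return CODEvent(
        start_s=group[0].time_s,
        end_s=group[-1].time_s,
        n_cois=len(group),
        peak_g=max(c.peak_g for c in group),
    )


def detect_cods(recording: SensorRecording, config: DetectionConfig) -> list[CODEvent]:
    """Full detection pipeline on a recording.

    Smooth the Earth acceleration channels (arithmetic mean) and the heading
    (circular mean), re-project into AP/ML, take the horizontal modulus,
    detect COIs at the PmI threshold, and unify them into CODs.
    Deterministic for fixed inputs.
    """
    fs = recording.fs_hz
    ex = smooth_linear(recording.earth_x, config.smoothing_pct, fs)
    ey = smooth_linear(recording.earth_y, config.smoothing_pct, fs)
    heading = smooth_heading(recording.euler_x, config.smoothing_pct, fs)
    a_ml, a_ap = reproject(ex, ey, heading)
    modulus = horizontal_modulus(a_ml, a_ap)
    cois = detect_cois(modulus, config.pmi_g, fs, config.min_peak_separation_s)
    return unify_cods(cois, config.merge_gap_s)
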