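"""Synthetic agility-trial generator with ground-truth COD annotations.

Emulates a standard change-of-direction test: a 15 m straight approach run
at a prescribed speed (13 or 18 km/h) down a marked line, hard braking into
a single turn of 45/90/135/180 degrees to the left or right at a break
point, and re-acceleration out of the turn. The generator produces the
three channels a body-worn inertial unit would record (Earth-frame
horizontal acceleration in G plus fused heading in degrees from north),
together with the planted turn time, so the detector and the validity
statistics can be exercised without access to real recordings.

The signal model is kinematics plus gait:

* a piecewise speed profile (standing start, build-up to the approach
  speed, constant approach, constant-deceleration brake to a fraction of
  approach speed, constant-speed turn with a linear heading ramp,
  constant-acceleration exit, run-out, deceleration to a stop),
  differentiated to an Earth-frame acceleration vector;
* a step-frequency oscillation standing in for foot-ground impacts, whose
  amplitude grows with running speed and with the instantaneous kinematic
  load — loaded cutting steps strike far harder than cruise steps, which
  is precisely the structure the change-of-inertia detector keys on — with
  step-to-step amplitude variability;
* white sensor noise on each axis and a small heading jitter.

All randomness flows through the explicit integer trial seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import G_MS2, SensorRecording

__all__ = [
    "TrialSpec",
    "NoiseModel",
    "GroundTruth",
    "simulate_trial",
    "generate_protocol",
    "drop_trials",
]

_APPROACH_M = 15.0  #: approach distance to the break point, metres
_V_REF_MS = 13.0 / 3.6  #: reference speed for step-amplitude scaling (13 km/h)


@dataclass(frozen=True)
class TrialSpec:
    """One change-of-direction trial of the test protocol."""

    speed_kmh: float
    angle_deg: float
    direction: str  # "left" or "right"
    participant_id: str = "P01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise ValueError(f"speed_kmh must be positive, got {self.speed_kmh}")
        if not 0 < self.angle_deg <= 180:
            raise ValueError(f"angle_deg must be in (0, 180], got {self.angle_deg}")
        if self.direction not in ("left", "right"):
            raise ValueError(f"direction must be 'left' or 'right', got {self.direction!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Signal-shape parameters of the simulator.

    The gait component on the body axes is
    ``A(t) * [sin(2*pi*f*t + phi), ml_ratio * cos(...)]`` with

    ``A(t) = step_amp_g * ((v(t)/v_13)**speed_exp + load_gain*|a_kin(t)|) * m(t)``

    where ``|a_kin|`` is the kinematic acceleration magnitude in G and
    ``m(t)`` a per-step multiplier with coefficient of variation
    ``step_cv``. The two amplitude terms model cruise impacts growing with
    running speed, and the much harder foot plants of loaded braking,
    cutting and push-off steps — the structure that makes percentage
    smoothing and the PmI threshold meaningful dials.
    """

    step_freq_hz: float = 2.8  #: gait oscillation frequency
    step_amp_g: float = 0.4  #: cruise step amplitude at 13 km/h, G
    white_sd_g: float = 0.05  #: white sensor noise SD per axis, G
    brake_decel_ms2: float = 4.0  #: braking deceleration into the turn
    reaccel_ms2: float = 4.0  #: re-acceleration out of the turn
    accel_ms2: float = 2.5  #: build-up / final-stop acceleration magnitude
    turn_speed_frac: float = 0.6  #: speed retained through a full 180-degree turn
    load_gain: float = 12.0  #: step-amplitude gain per G of kinematic load
    speed_exp: float = 3.0  #: exponent of the speed scaling of step amplitude
    step_cv: float = 0.25  #: step-to-step amplitude coefficient of variation
    ml_ratio: float = 0.6  #: medio-lateral/antero-posterior gait amplitude ratio
    heading_noise_deg: float = 1.0  #: SD of heading jitter, degrees
    runout_m: float = 5.0  #: straight run-out distance after the turn
    idle_s: float = 0.7  #: standing margin before and after the run

    def __post_init__(self) -> None:
        for name in (
            "step_freq_hz", "step_amp_g", "white_sd_g", "brake_decel_ms2",
            "reaccel_ms2", "accel_ms2", "load_gain", "speed_exp", "step_cv",
            "ml_ratio", "heading_noise_deg", "runout_m", "idle_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.turn_speed_frac <= 1:
            raise ValueError("turn_speed_frac must be in (0, 1]")

    def turn_duration_s(self, angle_deg: float) -> float:
        """Heading-transition duration: sharper cuts are quicker."""
        return 0.2 + angle_deg / 450.0

    def turn_speed_ms(self, speed_kmh: float, angle_deg: float) -> float:
        """Speed carried through the turn, m/s.

        Slowdown scales with turn angle: a shallow cut barely costs speed,
        a 180-degree reversal drops to ``turn_speed_frac`` of the approach
        speed.
        """
        v = speed_kmh / 3.6
        return v * (1.0 - (1.0 - self.turn_speed_frac) * angle_deg / 180.0)


@dataclass(frozen=True)
class GroundTruth:
    """Planted annotation for one simulated trial."""

    cod_time_s: float  #: break-point (mid-turn) time, seconds
    angle_deg: float
    direction: str
    trial: TrialSpec


def _timeline(spec: TrialSpec, noise: NoiseModel) -> dict[str, float]:
    """Phase boundary times of the trial, in seconds from recording start."""
    v = spec.speed_kmh / 3.6
    v_turn = noise.turn_speed_ms(spec.speed_kmh, spec.angle_deg)
    t_build = v / noise.accel_ms2 if noise.accel_ms2 > 0 else 0.0
    t_brake = (v - v_turn) / noise.brake_decel_ms2 if noise.brake_decel_ms2 > 0 else 0.0
    d_brake = 0.5 * (v + v_turn) * t_brake
    if d_brake >= _APPROACH_M:
        raise ValueError("braking distance exceeds the approach distance")
    bounds = {}
    bounds["run_start"] = noise.idle_s
    bounds["approach_start"] = bounds["run_start"] + t_build
    bounds["brake_start"] = bounds["approach_start"] + (_APPROACH_M - d_brake) / v
    bounds["turn_start"] = bounds["brake_start"] + t_brake  # the break point
    bounds["turn_end"] = bounds["turn_start"] + noise.turn_duration_s(spec.angle_deg)
    t_reacc = (v - v_turn) / noise.reaccel_ms2 if noise.reaccel_ms2 > 0 else 0.0
    bounds["reacc_end"] = bounds["turn_end"] + t_reacc
    bounds["runout_end"] = bounds["reacc_end"] + noise.runout_m / v
    t_stop = v / noise.accel_ms2 if noise.accel_ms2 > 0 else 0.0
    bounds["stop_end"] = bounds["runout_end"] + t_stop
    bounds["end"] = bounds["stop_end"] + noise.idle_s
    return bounds


def _speed_and_heading(
    t: np.ndarray, spec: TrialSpec, noise: NoiseModel, b: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise speed (m/s) and heading (deg) profiles over sample times."""
    v = spec.speed_kmh / 3.6
    v_turn = noise.turn_speed_ms(spec.speed_kmh, spec.angle_deg)
    speed = np.zeros_like(t)

    def between(a: str, z: str) -> np.ndarray:
        return (t >= b[a]) & (t < b[z])

    sel = between("run_start", "approach_start")
    speed[sel] = noise.accel_ms2 * (t[sel] - b["run_start"])
    speed[between("approach_start", "brake_start")] = v
    sel = between("brake_start", "turn_start")
    speed[sel] = v - noise.brake_decel_ms2 * (t[sel] - b["brake_start"])
    speed[between("turn_start", "turn_end")] = v_turn
    sel = between("turn_end", "reacc_end")
    speed[sel] = v_turn + noise.reaccel_ms2 * (t[sel] - b["turn_end"])
    speed[between("reacc_end", "runout_end")] = v
    sel = between("runout_end", "stop_end")
    speed[sel] = np.maximum(0.0, v - noise.accel_ms2 * (t[sel] - b["runout_end"]))

    sign = 1.0 if spec.direction == "right" else -1.0
    t_turn = b["turn_end"] - b["turn_start"]
    heading = np.zeros_like(t)
    ramp = between("turn_start", "turn_end")
    heading[ramp] = sign * spec.angle_deg * (t[ramp] - b["turn_start"]) / t_turn
    heading[t >= b["turn_end"]] = sign * spec.angle_deg
    return speed, heading


def simulate_trial(
    spec: TrialSpec,
    noise: NoiseModel | None = None,
    fs_hz: float = 100.0,
) -> tuple[SensorRecording, GroundTruth]:
    """Simulate one trial; returns the recording and its ground truth.

    Reproducible: the same ``spec`` (including its seed) always yields an
    identical recording.
    """
    if fs_hz <= 0:
        raise ValueError(f"fs_hz must be positive, got {fs_hz}")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(spec.seed)

    bounds = _timeline(spec, noise)
    n = int(round(bounds["end"] * fs_hz)) + 1
    t = np.arange(n) / fs_hz

    speed, heading_deg = _speed_and_heading(t, spec, noise, bounds)

    # Earth-frame velocity (east, north); heading measured clockwise from north
    h_rad = np.radians(heading_deg)
    vx = speed * np.sin(h_rad)
    vy = speed * np.cos(h_rad)
    ax_kin = np.gradient(vx, 1.0 / fs_hz) / G_MS2
    ay_kin = np.gradient(vy, 1.0 / fs_hz) / G_MS2
    load_g = np.hypot(ax_kin, ay_kin)

    # gait oscillation on the body axes, rotated into the Earth frame
    phase = rng.uniform(0.0, 2.0 * np.pi)
    step_idx = np.floor(t * noise.step_freq_hz).astype(int)
    n_steps = int(step_idx[-1]) + 1
    multipliers = np.clip(rng.normal(1.0, noise.step_cv, size=n_steps), 0.1, 2.5)
    amp = (
        noise.step_amp_g
        * ((speed / _V_REF_MS) ** noise.speed_exp + noise.load_gain * load_g)
        * multipliers[step_idx]
    )
    omega = 2.0 * np.pi * noise.step_freq_hz
    gait_ap = amp * np.sin(omega * t + phase)
    gait_ml = noise.ml_ratio * amp * np.cos(omega * t + phase)
    gait_x = gait_ap * np.sin(h_rad) + gait_ml * np.cos(h_rad)
    gait_y = gait_ap * np.cos(h_rad) - gait_ml * np.sin(h_rad)

    earth_x = ax_kin + gait_x + rng.normal(0.0, noise.white_sd_g, size=n)
    earth_y = ay_kin + gait_y + rng.normal(0.0, noise.white_sd_g, size=n)
    euler_x = heading_deg + rng.normal(0.0, noise.heading_noise_deg, size=n)

    recording = SensorRecording(
        fs_hz=fs_hz,
        earth_x=earth_x,
        earth_y=earth_y,
        euler_x=euler_x,
        device_id=spec.participant_id,
    )
    truth = GroundTruth(
        cod_time_s=0.5 * (bounds["turn_start"] + bounds["turn_end"]),
        angle_deg=spec.angle_deg,
        direction=spec.direction,
        trial=spec,
    )
    return recording, truth


_ANGLES = (45.0, 90.0, 135.0, 180.0)
_DIRECTIONS = ("left", "right")


def generate_protocol(
    n_participants: int,
    reps_per_cell_13: int,
    reps_per_cell_18: int = 0,
    base_seed: int = 0,
) -> list[TrialSpec]:
    """Full-factorial test protocol.

    Every participant performs ``reps_per_cell_13`` repetitions toward each
    of the four angles in both directions at 13 km/h, and
    ``reps_per_cell_18`` at 18 km/h (5 and 4 in the standard protocol: 40
    and 32 trials per participant). Trial seeds are ``base_seed + index``
    so any subset is reproducible.
    """
    if n_participants < 0 or reps_per_cell_13 < 0 or reps_per_cell_18 < 0:
        raise ValueError("counts must be non-negative")
    trials: list[TrialSpec] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for speed, reps in ((13.0, reps_per_cell_13), (18.0, reps_per_cell_18)):
            for angle in _ANGLES:
                for direction in _DIRECTIONS:
                    for _ in range(reps):
                        trials.append(
                            TrialSpec(
                                speed_kmh=speed,
                                angle_deg=angle,
                                direction=direction,
                                participant_id=pid,
                                seed=base_seed + len(trials),
                            )
                        )
    return trials


def drop_trials(protocol: list[TrialSpec], n_drop: int, seed: int = 0) -> list[TrialSpec]:
    """Remove ``n_drop`` trials uniformly at random (seeded), keeping order.

    Emulates the exclusion of repetitions with inconsistent approach speed.
    """
    if n_drop < 0 or n_drop > len(protocol):
        raise ValueError(f"n_drop must be in [0, {len(protocol)}], got {n_drop}")
    if n_drop == 0:
        return list(protocol)
    rng = np.random.default_rng(seed)
    dropped = set(rng.choice(len(protocol), size=n_drop, replace=False).tolist())
    return [spec for i, spec in enumerate(protocol) if i not in dropped]
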