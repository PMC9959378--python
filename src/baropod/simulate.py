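"""Gait simulator: synthetic plantar-load time series standing in for hardware.

The simulator generates per-sensor load traces with gait structure so that
every downstream stage — calibration, gating, wire codec, heatmaps,
analytics — is testable without a physical insole:

* Feet alternate strictly.  At cadence *f* steps/min (both feet combined)
  each foot strikes every ``2·60000/f`` ms, the right foot half a period
  after the left.
* Within a stance of ``contact_time_ms``, each sensor follows a raised-cosine
  activation envelope whose peak phase depends on its anatomical zone, giving
  heel-to-toe load progression for a heel strike (reversed emphasis for a
  forefoot strike).
* Per-sensor amplitudes split the peak total load (``peak_load_factor`` ×
  body weight) across zones, so the instantaneous total never exceeds it.
* Loads below the sensors' 500 g trigger force read as zero (hardware dead
  zone).

Loads are then pushed through the calibration curve plus Gaussian ADC-count
noise and quantized to 12 bits, producing the same frame stream a device
would.  ``simulate_session`` composes the full pipeline — loads → frames →
percent → gate → encode → decode — and attaches a constant-pace synthetic
GPS track plus ground truth for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from . import firmware
from .analytics import GpsPoint, RunSession
from .calibration import (
    DEFAULT_CURVE,
    TRIGGER_FORCE_G,
    CalibrationCurve,
    percent_table,
    predict_reading,
)
from .firmware import AdcFrame, DEFAULT_CONFIG, FirmwareConfig, PercentVector
from .heatmap import DEFAULT_ZONES

__all__ = [
    "RunnerProfile",
    "SimConfig",
    "LoadSeries",
    "simulate_loads",
    "loads_to_frames",
    "simulate_session",
    "write_session_bundle",
    "read_session_bundle",
]


class SimulationError(ValueError):
    """Invalid profile or simulation configuration."""


Strike = Literal["heel", "midfoot", "forefoot"]

# Fraction of body-weight-scaled peak load carried by each zone, per strike.
_ZONE_WEIGHTS: dict[str, dict[str, float]] = {
    "heel": {"heel": 0.40, "midfoot": 0.08, "metatarsal": 0.37, "toe": 0.15},
    "midfoot": {"heel": 0.25, "midfoot": 0.25, "metatarsal": 0.35, "toe": 0.15},
    "forefoot": {"heel": 0.10, "midfoot": 0.15, "metatarsal": 0.50, "toe": 0.25},
}

# Stance phase (0 = touchdown, 1 = toe-off) at which each zone's envelope peaks.
_ZONE_PEAK_PHASE: dict[str, dict[str, float]] = {
    "heel": {"heel": 0.25, "midfoot": 0.45, "metatarsal": 0.65, "toe": 0.85},
    "midfoot": {"heel": 0.45, "midfoot": 0.35, "metatarsal": 0.55, "toe": 0.80},
    "forefoot": {"heel": 0.60, "midfoot": 0.50, "metatarsal": 0.35, "toe": 0.60},
}

_GPS_ORIGIN = (50.0600, 19.9400)  # arbitrary fixed start point
_GPS_SPEED_M_S = 3.0
_GPS_INTERVAL_MS = 1000
_M_PER_DEG_LAT = 111_195.0  # 2*pi*R/360 at R = 6,371,000 m


@dataclass(frozen=True)
class RunnerProfile:
    """Physical parameters of the simulated runner."""

    mass_kg: float = 70.0
    cadence_spm: float = 180.0
    contact_time_ms: float = 250.0
    strike: Strike = "heel"
    peak_load_factor: float = 2.0
    noise_sd_counts: float = 20.0

    def __post_init__(self) -> None:
        if not self.mass_kg > 0:
            raise SimulationError(f"mass_kg must be positive, got {self.mass_kg}")
        if not 0 < self.cadence_spm <= 300:
            raise SimulationError(
                f"cadence_spm must be in (0, 300], got {self.cadence_spm}"
            )
        if not self.contact_time_ms < 2 * 60_000 / self.cadence_spm:
            raise SimulationError(
                "contact_time_ms must be shorter than the per-foot step period"
            )
        if self.strike not in _ZONE_WEIGHTS:
            raise SimulationError(f"unknown strike pattern: {self.strike!r}")
        if self.noise_sd_counts < 0:
            raise SimulationError("noise_sd_counts must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    duration_ms: int = 60_000
    sample_period_ms: int = 150
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise SimulationError(f"duration_ms must be >= 0, got {self.duration_ms}")
        if not self.sample_period_ms > 0:
            raise SimulationError("sample_period_ms must be positive")


@dataclass
class LoadSeries:
    """Per-foot sampled loads: timestamps (ms) and a (n_samples, 16) gram array."""

    foot: str
    timestamps_ms: np.ndarray
    loads_g: np.ndarray
    stance_starts_ms: np.ndarray  # ground truth step onsets


def _sensor_params(profile: RunnerProfile) -> tuple[np.ndarray, np.ndarray]:
    """Per-sensor envelope amplitude (g) and peak stance phase."""
    peak_total_g = profile.peak_load_factor * profile.mass_kg * 1000.0
    weights = _ZONE_WEIGHTS[profile.strike]
    phases = _ZONE_PEAK_PHASE[profile.strike]
    amp = np.zeros(firmware.N_SENSORS)
    phase = np.zeros(firmware.N_SENSORS)
    for zone, sensors in DEFAULT_ZONES.items():
        for s in sensors:
            amp[s] = peak_total_g * weights[zone] / len(sensors)
            phase[s] = phases[zone]
    return amp, phase


def simulate_loads(
    profile: RunnerProfile, config: SimConfig
) -> dict[str, LoadSeries]:
    """Generate alternating-feet load series sampled on the transmission clock.

    Per-step amplitude jitter (uniform on [0.92, 1.0], seeded) keeps steps
    from being carbon copies while never exceeding the configured peak load.
    """
    rng = np.random.default_rng(config.random_seed)
    step_period = 2 * 60_000.0 / profile.cadence_spm  # per-foot, ms
    n_samples = config.duration_ms // config.sample_period_ms
    t = np.arange(n_samples, dtype=float) * config.sample_period_ms
    amp, peak_phase = _sensor_params(profile)

    # count of step onsets strictly before duration, in step-period units;
    # computed fraction-free to dodge float drift at exact multiples
    threshold = config.duration_ms * profile.cadence_spm / 120_000.0

    series: dict[str, LoadSeries] = {}
    for foot, frac_offset in (("left", 0.0), ("right", 0.5)):
        n_steps = max(int(np.ceil(threshold - frac_offset)), 0)
        offset = frac_offset * step_period
        starts = (np.arange(n_steps) + frac_offset) * step_period
        # per-step jitter factors, drawn in a fixed order for determinism
        jitter = 0.92 + 0.08 * rng.random(n_steps)
        loads = np.zeros((n_samples, firmware.N_SENSORS))
        if n_samples and n_steps:
            phase_in_cycle = np.mod(t - offset, step_period)
            step_index = np.floor_divide(t - offset, step_period).astype(int)
            in_stance = (
                (t >= offset - 1e-9)
                & (phase_in_cycle < profile.contact_time_ms)
                & (step_index >= 0)
                & (step_index < n_steps)
            )
            u = phase_in_cycle / profile.contact_time_ms  # stance fraction
            step_jitter = jitter[np.clip(step_index, 0, n_steps - 1)]
            for s in range(firmware.N_SENSORS):
                d = u - peak_phase[s]
                env = np.where(np.abs(d) <= 0.5, np.cos(np.pi * d) ** 2, 0.0)
                g = np.where(in_stance, amp[s] * env * step_jitter, 0.0)
                g[g < TRIGGER_FORCE_G] = 0.0  # hardware dead zone
                loads[:, s] = g
        series[foot] = LoadSeries(
            foot=foot,
            timestamps_ms=t.astype(int),
            loads_g=loads,
            stance_starts_ms=starts,
        )
    return series


def loads_to_frames(
    loads: LoadSeries,
    curve: CalibrationCurve = DEFAULT_CURVE,
    profile: RunnerProfile = RunnerProfile(),
    config: SimConfig = SimConfig(),
) -> list[AdcFrame]:
    """Quantize loads to 12-bit ADC frames through the curve plus count noise.

    reading = clamp(floor(curve(load) + N(0, noise_sd)), 0, 4095); truncation
    mirrors ADC quantization.
    """
    rng = np.random.default_rng(config.random_seed + (1 if loads.foot == "left" else 2))
    expected = predict_reading(curve, loads.loads_g)
    if profile.noise_sd_counts > 0:
        expected = expected + rng.normal(0.0, profile.noise_sd_counts, expected.shape)
    readings = np.clip(np.floor(expected), 0, 4095).astype(int)
    return [
        AdcFrame(timestamp_ms=int(ts), readings=tuple(row), foot=loads.foot)
        for ts, row in zip(loads.timestamps_ms, readings)
    ]


def _synthetic_track(duration_ms: int) -> list[GpsPoint]:
    """Constant-pace straight-line track heading north from a fixed origin."""
    lat0, lon0 = _GPS_ORIGIN
    points = []
    for t in range(0, duration_ms + 1, _GPS_INTERVAL_MS):
        d_m = _GPS_SPEED_M_S * t / 1000.0
        points.append(GpsPoint(lat=lat0 + d_m / _M_PER_DEG_LAT, lon=lon0, t_ms=t))
    return points


def simulate_session(
    profile: RunnerProfile = RunnerProfile(),
    config: SimConfig = SimConfig(),
    curve: CalibrationCurve = DEFAULT_CURVE,
    fw_config: FirmwareConfig = DEFAULT_CONFIG,
) -> RunSession:
    """Full pipeline: loads → ADC → percent → gate → encode → decode → session.

    The returned session's percent streams are the *decoded* wire frames,
    timestamped at transmission time (the emulated Bluetooth arrival clock).
    Ground truth (step count, cadence, per-foot stance onsets) and the raw
    wire bytes are stored in ``session.meta``.
    """
    series = simulate_loads(profile, config)
    table = percent_table(curve)
    streams: dict[str, list[PercentVector]] = {}
    wire: dict[str, bytes] = {}
    arrival: dict[str, list[int]] = {}
    for foot in ("left", "right"):
        frames = loads_to_frames(series[foot], curve, profile, config)
        vectors = [firmware.to_percent_vector(f, curve, table) for f in frames]
        transmitted = [v for v in vectors if firmware.gate(v, fw_config)]
        encoded = firmware.encode_stream(transmitted, fw_config)
        times = [v.timestamp_ms for v in transmitted]
        decoded = firmware.decode_stream(encoded, timestamps=times)
        if decoded.errors:
            raise SimulationError(f"internal codec error: {decoded.errors}")
        streams[foot] = decoded.frames
        wire[foot] = encoded
        arrival[foot] = times

    true_steps = sum(len(series[f].stance_starts_ms) for f in ("left", "right"))
    true_cadence = (
        true_steps / config.duration_ms * 60_000.0 if config.duration_ms else 0.0
    )
    meta = {
        "profile": dataclasses.asdict(profile),
        "config": dataclasses.asdict(config),
        "curve": {"a": curve.a, "b": curve.b, "c": curve.c},
        "seed": config.random_seed,
        "ground_truth": {
            "step_count": true_steps,
            "cadence_spm": true_cadence,
            "stance_starts_ms": {
                f: [float(x) for x in series[f].stance_starts_ms]
                for f in ("left", "right")
            },
        },
        "arrival_t_ms": arrival,
    }
    session = RunSession(
        left=streams["left"],
        right=streams["right"],
        gps_track=_synthetic_track(config.duration_ms),
        started_at=0,
        meta=meta,
    )
    session.wire_bytes = wire  # raw frames for bundle export
    return session


# ---------------------------------------------------------------------------
# Session bundle IO: left.frames / right.frames / gps.csv / meta.json

def write_session_bundle(session: RunSession, directory: str | Path) -> Path:
    """Persist a session as a bundle directory (wire bytes + GPS CSV + meta)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    wire = getattr(session, "wire_bytes", None)
    for foot, stream in (("left", session.left), ("right", session.right)):
        data = wire[foot] if wire else firmware.encode_stream(stream)
        (directory / f"{foot}.frames").write_bytes(data)
    gps_lines = ["t_ms,lat,lon"] + [
        f"{p.t_ms},{p.lat:.7f},{p.lon:.7f}" for p in session.gps_track
    ]
    (directory / "gps.csv").write_text("\n".join(gps_lines) + "\n")
    meta = dict(session.meta)
    meta.setdefault(
        "arrival_t_ms",
        {
            "left": [v.timestamp_ms for v in session.left],
            "right": [v.timestamp_ms for v in session.right],
        },
    )
    meta["started_at"] = session.started_at
    (directory / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return directory


def read_session_bundle(directory: str | Path) -> RunSession:
    """Reconstruct a session from a bundle directory."""
    from .analytics import read_gps_csv

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    streams = {}
    for foot in ("left", "right"):
        data = (directory / f"{foot}.frames").read_bytes()
        times = meta.get("arrival_t_ms", {}).get(foot)
        decoded = firmware.decode_stream(data, timestamps=times)
        streams[foot] = decoded.frames
    track = read_gps_csv(directory / "gps.csv")
    return RunSession(
        left=streams["left"],
        right=streams["right"],
        gps_track=track,
        started_at=meta.get("started_at", 0),
        meta=meta,
    )
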