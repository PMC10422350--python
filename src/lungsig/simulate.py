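"""Seedable simulator for synchronized chest-sound + ECG recordings.

The generator reproduces the statistical structure the downstream analysis
measures, not physiological waveforms:

* metronome-paced breathing cycles (default 4 s: 2 s inhale, 2 s exhale);
* a band-limited (150-1000 Hz) sound burst gated over the inhale half whose
  amplitude is a monotone function of tidal volume, plus a slow (<2 Hz)
  chest-movement drift peaking mid-inhale;
* a periodic PQRST-shaped ECG whose beat amplitudes are attenuated by a
  factor (1 - rsa_modulation_depth) during inhalation (respiratory sinus
  arrhythmia seen as amplitude modulation);
* optional cough cycles: a short (~0.5 s) broadband transient well above
  normal-breath amplitude riding on a deep-inhalation drift excursion.

Units are arbitrary ADC-like amplitudes; only relative quantities matter
downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, FormatError, ParseError

__all__ = [
    "SimulationConfig",
    "CycleAnnotation",
    "MultimodalRecording",
    "generate_recording",
    "write_recording",
    "read_recording",
    "protocol_config",
]


def _default_burst_gain(tidal_volume_ml: float) -> float:
    """Default monotone tidal-volume -> burst-amplitude map (linear, 1.0 at 1000 mL)."""
    return tidal_volume_ml / 1000.0


# PQRST as Gaussian bumps: (amplitude, center offset from R [s], width [s])
_PQRST = (
    (0.12, -0.22, 0.030),
    (-0.15, -0.045, 0.012),
    (1.00, 0.0, 0.020),
    (-0.25, 0.045, 0.015),
    (0.30, 0.25, 0.050),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording session.

    Defaults follow the breathing protocol the analysis targets: 4 s cycles
    (2 s inhale + 2 s exhale) at 4 kHz per channel, tidal volumes in the
    500-1000 mL range, coughs exceeding 1000 mL.
    """

    n_cycles: int
    sampling_rate_hz: float = 4000.0
    cycle_duration_s: float = 4.0
    tidal_volume_ml: float = 1000.0
    cough_cycles: frozenset = frozenset()
    cough_tidal_volume_ml: float = 1200.0
    cough_gain_factor: float = 3.0
    heart_rate_bpm: float = 75.0
    rsa_modulation_depth: float = 0.3
    sound_burst_gain: Callable[[float], float] = field(default=_default_burst_gain)
    drift_amplitude: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be a positive integer")
        for name in ("sampling_rate_hz", "cycle_duration_s", "tidal_volume_ml",
                     "cough_tidal_volume_ml", "heart_rate_bpm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not 0.0 <= self.rsa_modulation_depth < 1.0:
            raise ConfigurationError("rsa_modulation_depth must lie in [0, 1)")
        n = self.cycle_duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "cycle_duration_s x sampling_rate_hz must be an integer sample count"
            )
        object.__setattr__(self, "cough_cycles", frozenset(self.cough_cycles))
        for c in self.cough_cycles:
            if not 0 <= c < self.n_cycles:
                raise ConfigurationError(f"cough cycle index {c} out of range")

    @property
    def samples_per_cycle(self) -> int:
        return round(self.cycle_duration_s * self.sampling_rate_hz)


@dataclass(frozen=True)
class CycleAnnotation:
    """Ground-truth window of one breathing cycle, in sample indices."""

    start: int
    inhale_end: int
    end: int
    tidal_volume_ml: float
    is_cough: bool


@dataclass
class MultimodalRecording:
    """Synchronized sound + ECG streams with per-cycle ground truth."""

    sampling_rate_hz: float
    sound: np.ndarray
    ecg: np.ndarray
    annotations: list

    def __post_init__(self) -> None:
        self.sound = np.asarray(self.sound, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        if self.sound.shape != self.ecg.shape or self.sound.ndim != 1:
            raise FormatError("sound and ecg must be 1-D sequences of equal length")
        n = self.sound.size
        pos = 0
        for ann in self.annotations:
            if ann.start != pos:
                raise FormatError("annotations must tile the recording without gaps")
            if not ann.start < ann.inhale_end < ann.end <= n:
                raise FormatError("annotation indices out of order or out of bounds")
            pos = ann.end
        if self.annotations and pos != n:
            raise FormatError("annotations do not cover the full recording")

    @property
    def n_samples(self) -> int:
        return self.sound.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def generate_recording(config: SimulationConfig) -> MultimodalRecording:
    """Generate one seeded recording; identical config => bitwise-identical output."""
    fs = config.sampling_rate_hz
    npc = config.samples_per_cycle
    n_half = npc // 2
    n = config.n_cycles * npc
    rng = np.random.default_rng(config.seed)

    sound = np.zeros(n)
    ecg = np.zeros(n)
    annotations: list[CycleAnnotation] = []

    burst_sos = sps.butter(4, (150.0, min(1000.0, 0.45 * fs)), btype="bandpass",
                           fs=fs, output="sos")
    inhale_gate = np.hanning(n_half)
    drift_bump = np.sin(np.pi * np.arange(n_half) / n_half)
    n_cough = round(0.5 * fs)
    cough_gate = np.hanning(n_cough)

    gain = config.sound_burst_gain
    for c in range(config.n_cycles):
        start = c * npc
        is_cough = c in config.cough_cycles
        # draw every random piece unconditionally so the stream stays aligned
        # across configs that differ only in tidal volume or cough set
        white = rng.standard_normal(n_half)
        cough_white = rng.standard_normal(n_cough)

        tv = config.cough_tidal_volume_ml if is_cough else config.tidal_volume_ml
        burst = sps.sosfilt(burst_sos, white) * inhale_gate
        sound[start:start + n_half] += gain(tv) * burst
        sound[start:start + n_half] += config.drift_amplitude * (tv / 1000.0) * drift_bump
        if is_cough:
            off = start + (n_half - n_cough) // 2
            amp = config.cough_gain_factor * gain(tv)
            sound[off:off + n_cough] += amp * cough_gate * cough_white
            sound[start:start + n_half] += 0.5 * config.drift_amplitude * drift_bump

        annotations.append(CycleAnnotation(start, start + n_half, start + npc, tv, is_cough))

    _add_ecg(ecg, config)

    if config.noise_sd > 0:
        sound += rng.normal(0.0, config.noise_sd, n)
        ecg += rng.normal(0.0, config.noise_sd, n)

    return MultimodalRecording(fs, sound, ecg, annotations)


def _add_ecg(ecg: np.ndarray, config: SimulationConfig) -> None:
    """Superpose PQRST beats, attenuating beats whose R peak falls in an inhale half."""
    fs = config.sampling_rate_hz
    n = ecg.size
    beat_period = 60.0 / config.heart_rate_bpm
    half_s = config.cycle_duration_s / 2.0
    t_beat = 0.4 * beat_period  # first R peak a fraction into the recording
    local_halfwidth = round(0.5 * fs)
    while t_beat < n / fs:
        phase = math.fmod(t_beat, config.cycle_duration_s)
        factor = (1.0 - config.rsa_modulation_depth) if phase < half_s else 1.0
        center = round(t_beat * fs)
        lo = max(0, center - local_halfwidth)
        hi = min(n, center + local_halfwidth)
        t_local = (np.arange(lo, hi) / fs) - t_beat
        beat = np.zeros(hi - lo)
        for amp, off, width in _PQRST:
            beat += amp * np.exp(-0.5 * ((t_local - off) / width) ** 2)
        ecg[lo:hi] += factor * beat
        t_beat += beat_period


def protocol_config(experiment: str, n_cycles: int = 5, seed: int = 0,
                    noise_sd: float = 0.0) -> SimulationConfig:
    """Config for one of the four protocol experiments.

    ``deep`` (1000 mL), ``moderate`` (750 mL), ``shallow`` (500 mL) breathe at a
    fixed 4 s cadence; ``cough`` makes every cycle a cough. RSA depth scales
    with tidal volume (0.3 at 1000 mL) so deeper breathing modulates the ECG
    more strongly.
    """
    volumes = {"deep": 1000.0, "moderate": 750.0, "shallow": 500.0, "cough": 1000.0}
    if experiment not in volumes:
        raise ConfigurationError(
            f"unknown experiment {experiment!r}; expected one of {sorted(volumes)}")
    tv = volumes[experiment]
    return SimulationConfig(
        n_cycles=n_cycles,
        tidal_volume_ml=tv,
        cough_cycles=frozenset(range(n_cycles)) if experiment == "cough" else frozenset(),
        rsa_modulation_depth=0.3 * tv / 1000.0,
        noise_sd=noise_sd,
        seed=seed,
    )


def write_recording(recording: MultimodalRecording, csv_path, annotations_path=None) -> None:
    """Write samples as ``time_s,sound,ecg`` CSV plus a JSON annotation sidecar.

    Floats are printed with 17 significant digits so the round trip is exact.
    """
    csv_path = Path(csv_path)
    if annotations_path is None:
        annotations_path = csv_path.with_suffix(".annotations.json")
    t = np.arange(recording.n_samples) / recording.sampling_rate_hz
    data = np.column_stack([t, recording.sound, recording.ecg])
    with open(csv_path, "w") as fh:
        fh.write("time_s,sound,ecg\n")
        np.savetxt(fh, data, fmt="%.17g", delimiter=",")
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "cycles": [
            {"start": a.start, "inhale_end": a.inhale_end, "end": a.end,
             "tidal_volume_ml": a.tidal_volume_ml, "is_cough": a.is_cough}
            for a in recording.annotations
        ],
    }
    Path(annotations_path).write_text(json.dumps(sidecar, indent=1))


def read_recording(csv_path, annotations_path=None) -> MultimodalRecording:
    """Inverse of :func:`write_recording`; raises ParseError/FormatError on bad files."""
    csv_path = Path(csv_path)
    if annotations_path is None:
        annotations_path = csv_path.with_suffix(".annotations.json")
    try:
        frame = pd.read_csv(csv_path, dtype=float, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{csv_path}: empty file, not a recording") from exc
    except ValueError as exc:
        raise ParseError(f"{csv_path}: {_locate_bad_line(csv_path)}") from exc
    missing = {"time_s", "sound", "ecg"} - set(frame.columns)
    if missing:
        raise FormatError(f"{csv_path}: missing column(s) {sorted(missing)}")
    if frame[["sound", "ecg"]].isna().any().any():
        raise ParseError(f"{csv_path}: {_locate_bad_line(csv_path)}")
    try:
        sidecar = json.loads(Path(annotations_path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{annotations_path}: invalid JSON at line {exc.lineno}") from exc
    try:
        annotations = [
            CycleAnnotation(int(c["start"]), int(c["inhale_end"]), int(c["end"]),
                            float(c["tidal_volume_ml"]), bool(c["is_cough"]))
            for c in sidecar["cycles"]
        ]
        fs = float(sidecar["sampling_rate_hz"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{annotations_path}: missing annotation field {exc}") from exc
    return MultimodalRecording(fs, frame["sound"].to_numpy(),
                               frame["ecg"].to_numpy(), annotations)


def _locate_bad_line(csv_path: Path) -> str:
    """Best-effort scan for the first non-numeric data line, for error messages."""
    with open(csv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1:
                continue
            parts = line.rstrip("\n").split(",")
            try:
                [float(p) for p in parts]
            except ValueError:
                return f"cannot parse line {lineno}: {line.strip()!r}"
            if len(parts) != 3:
                return f"wrong field count on line {lineno}"
    return "malformed numeric data"
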