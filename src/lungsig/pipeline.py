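"""End-to-end orchestration: recordings -> per-cycle features -> signature
matrices -> classification and group statistics.

The stages are pure functions of their inputs plus a :class:`PipelineConfig`,
so a fixed seed reproduces every report byte for byte. The synthetic study
helper mirrors the breathing protocol the method targets: metronome-paced
4 s cycles at tidal volumes 1000 / 750 / 500 mL plus a coughing condition,
a handful of cycles per condition for templates and as many held out for
evaluation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError
from .features import extract_cycle_features
from .fusion import (FusionResult, SignatureMatrix, TemplateLibrary,
                     ZoneBoundaries, _level_thresholds, build_signature_matrix,
                     classify)
from .simulate import MultimodalRecording, SimulationConfig, generate_recording
from .stats import GroupComparison, one_way_f_test

__all__ = [
    "PipelineConfig",
    "CycleSeries",
    "StudyResult",
    "signature_frame_rate",
    "recording_cycle_series",
    "build_template_library",
    "build_targets",
    "classify_cycles",
    "stats_report",
    "run_template_study",
]

_CONFIG_FIELDS = {"window_samples", "hop_samples", "polynomial_order",
                  "windows_per_matrix", "zone_boundaries", "alpha", "seed"}


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables shared by every stage; defaults follow the method's settings
    (250 ms / 1000-sample variance window, order-7 fits, 40-point frames)."""

    window_samples: int = 1000
    hop_samples: int = 1
    polynomial_order: int = 7
    windows_per_matrix: int = 40
    zone_boundaries: object = "auto"  # "auto" | "tertiles" | ((t1,t2),(t1,t2))
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_samples <= 1 or self.hop_samples < 1:
            raise ConfigurationError("invalid moving-variance window/hop")
        if self.polynomial_order < 1 or self.windows_per_matrix < 2:
            raise ConfigurationError("invalid polynomial order or frame size")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.zone_boundaries not in ("auto", "tertiles"):
            ZoneBoundaries(tuple(self.zone_boundaries[0]), tuple(self.zone_boundaries[1]))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        payload = json.loads(open(path).read())
        unknown = set(payload) - _CONFIG_FIELDS
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps({k: getattr(self, k) for k in sorted(_CONFIG_FIELDS)},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def signature_frame_rate(sampling_rate_hz: float, frame_samples: int) -> float:
    """Signature frames per second of raw signal (e.g. 4000 Hz / 40 = 100)."""
    if frame_samples < 1:
        raise ConfigurationError("frame_samples must be positive")
    return sampling_rate_hz / frame_samples


@dataclass
class CycleSeries:
    """Joint sound/ECG cumulative-AUC series of one breathing cycle."""

    cycle_index: int
    sound_cum: np.ndarray
    ecg_cum: np.ndarray
    tidal_volume_ml: Optional[float] = None
    is_cough: bool = False
    condition: Optional[str] = None


def recording_cycle_series(recording: MultimodalRecording,
                           config: PipelineConfig = PipelineConfig(),
                           condition: Optional[str] = None) -> List[CycleSeries]:
    """Run the AUC chain on both channels and pair the cumulative series."""
    kw = dict(window_samples=config.window_samples, hop_samples=config.hop_samples,
              order=config.polynomial_order, n_points=config.windows_per_matrix)
    sound = extract_cycle_features(recording, "sound", **kw)
    ecg = extract_cycle_features(recording, "ecg", **kw)
    return [
        CycleSeries(s.cycle_index, s.cumulative_auc, e.cumulative_auc,
                    tidal_volume_ml=s.tidal_volume_ml, is_cough=s.is_cough,
                    condition=condition)
        for s, e in zip(sound, ecg)
    ]


def _resolve_boundaries(config: PipelineConfig,
                        cycles_by_condition: Dict[str, Sequence[CycleSeries]]) -> ZoneBoundaries:
    """Zone thresholds per the config: explicit, pooled tertiles, or (the
    default) condition-level midpoints falling back to tertiles when fewer
    than three distinct levels exist."""
    if config.zone_boundaries not in ("auto", "tertiles"):
        return ZoneBoundaries(tuple(config.zone_boundaries[0]),
                              tuple(config.zone_boundaries[1]))
    pooled = [c for cycles in cycles_by_condition.values() for c in cycles]

    def resolve(channel: str) -> tuple:
        values = [c.sound_cum if channel == "sound" else c.ecg_cum for c in pooled]
        if config.zone_boundaries == "auto":
            finals = {n: [float((c.sound_cum if channel == "sound" else c.ecg_cum)[-1])
                          for c in cyc]
                      for n, cyc in cycles_by_condition.items()}
            try:
                return _level_thresholds(finals, channel)
            except ConfigurationError:
                pass  # fewer than three distinct levels on this channel
        return tuple(np.quantile(np.concatenate(values), [1 / 3, 2 / 3]))

    return ZoneBoundaries(resolve("sound"), resolve("ecg"))


def build_targets(cycles: Sequence[CycleSeries],
                  boundaries: ZoneBoundaries) -> List[SignatureMatrix]:
    """One target signature matrix per cycle."""
    return [
        build_signature_matrix(c.sound_cum, c.ecg_cum, boundaries,
                               k=c.cycle_index, label=c.condition)
        for c in cycles
    ]


def build_template_library(cycles_by_condition: Dict[str, Sequence[CycleSeries]],
                           config: PipelineConfig = PipelineConfig()) -> TemplateLibrary:
    """Per-condition mean signature matrices with shared zone boundaries.

    Boundaries default to per-channel condition-level midpoints (tertiles of
    the pooled cumulative-AUC values when levels are too few or too close),
    and are persisted with the library so targets are zoned identically.
    """
    if not cycles_by_condition:
        raise ConfigurationError("no template conditions supplied")
    boundaries = _resolve_boundaries(config, cycles_by_condition)
    library = TemplateLibrary(boundaries=boundaries)
    for name, cycles in cycles_by_condition.items():
        per_cycle = build_targets(cycles, boundaries)
        library.add(name, TemplateLibrary.mean_template(per_cycle, label=name))
    return library


def classify_cycles(cycles: Sequence[CycleSeries],
                    library: TemplateLibrary) -> List[FusionResult]:
    """Zone held-out cycles with the library's boundaries and match templates."""
    if library.boundaries is None:
        raise ConfigurationError("template library carries no zone boundaries")
    return [classify(t, library) for t in build_targets(cycles, library.boundaries)]


def stats_report(finals_by_condition: Dict[str, Dict[str, Sequence[float]]],
                 comparisons: Sequence[Tuple[str, str]] = (),
                 alpha: float = 0.05) -> dict:
    """Two-group F tests per channel over per-cycle final cumulative AUCs.

    ``finals_by_condition[condition][channel]`` is the list of per-cycle
    values; the report mirrors one row per comparison with sound and ECG
    F / p values plus the shared critical value.
    """
    if not comparisons:
        names = list(finals_by_condition)
        comparisons = [(names[0], other) for other in names[1:]]
    rows = []
    for a, b in comparisons:
        row: dict = {"groups": [a, b], "alpha": alpha}
        for channel in ("sound", "ecg"):
            cmp = one_way_f_test(finals_by_condition[a][channel],
                                 finals_by_condition[b][channel],
                                 alpha=alpha, labels=(a, b))
            row[f"f_{channel}"] = cmp.f_value
            row[f"p_{channel}"] = cmp.p_value
            row["f_critical"] = cmp.f_critical
            row["n_per_group"] = list(cmp.n_per_group)
        rows.append(row)
    return {"alpha": alpha, "comparisons": rows}


@dataclass
class StudyResult:
    """Outcome of the synthetic template-classification study."""

    accuracy: float
    n_test_cycles: int
    mean_sound_auc: Dict[str, float]
    comparison_1000_vs_500: GroupComparison
    comparison_1000_vs_cough: GroupComparison
    library: TemplateLibrary
    results: List[FusionResult]
    truth: List[str]


_STUDY_CONDITIONS = (("1000mL", 1000.0, False), ("750mL", 750.0, False),
                     ("500mL", 500.0, False), ("cough", 1000.0, True))


def run_template_study(seed: int = 0, n_train: int = 5, n_test: int = 5,
                       noise_sd: float = 0.0,
                       config: PipelineConfig = PipelineConfig()) -> StudyResult:
    """Simulate the four-condition protocol, learn templates, classify held-out
    cycles, and run the 1000-vs-500 and 1000-vs-cough F tests on sound AUCs.

    Each condition gets ``n_train + n_test`` cycles from its own child seed;
    templates (and tertile zone boundaries) come from the training cycles only.
    """
    child_seeds = [int(s) & 0x7FFFFFFF
                   for s in np.random.SeedSequence(seed).generate_state(len(_STUDY_CONDITIONS))]
    train: Dict[str, List[CycleSeries]] = {}
    test: List[CycleSeries] = []
    finals: Dict[str, Dict[str, List[float]]] = {}
    mean_auc: Dict[str, float] = {}
    for (name, tv, is_cough), child_seed in zip(_STUDY_CONDITIONS, child_seeds):
        n_cycles = n_train + n_test
        sim = SimulationConfig(
            n_cycles=n_cycles,
            tidal_volume_ml=tv,
            cough_cycles=frozenset(range(n_cycles)) if is_cough else frozenset(),
            rsa_modulation_depth=0.3 * tv / 1000.0,
            noise_sd=noise_sd,
            seed=child_seed,
        )
        cycles = recording_cycle_series(generate_recording(sim), config, condition=name)
        train[name] = cycles[:n_train]
        test.extend(cycles[n_train:])
        finals[name] = {
            "sound": [float(c.sound_cum[-1]) for c in cycles[:n_train]],
            "ecg": [float(c.ecg_cum[-1]) for c in cycles[:n_train]],
        }
        mean_auc[name] = float(np.mean([c.sound_cum[-1] for c in cycles]))

    library = build_template_library(train, config)
    results = classify_cycles(test, library)
    truth = [c.condition for c in test]
    correct = sum(r.label == t for r, t in zip(results, truth))
    accuracy = correct / len(results) if results else float("nan")
    cmp_500 = one_way_f_test(finals["1000mL"]["sound"], finals["500mL"]["sound"],
                             alpha=config.alpha, labels=("1000mL", "500mL"))
    cmp_cough = one_way_f_test(finals["1000mL"]["sound"], finals["cough"]["sound"],
                               alpha=config.alpha, labels=("1000mL", "cough"))
    return StudyResult(accuracy, len(results), mean_auc, cmp_500, cmp_cough,
                       library, results, truth)
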