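"""Signature-matrix sensor fusion and template classification.

The fusion step compresses one breathing cycle of two synchronized channels
into a 3x3 probability map. Per cycle, the sound (channel X) and ECG
(channel Y) cumulative-AUC series are sampled at a fixed number of points
(default 40; at 4 kHz that is 100 frames per second of raw signal). Each
point's X value falls into one of three zones (lower / middle / upper,
half-open lower-inclusive intervals set by two thresholds), likewise Y, and
element ``sig[i, j]`` of the signature matrix is the fraction of points with
Y zone ``i+1`` and X zone ``j+1``. A freshly built matrix sums to exactly 1.

Classification compares a measured matrix (target) against stored condition
templates by the element-wise squared difference summed over all nine cells
(SSE); the template with minimal SSE wins.

Zone thresholds are nowhere standardized; the default here is data driven:
per-channel tertiles of the pooled template-condition cumulative-AUC values,
persisted alongside the template library so targets are zoned identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError

__all__ = [
    "ZoneBoundaries",
    "SignatureMatrix",
    "TemplateLibrary",
    "FusionResult",
    "assign_zone",
    "assign_zones",
    "build_signature_matrix",
    "squared_difference",
    "sse",
    "classify",
    "reference_signatures",
]


@dataclass(frozen=True)
class ZoneBoundaries:
    """Two increasing thresholds per channel splitting values into 3 zones."""

    sound: tuple
    ecg: tuple

    def __post_init__(self) -> None:
        for name, (t1, t2) in (("sound", self.sound), ("ecg", self.ecg)):
            if not t1 < t2:
                raise ConfigurationError(f"{name} thresholds must be strictly increasing")

    @classmethod
    def from_tertiles(cls, sound_values, ecg_values) -> "ZoneBoundaries":
        """Thresholds at the 1/3 and 2/3 quantiles of pooled per-channel values."""
        s = np.quantile(np.asarray(sound_values, dtype=float), [1 / 3, 2 / 3])
        e = np.quantile(np.asarray(ecg_values, dtype=float), [1 / 3, 2 / 3])
        return cls(tuple(s), tuple(e))

    @classmethod
    def from_condition_levels(cls, sound_finals: Dict[str, Sequence[float]],
                              ecg_finals: Dict[str, Sequence[float]]) -> "ZoneBoundaries":
        """Anchor the three zones to the lowest three condition levels.

        Per channel, the mean final cumulative AUC of each template condition
        defines a level; levels closer than 1% of the overall spread merge
        (e.g. coughing and deep breathing coincide on the ECG channel), and
        the thresholds sit midway between the three lowest distinct levels.
        Conditions above the third level saturate the upper zone. Raises
        ConfigurationError when fewer than three distinct levels exist.
        """
        return cls(_level_thresholds(sound_finals, "sound"),
                   _level_thresholds(ecg_finals, "ecg"))


@dataclass
class SignatureMatrix:
    """3x3 probability map; rows follow ECG (Y) zones, columns sound (X) zones."""

    values: np.ndarray
    sample_point: Optional[int] = None
    n_samples: Optional[int] = None
    label: Optional[str] = None
    kind: Optional[str] = None  # template | target

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3, 3):
            raise FormatError("signature matrix must be 3x3")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise FormatError("signature matrix elements must lie in [0, 1]")
        if self.values.sum() > 1 + 1e-9:
            raise FormatError("signature matrix elements must sum to at most 1")


def _level_thresholds(finals_by_condition: Dict[str, Sequence[float]],
                      channel: str) -> tuple:
    means = sorted(float(np.mean(v)) for v in finals_by_condition.values())
    spread = means[-1] - means[0]
    if spread <= 0:
        raise ConfigurationError(f"{channel}: condition levels are indistinguishable")
    levels = [means[0]]
    for m in means[1:]:
        if m - levels[-1] > 0.01 * spread:
            levels.append(m)
    if len(levels) < 3:
        raise ConfigurationError(
            f"{channel}: need >= 3 distinct condition levels, found {len(levels)}")
    return ((levels[0] + levels[1]) / 2.0, (levels[1] + levels[2]) / 2.0)


def assign_zone(value: float, boundaries) -> int:
    """Zone of one value: 1 below t1, 2 in [t1, t2), 3 at or above t2."""
    return int(assign_zones([value], boundaries)[0])


def assign_zones(values, boundaries) -> np.ndarray:
    """Vectorized half-open, lower-inclusive zone assignment."""
    t1, t2 = boundaries
    if not t1 < t2:
        raise ConfigurationError("zone thresholds must be strictly increasing")
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ConfigurationError("cannot zone non-finite values")
    return np.searchsorted([t1, t2], values, side="right") + 1


def build_signature_matrix(x_values, y_values, boundaries: ZoneBoundaries,
                           k: Optional[int] = None,
                           label: Optional[str] = None) -> SignatureMatrix:
    """Joint zone-frequency matrix of the two channels at sample point ``k``.

    ``sig[i, j]`` = (#points with X zone j+1 and Y zone i+1) / n; every point
    is counted, so the matrix sums to exactly 1.
    """
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)
    if x_values.shape != y_values.shape or x_values.ndim != 1:
        raise FormatError("x and y series must be 1-D and of equal length")
    n = x_values.size
    if n == 0:
        raise FormatError("cannot build a signature matrix from zero points")
    cols = assign_zones(x_values, boundaries.sound) - 1
    rows = assign_zones(y_values, boundaries.ecg) - 1
    counts = np.zeros((3, 3))
    np.add.at(counts, (rows, cols), 1.0)
    return SignatureMatrix(counts / n, sample_point=k, n_samples=n,
                           label=label, kind="target")


def squared_difference(template: SignatureMatrix, target: SignatureMatrix) -> np.ndarray:
    """Element-wise squared difference d_ij = (template_ij - target_ij)^2."""
    if template.values.shape != target.values.shape:
        raise FormatError("signature matrices must share the 3x3 shape")
    return (template.values - target.values) ** 2


def sse(template: SignatureMatrix, target: SignatureMatrix) -> float:
    """Sum of the nine squared differences; 0 iff the matrices are identical."""
    return float(squared_difference(template, target).sum())


@dataclass
class TemplateLibrary:
    """Ordered, uniquely named reference signature matrices (+ zone boundaries)."""

    entries: Dict[str, SignatureMatrix] = field(default_factory=dict)
    boundaries: Optional[ZoneBoundaries] = None

    def add(self, name: str, matrix: SignatureMatrix) -> None:
        if name in self.entries:
            raise ConfigurationError(f"duplicate template name {name!r}")
        self.entries[name] = matrix

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def mean_template(matrices: Sequence[SignatureMatrix],
                      label: Optional[str] = None) -> SignatureMatrix:
        """Element-wise mean of per-cycle matrices, the stored condition template."""
        if not matrices:
            raise ConfigurationError("cannot average zero matrices")
        mean = np.mean([m.values for m in matrices], axis=0)
        n = sum(m.n_samples or 0 for m in matrices)
        return SignatureMatrix(mean, n_samples=n or None, label=label, kind="template")

    def to_json(self, path) -> None:
        payload = {
            "boundaries": None if self.boundaries is None else {
                "sound": list(self.boundaries.sound),
                "ecg": list(self.boundaries.ecg),
            },
            "entries": [
                {"name": name, "condition": m.label, "kind": m.kind or "template",
                 "n_samples": m.n_samples, "values": m.values.tolist()}
                for name, m in self.entries.items()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TemplateLibrary":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid template JSON ({exc})") from exc
        lib = cls()
        b = payload.get("boundaries")
        if b:
            lib.boundaries = ZoneBoundaries(tuple(b["sound"]), tuple(b["ecg"]))
        for entry in payload.get("entries", []):
            lib.add(entry["name"], SignatureMatrix(
                np.array(entry["values"]), n_samples=entry.get("n_samples"),
                label=entry.get("condition"), kind=entry.get("kind", "template")))
        return lib


@dataclass
class FusionResult:
    """Outcome of matching one target against a template library."""

    sse_by_template: Dict[str, float]
    label: str
    margin: float
    tie: bool


def classify(target: SignatureMatrix, library: TemplateLibrary) -> FusionResult:
    """Assign the template with minimal SSE; ties break by insertion order."""
    if len(library) == 0:
        raise ConfigurationError("template library is empty")
    errors = {name: sse(m, target) for name, m in library.entries.items()}
    ordered = sorted(errors.items(), key=lambda kv: kv[1])
    label, best = min(errors.items(), key=lambda kv: kv[1])  # insertion-order tie-break
    second = ordered[1][1] if len(ordered) > 1 else float("inf")
    return FusionResult(errors, label, second - best, tie=bool(second == best))


def reference_signatures() -> TemplateLibrary:
    """Bundled reference matrices: two subjects, three conditions, two templates."""
    text = resources.files("lungsig").joinpath("data/reference_signatures.json").read_text()
    payload = json.loads(text)
    lib = TemplateLibrary()
    for entry in payload["entries"]:
        lib.add(entry["name"], SignatureMatrix(
            np.array(entry["values"]), label=entry["condition"], kind=entry["kind"]))
    return lib
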