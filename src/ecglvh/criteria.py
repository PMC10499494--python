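"""ECG voltage criteria for left ventricular hypertrophy.

Four criteria are computed from per-beat R/S magnitudes:

* **Witteles–Somani (WS)** — for each adjacent precordial pair (V1–V2 ...
  V5–V6), S(Vi) + R(Vi+1); the visual correlate is QRS overlap between
  neighbouring chest leads. Positive when the statistic *exceeds* 20 mm
  (2 mV at 10 mm/mV) — strict inequality.
* **Sokolow–Lyon** — S(V1) + R(V5) and S(V1) + R(V6); cutoff 35 mm (≥).
* **Cornell** — R(aVL) + S(V3); sex-specific cutoffs 28 mm male / 20 mm
  female (≥).
* **Peguero–Lo Presti** — deepest S in any available lead plus S(V4)
  (V4 may serve as both terms); cutoffs 28 mm male / 23 mm female (≥).

Each criterion is reduced to a single ECG-level statistic, the **MMCV**:
the median over beats within each lead combination, then the maximum over
combinations. Binary calls compare the MMCV against the threshold; the same
statistic feeds threshold-independent ROC analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import DEFAULT_CALIBRATION_MM_PER_MV, ECGRecord, mm_to_mv
from .qrs import (FLAG_TOO_FEW_BEATS, BeatSet, ChristovParams, detect_beats,
                  qc_flags)
from .waves import AmplitudeMatrix, measure_amplitudes

WS = "WS"
SOKOLOW_LYON = "SOKOLOW_LYON"
CORNELL = "CORNELL"
PEGUERO_LO_PRESTI = "PEGUERO_LO_PRESTI"
CRITERION_NAMES = (WS, SOKOLOW_LYON, CORNELL, PEGUERO_LO_PRESTI)

_PRECORDIAL = ("V1", "V2", "V3", "V4", "V5", "V6")


class QCError(RuntimeError):
    """Raised when a record fails quality control and no override is given."""


@dataclass
class ThresholdConfig:
    """Criterion thresholds in display millimetres, converted to mV once.

    The WS sex adjustment (off by default) shifts the threshold by
    ``ws_sex_offset_mm``; the default direction lowers the female threshold
    (raising sensitivity in females), ``ws_adjust_direction="raise_male"``
    raises the male threshold instead.
    """

    calibration_mm_per_mv: float = DEFAULT_CALIBRATION_MM_PER_MV
    ws_mm: float = 20.0
    sokolow_mm: float = 35.0
    cornell_male_mm: float = 28.0
    cornell_female_mm: float = 20.0
    peguero_male_mm: float = 28.0
    peguero_female_mm: float = 23.0
    ws_sex_adjusted: bool = False
    ws_sex_offset_mm: float = 10.0
    ws_adjust_direction: str = "lower_female"   # or "raise_male"
    # strict: positive requires value > threshold; otherwise >=
    strict: dict[str, bool] = field(default_factory=lambda: {
        WS: True, SOKOLOW_LYON: False, CORNELL: False, PEGUERO_LO_PRESTI: False})

    def __post_init__(self) -> None:
        if self.ws_adjust_direction not in ("lower_female", "raise_male"):
            raise ValueError(f"unknown ws_adjust_direction {self.ws_adjust_direction!r}")
        for name, mm in (("ws", self.ws_mm), ("sokolow", self.sokolow_mm),
                         ("cornell_male", self.cornell_male_mm),
                         ("cornell_female", self.cornell_female_mm),
                         ("peguero_male", self.peguero_male_mm),
                         ("peguero_female", self.peguero_female_mm)):
            if mm_to_mv(mm, self.calibration_mm_per_mv) <= 0:
                raise ValueError(f"{name} threshold must be positive after conversion")
        if self.ws_sex_adjusted:
            adjusted = self.ws_mm - self.ws_sex_offset_mm \
                if self.ws_adjust_direction == "lower_female" else self.ws_mm
            if mm_to_mv(adjusted, self.calibration_mm_per_mv) <= 0:
                raise ValueError("sex-adjusted WS threshold must remain positive")

    def _resolve_sex(self, sex: str, criterion: str) -> str:
        if sex in ("male", "female"):
            return sex
        warnings.warn(
            f"{criterion}: sex unknown, falling back to the stricter male cutoff",
            stacklevel=3)
        return "male"

    def threshold_mv(self, criterion: str, sex: str = "unknown") -> float:
        """The threshold actually applied, in mV."""
        cal = self.calibration_mm_per_mv
        if criterion == WS:
            mm = self.ws_mm
            if self.ws_sex_adjusted:
                sex_r = self._resolve_sex(sex, criterion)
                if self.ws_adjust_direction == "lower_female" and sex_r == "female":
                    mm = self.ws_mm - self.ws_sex_offset_mm
                elif self.ws_adjust_direction == "raise_male" and sex_r == "male":
                    mm = self.ws_mm + self.ws_sex_offset_mm
            return mm_to_mv(mm, cal)
        if criterion == SOKOLOW_LYON:
            return mm_to_mv(self.sokolow_mm, cal)
        if criterion == CORNELL:
            sex_r = self._resolve_sex(sex, criterion)
            mm = self.cornell_male_mm if sex_r == "male" else self.cornell_female_mm
            return mm_to_mv(mm, cal)
        if criterion == PEGUERO_LO_PRESTI:
            sex_r = self._resolve_sex(sex, criterion)
            mm = self.peguero_male_mm if sex_r == "male" else self.peguero_female_mm
            return mm_to_mv(mm, cal)
        raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class CriterionResult:
    """Per-record output of one criterion."""

    criterion_name: str
    per_beat_values_mv: np.ndarray          # (n_beats, n_combinations)
    combination_labels: list[str]
    per_combination_median_mv: np.ndarray
    mmcv_mv: float
    threshold_mv: float
    sex_used: str
    positive: bool

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion_name,
            "combination_labels": self.combination_labels,
            "combination_medians_mv": [round(float(v), 6)
                                       for v in self.per_combination_median_mv],
            "mmcv_mv": round(float(self.mmcv_mv), 6),
            "threshold_mv": float(self.threshold_mv),
            "sex_used": self.sex_used,
            "positive": bool(self.positive),
        }


# ---------------------------------------------------------------------------
# Per-beat combination values
# ---------------------------------------------------------------------------

def ws_per_beat(amps: AmplitudeMatrix) -> tuple[np.ndarray, list[str]]:
    """S(Vi) + R(Vi+1) for the five adjacent precordial pairs."""
    cols, labels = [], []
    for i in range(5):
        a, b = _PRECORDIAL[i], _PRECORDIAL[i + 1]
        cols.append(amps.s(a) + amps.r(b))
        labels.append(f"{a}-{b}")
    return np.column_stack(cols), labels


def sokolow_per_beat(amps: AmplitudeMatrix) -> tuple[np.ndarray, list[str]]:
    """S(V1) + R(V5) and S(V1) + R(V6)."""
    values = np.column_stack([amps.s("V1") + amps.r("V5"),
                              amps.s("V1") + amps.r("V6")])
    return values, ["SV1+RV5", "SV1+RV6"]


def cornell_per_beat(amps: AmplitudeMatrix) -> tuple[np.ndarray, list[str]]:
    """R(aVL) + S(V3)."""
    return (amps.r("aVL") + amps.s("V3"))[:, None], ["RaVL+SV3"]


def peguero_per_beat(amps: AmplitudeMatrix) -> tuple[np.ndarray, list[str]]:
    """Deepest S in any available lead plus S(V4).

    The search spans every measured lead; when V4 itself carries the deepest
    S it contributes both terms, per the published criterion.
    """
    deepest = amps.s_amp_mv.max(axis=1)
    return (deepest + amps.s("V4"))[:, None], ["SD+SV4"]


_PER_BEAT = {
    WS: ws_per_beat,
    SOKOLOW_LYON: sokolow_per_beat,
    CORNELL: cornell_per_beat,
    PEGUERO_LO_PRESTI: peguero_per_beat,
}


def mmcv(per_beat_values: np.ndarray) -> float:
    """Maximum over combinations of the median over beats.

    The median of an even beat count is the mean of the middle two values.
    """
    per_beat_values = np.asarray(per_beat_values, dtype=float)
    if per_beat_values.ndim != 2 or per_beat_values.size == 0:
        raise ValueError("per-beat value matrix must be 2-D and non-empty")
    return float(np.median(per_beat_values, axis=0).max())


def classify(value_mv: float, criterion: str, sex: str = "unknown",
             config: ThresholdConfig | None = None) -> bool:
    """Binary LVH call for one criterion value against its threshold."""
    config = config or ThresholdConfig()
    threshold = config.threshold_mv(criterion, sex)
    if config.strict.get(criterion, False):
        return value_mv > threshold
    return value_mv >= threshold


def compute_criterion(criterion: str, amps: AmplitudeMatrix,
                      sex: str = "unknown",
                      config: ThresholdConfig | None = None) -> CriterionResult:
    """Per-beat values, combination medians, MMCV and the binary call."""
    config = config or ThresholdConfig()
    if criterion not in _PER_BEAT:
        raise ValueError(f"unknown criterion {criterion!r}")
    values, labels = _PER_BEAT[criterion](amps)
    medians = np.median(values, axis=0)
    statistic = float(medians.max())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # one unknown-sex warning is enough
        threshold = config.threshold_mv(criterion, sex)
    positive = classify(statistic, criterion, sex, config)
    return CriterionResult(criterion, values, labels, medians, statistic,
                           threshold, sex, positive)


# ---------------------------------------------------------------------------
# End-to-end record evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecordEvaluation:
    """Full per-record output: QC flags plus one CriterionResult each."""

    record_id: str
    flags: set[str]
    results: dict[str, CriterionResult]
    n_beats: int

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "n_beats": self.n_beats,
            "qc_flags": sorted(self.flags),
            "criteria": {name: res.to_dict() for name, res in self.results.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_record(record: ECGRecord, config: ThresholdConfig | None = None,
                    criteria: tuple[str, ...] = CRITERION_NAMES,
                    detector_params: ChristovParams | None = None,
                    qc_override: bool = False) -> RecordEvaluation:
    """Detection → measurement → per-beat criteria → MMCV → binary calls.

    Deterministic for fixed input and configuration. Raises :class:`QCError`
    when fewer than three beats are detected, unless ``qc_override``.
    """
    config = config or ThresholdConfig()
    unknown = [c for c in criteria if c not in CRITERION_NAMES]
    if unknown:
        raise ValueError(f"unknown criteria: {', '.join(unknown)}")
    record.require_leads()
    beats = detect_beats(record, detector_params)
    if beats.n_beats < 1 or (FLAG_TOO_FEW_BEATS in beats.flags and not qc_override):
        raise QCError(
            f"record {record.record_id}: QC failure ({', '.join(sorted(beats.flags)) or 'no beats'}); "
            f"pass qc_override=True to force evaluation")
    amps = measure_amplitudes(record, beats, detector_params)
    flags = qc_flags(record, beats, amps, detector_params)
    results = {c: compute_criterion(c, amps, record.sex, config) for c in criteria}
    return RecordEvaluation(record.record_id, flags, results, amps.n_beats)
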