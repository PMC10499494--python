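"""Per-beat, per-lead R/S amplitude and QRS-duration measurement.

R and S are defined as the extremal positive and negative deviations from an
isoelectric baseline inside a fixed window around the fiducial — not by
sequence-order Q/R/S labelling — so biphasic and RSR' complexes collapse
safely onto the two magnitudes every voltage criterion consumes. The
baseline is the median of the PR segment (120 to 60 ms before the fiducial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ECGRecord
from .qrs import BeatSet, ChristovParams, difference_lead

QRS_PRE_MS = 60.0      # window start before the fiducial
QRS_POST_MS = 80.0     # window end after the fiducial
BASELINE_FROM_MS = 120.0
BASELINE_TO_MS = 60.0
QRS_DUR_SEARCH_MS = 100.0   # complex-lead search half-window for duration
QRS_DUR_FRACTION = 0.10     # of the beat-local complex-lead peak


@dataclass
class AmplitudeMatrix:
    """Beat-by-lead amplitude measurements in mV.

    ``r_amp_mv`` and ``s_amp_mv`` are non-negative magnitudes; ``s_amp_mv``
    stores the depth of the S deflection below baseline.
    """

    r_amp_mv: np.ndarray            # (n_beats, n_leads)
    s_amp_mv: np.ndarray            # (n_beats, n_leads)
    baseline_mv: np.ndarray         # (n_beats, n_leads)
    qrs_duration_ms: np.ndarray     # (n_beats,)
    lead_names: list[str]
    fiducial_samples: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    baseline_fallback: bool = False

    def __post_init__(self) -> None:
        if np.any(self.r_amp_mv < 0) or np.any(self.s_amp_mv < 0):
            raise ValueError("amplitudes must be non-negative magnitudes")
        if self.r_amp_mv.shape != self.s_amp_mv.shape:
            raise ValueError("R and S matrices must share a shape")
        if self.r_amp_mv.shape[1] != len(self.lead_names):
            raise ValueError("lead_names must align with matrix columns")

    @property
    def n_beats(self) -> int:
        return self.r_amp_mv.shape[0]

    def lead_index(self, name: str) -> int:
        try:
            return self.lead_names.index(name)
        except ValueError:
            raise KeyError(f"no measured lead {name!r}") from None

    def r(self, lead: str) -> np.ndarray:
        return self.r_amp_mv[:, self.lead_index(lead)]

    def s(self, lead: str) -> np.ndarray:
        return self.s_amp_mv[:, self.lead_index(lead)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format audit table: one row per beat per lead."""
        rows = []
        for b in range(self.n_beats):
            for li, lead in enumerate(self.lead_names):
                rows.append({
                    "beat": b, "lead": lead,
                    "r_mv": self.r_amp_mv[b, li],
                    "s_mv": self.s_amp_mv[b, li],
                    "baseline_mv": self.baseline_mv[b, li],
                    "qrs_duration_ms": self.qrs_duration_ms[b],
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def estimate_baseline(lead_signal: np.ndarray, fiducial: int,
                      sampling_rate_hz: float) -> tuple[float, bool]:
    """Median of the PR-segment window before the fiducial.

    Returns ``(baseline_mV, used_fallback)``; when the window falls entirely
    outside the signal the median of the whole lead is used and flagged.
    """
    lead_signal = np.asarray(lead_signal, dtype=float)
    n = lead_signal.size
    if not 0 <= fiducial < n:
        raise ValueError(f"fiducial {fiducial} outside signal of length {n}")
    lo = fiducial - int(round(BASELINE_FROM_MS / 1000 * sampling_rate_hz))
    hi = fiducial - int(round(BASELINE_TO_MS / 1000 * sampling_rate_hz))
    lo_c, hi_c = max(lo, 0), max(min(hi, n), 0)
    if hi_c <= lo_c:
        return float(np.median(lead_signal)), True
    return float(np.median(lead_signal[lo_c:hi_c])), False


def _qrs_duration_ms(diff_lead: np.ndarray, fiducial: int,
                     sampling_rate_hz: float) -> float:
    """QRS width from the cross-lead difference signal.

    Span between the first and last crossings of ``QRS_DUR_FRACTION`` of the
    beat-local peak inside the search window. First-to-last (rather than a
    contiguous region) bridges the zero-derivative dips at wave apices.
    """
    half = int(round(QRS_DUR_SEARCH_MS / 1000 * sampling_rate_hz))
    lo, hi = max(fiducial - half, 0), min(fiducial + half, diff_lead.size)
    window = diff_lead[lo:hi]
    if window.size == 0:
        return 0.0
    level = QRS_DUR_FRACTION * float(window.max())
    above = np.nonzero(window >= level)[0]
    if above.size == 0:
        return 0.0
    return (above[-1] - above[0] + 1) / sampling_rate_hz * 1000.0


def measure_amplitudes(record: ECGRecord, beats: BeatSet,
                       params: ChristovParams | None = None,
                       diff_lead: np.ndarray | None = None) -> AmplitudeMatrix:
    """Measure R/S magnitudes and QRS duration for every beat and lead.

    Beats whose measurement window crosses the record edges are dropped
    rather than padded; amplitudes are never fabricated.
    """
    if beats.n_beats < 1:
        raise ValueError(f"record {record.record_id}: no beats to measure")
    fs = record.sampling_rate_hz
    pre = int(round(QRS_PRE_MS / 1000 * fs))
    post = int(round(QRS_POST_MS / 1000 * fs))
    n = record.n_samples
    if diff_lead is None:
        diff_lead = difference_lead(record, params)

    kept = [f for f in beats.fiducial_samples if f - pre >= 0 and f + post < n]
    if not kept:
        raise ValueError(f"record {record.record_id}: all beats fall on record edges")

    n_beats, n_leads = len(kept), len(record.lead_names)
    r_amp = np.zeros((n_beats, n_leads))
    s_amp = np.zeros((n_beats, n_leads))
    baseline = np.zeros((n_beats, n_leads))
    durations = np.zeros(n_beats)
    any_fallback = False

    for b, fid in enumerate(kept):
        durations[b] = _qrs_duration_ms(diff_lead, fid, fs)
        for li in range(n_leads):
            sig = record.signals[li]
            base, fallback = estimate_baseline(sig, fid, fs)
            any_fallback = any_fallback or fallback
            window = sig[fid - pre: fid + post + 1]
            r_amp[b, li] = max(float(window.max()) - base, 0.0)
            s_amp[b, li] = max(base - float(window.min()), 0.0)
            baseline[b, li] = base

    return AmplitudeMatrix(r_amp, s_amp, baseline, durations,
                           list(record.lead_names),
                           fiducial_samples=np.asarray(kept, dtype=int),
                           baseline_fallback=any_fallback)
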