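"""QRS detection with the Christov combined-adaptive-threshold algorithm.

Beats are found once per record on a cross-lead "complex lead": each channel
is smoothed by two moving averages (one spanning a power-line period, one of
28 ms) to suppress mains interference and high-frequency noise, absolutely
differenced, averaged across channels, and smoothed again over 40 ms. Three
adaptive thresholds then gate detection:

* ``M`` — steep-slope threshold, initialised from the opening seconds and
  re-estimated after every detection, decaying between beats;
* ``F`` — integrating threshold tracking the noise floor of a sliding
  350 ms window;
* ``R`` — beat-expectation term that lowers the combined threshold once
  two-thirds of the expected RR interval has elapsed.

A sample triggers a detection when the complex lead exceeds M + F + R outside
the refractory period; the reported fiducial is the complex-lead peak of the
detection region.  All three thresholds scale linearly with the signal, so
detection is invariant to global amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ECGRecord

FLAG_WIDE_QRS = "WIDE_QRS"
FLAG_TOO_FEW_BEATS = "TOO_FEW_BEATS"
FLAG_LOW_SIGNAL = "LOW_SIGNAL"


@dataclass
class ChristovParams:
    """Tunable constants of the detector; defaults follow the reference design."""

    powerline_hz: float = 50.0          # mains notch via one-period moving average
    smooth_ms: float = 28.0             # high-frequency moving average
    complex_smooth_ms: float = 40.0     # post-combination smoothing
    refractory_ms: float = 200.0        # absolute refractory after a detection
    m_init_s: float = 5.0               # training span for the initial M
    m_fraction: float = 0.6             # M as a fraction of the local peak
    m_decay_end_ms: float = 1200.0      # linear M decay horizon after a beat
    f_window_ms: float = 350.0          # integrating-threshold window
    f_gain: float = 150.0               # divisor of the F update increment
    rr_expectation_fraction: float = 2 / 3  # where the R term starts dropping
    edge_exclusion_s: float = 0.5       # fiducials banned this close to edges
    low_signal_floor_mv: float = 0.005  # complex-lead peak floor for LOW_SIGNAL


@dataclass
class BeatSet:
    """Detected QRS fiducials for one record."""

    fiducial_samples: np.ndarray        # strictly increasing ints
    sampling_rate_hz: float
    detection_lead: str = "christov-complex"
    flags: set[str] = field(default_factory=set)
    thresholds_trace: np.ndarray | None = None   # (n, 3) columns M, F, R

    def __post_init__(self) -> None:
        self.fiducial_samples = np.asarray(self.fiducial_samples, dtype=int)
        if self.fiducial_samples.size and np.any(np.diff(self.fiducial_samples) <= 0):
            raise ValueError("fiducials must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.fiducial_samples.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.fiducial_samples / self.sampling_rate_hz

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.fiducial_samples, "time_s": self.times_s})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with reflection padding, same length as input."""
    if width <= 1:
        return x.astype(float)
    left = width // 2
    right = width - 1 - left
    padded = np.pad(x, (left, right), mode="reflect")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def difference_lead(record: ECGRecord,
                    params: ChristovParams | None = None) -> np.ndarray:
    """Cross-lead mean absolute difference after mains/high-frequency MAs.

    This is the complex lead before its final smoothing; wave-measurement
    uses it for QRS-duration estimation because the last moving average
    widens every feature by its own span.
    """
    params = params or ChristovParams()
    fs = record.sampling_rate_hz
    w_mains = max(int(round(fs / params.powerline_hz)), 1)
    w_smooth = max(int(round(params.smooth_ms / 1000 * fs)), 1)
    w_complex = max(int(round(params.complex_smooth_ms / 1000 * fs)), 1)
    span = max(w_mains, w_smooth, w_complex) + 1
    if record.n_samples < span:
        raise ValueError(
            f"record {record.record_id}: {record.n_samples} samples shorter than "
            f"the {span}-sample filter span")

    diffs = np.zeros((record.signals.shape[0], record.n_samples))
    for i, sig in enumerate(record.signals):
        filtered = _moving_average(_moving_average(sig, w_mains), w_smooth)
        diffs[i, 1:] = np.abs(np.diff(filtered))
        diffs[i, 0] = diffs[i, 1]
    return diffs.mean(axis=0)


def preprocess_complex_lead(record: ECGRecord,
                            params: ChristovParams | None = None) -> np.ndarray:
    """Build the cross-lead complex lead used for detection.

    Per lead: moving average over one power-line period, moving average over
    ``smooth_ms``, absolute first difference; then the mean across leads,
    smoothed over ``complex_smooth_ms``. Constant inputs map to zero.
    """
    params = params or ChristovParams()
    fs = record.sampling_rate_hz
    w_complex = max(int(round(params.complex_smooth_ms / 1000 * fs)), 1)
    return _moving_average(difference_lead(record, params), w_complex)


def detect_beats(record: ECGRecord, params: ChristovParams | None = None,
                 keep_trace: bool = False) -> BeatSet:
    """Run the adaptive-threshold detector and return fiducials.

    Flat or near-flat records yield an empty, LOW_SIGNAL-flagged BeatSet
    rather than raising.
    """
    params = params or ChristovParams()
    fs = record.sampling_rate_hz
    if record.duration_s < 2.0:
        raise ValueError(f"record {record.record_id}: need at least 2 s for detection")
    y = preprocess_complex_lead(record, params)
    n = y.size

    refractory = int(round(params.refractory_ms / 1000 * fs))
    ms50 = max(int(round(0.05 * fs)), 1)
    f_win = int(round(params.f_window_ms / 1000 * fs))
    m_init = int(round(params.m_init_s * fs))
    decay_len = int(round((params.m_decay_end_ms - params.refractory_ms) / 1000 * fs))
    decay_slope = 0.4 / max(decay_len, 1)          # from 1.0 down to 0.6 of MM

    flags: set[str] = set()
    peak = float(y.max()) if n else 0.0
    if peak < params.low_signal_floor_mv:
        flags.add(FLAG_LOW_SIGNAL)
        flags.add(FLAG_TOO_FEW_BEATS)
        return BeatSet(np.array([], dtype=int), fs, flags=flags)

    mm_buffer = [params.m_fraction * float(y[: min(m_init, n)].max())] * 5
    m_current = mm_buffer[-1]
    new_m = 0.0
    f_current = float(y[:f_win].mean()) if n >= f_win else float(y.mean())
    r_current = 0.0
    rr_buffer: list[int] = []
    rr_mean = int(round(0.75 * fs))                # prior expectation ~80 bpm

    detections: list[int] = []
    trace = np.zeros((n, 3)) if keep_trace else None

    for i in range(n):
        since = i - detections[-1] if detections else None

        # --- steep-slope threshold M -----------------------------------
        if not detections and i < m_init:
            m_current = params.m_fraction * float(y[: i + 1].max())
        elif since is not None:
            if since <= refractory:
                new_m = params.m_fraction * float(y[detections[-1]: i + 1].max())
                if new_m > 1.5 * mm_buffer[-1]:
                    new_m = 1.1 * mm_buffer[-1]
                if since == refractory:
                    mm_buffer.append(new_m)
                    mm_buffer.pop(0)
                m_current = np.mean(mm_buffer)
            elif since <= refractory + decay_len:
                m_current = np.mean(mm_buffer) * (1.0 - decay_slope * (since - refractory))
            else:
                m_current = 0.6 * np.mean(mm_buffer)

        # --- integrating threshold F ------------------------------------
        if i >= f_win:
            window = y[i - f_win: i]
            f_current += (float(window[-ms50:].max()) - float(window[:ms50].max())) / params.f_gain
            f_current = max(f_current, 0.0)

        # --- beat-expectation threshold R -------------------------------
        if since is not None and len(rr_buffer) >= 1:
            expect = int(params.rr_expectation_fraction * rr_mean)
            if since > expect:
                r_current = -min((since - expect) * decay_slope, 0.4) * np.mean(mm_buffer)
            else:
                r_current = 0.0
        else:
            r_current = 0.0

        if trace is not None:
            trace[i] = (m_current, f_current, r_current)

        threshold = m_current + f_current + r_current
        if y[i] > threshold and (since is None or since > refractory):
            detections.append(i)
            if len(detections) >= 2:
                rr_buffer.append(detections[-1] - detections[-2])
                if len(rr_buffer) > 5:
                    rr_buffer.pop(0)
                rr_mean = int(np.mean(rr_buffer))

    # Refine each detection to the complex-lead peak of its region and
    # drop fiducials inside the edge-exclusion zones.
    edge = int(round(params.edge_exclusion_s * fs))
    half = refractory // 2
    fiducials: list[int] = []
    for det in detections:
        lo, hi = det, min(det + refractory, n)
        peak_idx = lo + int(np.argmax(y[lo:hi]))
        # allow the peak to sit slightly before the crossing
        lo2 = max(peak_idx - half, 0)
        peak_idx = lo2 + int(np.argmax(y[lo2: min(peak_idx + half, n)]))
        if peak_idx < edge or peak_idx >= n - edge:
            continue
        if fiducials and peak_idx - fiducials[-1] <= refractory:
            continue
        fiducials.append(peak_idx)

    if len(fiducials) < 3:
        flags.add(FLAG_TOO_FEW_BEATS)
    return BeatSet(np.array(fiducials, dtype=int), fs, flags=flags,
                   thresholds_trace=trace)


def qc_flags(record: ECGRecord, beats: BeatSet,
             amplitudes=None, params: ChristovParams | None = None) -> set[str]:
    """Advisory quality flags; the caller decides whether to exclude.

    WIDE_QRS (median QRS duration > 120 ms) stands proxy for the
    bundle-branch-block / paced-rhythm exclusions that clinical pipelines
    apply from machine interpretation statements.
    """
    params = params or ChristovParams()
    flags = set(beats.flags)
    if beats.n_beats < 3:
        flags.add(FLAG_TOO_FEW_BEATS)
    if amplitudes is not None and len(amplitudes.qrs_duration_ms):
        if float(np.median(amplitudes.qrs_duration_ms)) > 120.0:
            flags.add(FLAG_WIDE_QRS)
    return flags


def match_beats(true_samples: np.ndarray, detected_samples: np.ndarray,
                sampling_rate_hz: float, window_ms: float = 75.0) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to reference beats.

    Returns (true positives, false negatives, false positives) under the
    given matching window. Used to score detector sensitivity and positive
    predictivity against generator ground truth.
    """
    window = window_ms / 1000 * sampling_rate_hz
    true_samples = np.sort(np.asarray(true_samples, dtype=float))
    detected = np.sort(np.asarray(detected_samples, dtype=float))
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for ts in true_samples:
        if detected.size == 0:
            break
        dist = np.abs(detected - ts)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= window:
            used[j] = True
            tp += 1
    fn = true_samples.size - tp
    fp = int((~used).sum())
    return tp, fn, fp


def score_detection(truth_times_s: np.ndarray, beats: BeatSet,
                    duration_s: float, window_ms: float = 75.0,
                    params: ChristovParams | None = None) -> tuple[int, int, int]:
    """Score a BeatSet against ground-truth fiducial times.

    Both reference beats and detections are restricted to the analysable
    region — more than ``edge_exclusion_s`` plus the matching window away
    from either record edge — since the detector declares edge fiducials
    ineligible by design. Returns (tp, fn, fp).
    """
    params = params or ChristovParams()
    fs = beats.sampling_rate_hz
    margin = params.edge_exclusion_s + window_ms / 1000
    lo, hi = margin, duration_s - margin
    truth_times_s = np.asarray(truth_times_s, dtype=float)
    truth = truth_times_s[(truth_times_s >= lo) & (truth_times_s <= hi)] * fs
    det_t = beats.fiducial_samples / fs
    detected = beats.fiducial_samples[(det_t >= lo) & (det_t <= hi)]
    return match_beats(truth, detected, fs, window_ms)
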