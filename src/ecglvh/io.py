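"""Reading, writing and validating 12-lead ECG waveform records.

All signals are held internally in millivolts, in a fixed leads-by-samples
matrix with canonical lead order (I, II, III, aVR, aVL, aVF, V1..V6); readers
reorder on load so downstream code can index leads by name, never by file
position.  Display-unit ("mm on paper") thresholds are converted to mV once,
at configuration time, via :func:`mm_to_mv`.

Two on-disk formats are supported: WFDB header/signal pairs restricted to the
16-bit integer signal format, and a plain CSV dialect (one header row of lead
names, one column per lead, samples in mV).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical 12-lead order used for the internal signal matrix.
CANONICAL_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Chest leads required by every voltage criterion.
PRECORDIAL_LEADS = ("V1", "V2", "V3", "V4", "V5", "V6")

#: Standard ECG paper calibration: 10 mm of display per 1 mV.
DEFAULT_CALIBRATION_MM_PER_MV = 10.0

#: Sampling rates below this cannot resolve QRS morphology for amplitude work.
MIN_SAMPLING_RATE_HZ = 100.0

_CANONICAL_BY_UPPER = {name.upper(): name for name in CANONICAL_LEADS}


class ECGValidationError(ValueError):
    """Raised when a record violates the ECGRecord contract."""


class ECGParseError(ValueError):
    """Raised when an on-disk record cannot be parsed."""


def normalize_lead_name(name: str) -> str:
    """Map a lead name to canonical spelling, case-insensitively.

    Unknown names are stripped of whitespace but otherwise preserved, so
    extra channels (respiration, pacing spikes, ...) can ride along.
    """
    cleaned = name.strip()
    return _CANONICAL_BY_UPPER.get(cleaned.upper(), cleaned)


def mm_to_mv(display_mm: float, calibration_mm_per_mv: float = DEFAULT_CALIBRATION_MM_PER_MV) -> float:
    """Convert a display amplitude in mm of ECG paper to mV.

    At the conventional 10 mm/mV calibration, 20 mm equals 2 mV.
    """
    if calibration_mm_per_mv <= 0:
        raise ValueError(f"calibration must be positive, got {calibration_mm_per_mv}")
    return display_mm / calibration_mm_per_mv


def mv_to_mm(amplitude_mv: float, calibration_mm_per_mv: float = DEFAULT_CALIBRATION_MM_PER_MV) -> float:
    """Inverse of :func:`mm_to_mv`."""
    if calibration_mm_per_mv <= 0:
        raise ValueError(f"calibration must be positive, got {calibration_mm_per_mv}")
    return amplitude_mv * calibration_mm_per_mv


@dataclass
class ECGRecord:
    """A multichannel ECG waveform in mV.

    Parameters
    ----------
    record_id : str
        Identifier used in reports and file names.
    sampling_rate_hz : float
        Sampling rate; must be at least ``MIN_SAMPLING_RATE_HZ``.
    lead_names : list of str
        One name per signal row, canonical spelling.
    signals : ndarray, shape (n_leads, n_samples)
        Waveforms in mV.
    sex : {"male", "female", "unknown"}
    age_years : float, optional
    calibration_mm_per_mv : float
        Display calibration associated with the record.
    """

    record_id: str
    sampling_rate_hz: float
    lead_names: list[str]
    signals: np.ndarray
    sex: str = "unknown"
    age_years: float | None = None
    calibration_mm_per_mv: float = DEFAULT_CALIBRATION_MM_PER_MV

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.lead_names = [normalize_lead_name(n) for n in self.lead_names]
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ECGValidationError(f"sampling rate must be positive, got {self.sampling_rate_hz}")
        if self.sampling_rate_hz < MIN_SAMPLING_RATE_HZ:
            raise ECGValidationError(
                f"sampling rate {self.sampling_rate_hz} Hz is below the "
                f"{MIN_SAMPLING_RATE_HZ} Hz floor required for QRS morphology"
            )
        if self.signals.ndim != 2:
            raise ECGValidationError("signals must be a 2-D leads-by-samples matrix")
        if self.signals.shape[0] != len(self.lead_names):
            raise ECGValidationError(
                f"{len(self.lead_names)} lead names but {self.signals.shape[0]} signal rows"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ECGValidationError("duplicate lead names")
        if not np.all(np.isfinite(self.signals)):
            bad = [self.lead_names[i] for i in
                   sorted(set(np.argwhere(~np.isfinite(self.signals))[:, 0]))]
            raise ECGValidationError(f"non-finite samples in leads: {', '.join(bad)}")
        if self.sex not in ("male", "female", "unknown"):
            raise ECGValidationError(f"sex must be male/female/unknown, got {self.sex!r}")

    def require_leads(self, needed: tuple[str, ...] = PRECORDIAL_LEADS) -> None:
        missing = [n for n in needed if n not in self.lead_names]
        if missing:
            raise ECGValidationError(f"record {self.record_id} missing leads: {', '.join(missing)}")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def lead_index(self, name: str) -> int:
        name = normalize_lead_name(name)
        try:
            return self.lead_names.index(name)
        except ValueError:
            raise ECGValidationError(f"record {self.record_id} has no lead {name!r}") from None

    def lead(self, name: str) -> np.ndarray:
        return self.signals[self.lead_index(name)]


def _canonical_order(names: list[str]) -> list[int]:
    """Row permutation putting known leads in canonical order, extras last."""
    rank = {name: i for i, name in enumerate(CANONICAL_LEADS)}
    return sorted(range(len(names)), key=lambda i: (rank.get(names[i], len(rank)), i))


def _reorder(record_id, fs, names, signals, **kw) -> ECGRecord:
    order = _canonical_order(names)
    return ECGRecord(record_id, fs, [names[i] for i in order], signals[order], **kw)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_csv_record(path: str | os.PathLike, sampling_rate_hz: float,
                    record_id: str | None = None, sex: str = "unknown") -> ECGRecord:
    """Read the package CSV dialect: header row of lead names, samples in mV."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ECGParseError(f"{path}: empty file") from exc
    if frame.shape[0] == 0:
        raise ECGParseError(f"{path}: no sample rows")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any() and not frame[col].isna().any():
            row = int(numeric.isna().idxmax())
            raise ECGParseError(f"{path}: non-numeric cell in column {col!r} at row {row}")
        if frame[col].isna().any():
            row = int(frame[col].isna().idxmax())
            raise ECGParseError(f"{path}: missing value (ragged column?) in {col!r} at row {row}")
        frame[col] = numeric
    names = [normalize_lead_name(c) for c in frame.columns]
    signals = frame.to_numpy(dtype=float).T
    rec_id = record_id or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return _reorder(rec_id, sampling_rate_hz, names, signals, sex=sex)


def write_csv_record(record: ECGRecord, path: str | os.PathLike) -> None:
    """Write a record in the package CSV dialect (mV, header = lead names)."""
    frame = pd.DataFrame(record.signals.T, columns=record.lead_names)
    frame.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Minimal WFDB (header + format-16 signal file)
# ---------------------------------------------------------------------------
# A purpose-built reader/writer for the subset of the WFDB standard this
# package emits: a single .dat file shared by all signals, format 16
# (16-bit little-endian two's complement, sample-interleaved), gain in
# adu/mV with an integer baseline.

_HEADER_SIGNAL_RE = re.compile(
    r"^(?P<fname>\S+)\s+(?P<fmt>\d+)"
    r"(?:x\d+)?(?::\d+)?(?:\+\d+)?"          # samples/frame, skew, byte offset
    r"(?:\s+(?P<gain>[-0-9.eE]+)(?:\((?P<base>-?\d+)\))?(?:/(?P<units>\S+))?)?"
    r"(?:\s+(?P<adcres>\d+))?(?:\s+(?P<adczero>-?\d+))?"
    r"(?:\s+(?P<initval>-?\d+))?(?:\s+(?P<cksum>-?\d+))?(?:\s+(?P<bsize>\d+))?"
    r"(?:\s+(?P<desc>.*))?$"
)

_WFDB_DEFAULT_GAIN = 200.0  # adu per mV


def read_wfdb_record(path: str | os.PathLike, sex: str = "unknown") -> ECGRecord:
    """Read a WFDB record given its path (with or without the .hea suffix).

    Supports single-segment records whose signals live in one format-16
    signal file. Signals are converted to mV as (digital - baseline) / gain.
    """
    path = os.fspath(path)
    if path.endswith(".hea"):
        path = path[:-4]
    hea_path = path + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(f"missing WFDB header: {hea_path}")
    with open(hea_path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ECGParseError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 3:
        raise ECGParseError(f"{hea_path}: malformed record line {lines[0]!r}")
    record_name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3]) if len(head) > 3 else None
    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) != n_sig:
        raise ECGParseError(f"{hea_path}: expected {n_sig} signal lines, found {len(sig_lines)}")

    fnames, gains, baselines, names = [], [], [], []
    for i, line in enumerate(sig_lines):
        m = _HEADER_SIGNAL_RE.match(line)
        if m is None:
            raise ECGParseError(f"{hea_path}: cannot parse signal line {line!r}")
        if int(m.group("fmt")) != 16:
            raise ECGParseError(
                f"{hea_path}: unsupported WFDB signal format {m.group('fmt')} (only 16)")
        fnames.append(m.group("fname"))
        gain = float(m.group("gain")) if m.group("gain") else _WFDB_DEFAULT_GAIN
        gains.append(gain if gain != 0 else _WFDB_DEFAULT_GAIN)
        baselines.append(int(m.group("base")) if m.group("base") else 0)
        desc = (m.group("desc") or "").strip()
        names.append(desc if desc else f"sig{i}")
    if len(set(fnames)) != 1:
        raise ECGParseError(f"{hea_path}: multi-file signal layout not supported")

    dat_path = os.path.join(os.path.dirname(hea_path), fnames[0])
    if not os.path.exists(dat_path):
        raise FileNotFoundError(f"missing WFDB signal file: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size % n_sig:
        raise ECGParseError(f"{dat_path}: sample count {raw.size} not divisible by {n_sig} signals")
    digital = raw.reshape(-1, n_sig).T.astype(float)
    if n_samples is not None and digital.shape[1] != n_samples:
        raise ECGParseError(
            f"{dat_path}: header promises {n_samples} samples, file holds {digital.shape[1]}")
    signals = (digital - np.array(baselines)[:, None]) / np.array(gains)[:, None]
    names = [normalize_lead_name(n) for n in names]
    return _reorder(record_name, fs, names, signals, sex=sex)


def write_wfdb_record(record: ECGRecord, directory: str | os.PathLike,
                      gain: float = _WFDB_DEFAULT_GAIN) -> str:
    """Write a record as a WFDB header + format-16 signal file pair.

    Returns the record path (without suffix). Quantisation is 1/gain mV
    (5 µV at the default gain of 200 adu/mV).
    """
    os.makedirs(directory, exist_ok=True)
    base = os.path.join(os.fspath(directory), record.record_id)
    digital = np.rint(record.signals * gain)
    if np.any(np.abs(digital) > 32767):
        raise ValueError("signal exceeds int16 range at this gain; lower the gain")
    interleaved = digital.T.astype("<i2")
    interleaved.tofile(base + ".dat")

    n_sig, n_samp = record.signals.shape
    lines = [f"{record.record_id} {n_sig} {record.sampling_rate_hz:g} {n_samp}"]
    first = interleaved[0] if n_samp else np.zeros(n_sig, dtype=np.int16)
    checksums = interleaved.astype(np.int64).sum(axis=0) % 65536
    checksums = np.where(checksums >= 32768, checksums - 65536, checksums)
    for i, name in enumerate(record.lead_names):
        lines.append(
            f"{record.record_id}.dat 16 {gain:g}(0)/mV 16 0 "
            f"{int(first[i])} {int(checksums[i])} 0 {name}"
        )
    with open(base + ".hea", "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return base
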