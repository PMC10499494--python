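"""Synthetic 12-lead ECG generation with known ground truth.

Each lead is a train of Gaussian-shaped P/Q/R/S/T waves (an ECGSYN-style
simplification with per-lead amplitudes set independently) plus sinusoidal
baseline wander and white noise. The default template mimics normal R-wave
progression: deep S waves in V1-V2, transition around V3-V4, tall R waves in
V5-V6 — so adjacent-precordial QRS "overlap" can be induced by scaling two
neighbouring leads.

Cohort generation plants a monotone linear relationship between the LV mass
index (LVMI, g/m²) and precordial voltage: higher LVMI deepens S in V1-V3 and
raises R in V4-V6.  Every subject gets an independent RNG stream derived from
(seed, subject index), so inserting or removing subjects never reshuffles the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CANONICAL_LEADS, ECGRecord

#: (amplitude mV, centre offset from the R fiducial in s, Gaussian sigma in s)
Wave = tuple[float, float, float]

# Wave timing shared by all leads; amplitudes vary per lead. Offsets/widths
# chosen so the complex-lead QRS-duration rule reads ~90 ms at defaults.
_P_OFFSET, _P_WIDTH = -0.190, 0.022
_Q_OFFSET, _Q_WIDTH = -0.028, 0.009
_R_OFFSET, _R_WIDTH = 0.000, 0.011
_S_OFFSET, _S_WIDTH = 0.030, 0.009
_T_OFFSET, _T_WIDTH = 0.280, 0.055

# Per-lead (P, Q, R, S, T) amplitudes in mV for a normal adult 12-lead ECG.
_DEFAULT_AMPLITUDES: dict[str, tuple[float, float, float, float, float]] = {
    "I":   (0.08, -0.05, 0.60, -0.10, 0.20),
    "II":  (0.12, -0.08, 0.90, -0.15, 0.25),
    "III": (0.05, -0.05, 0.40, -0.10, 0.10),
    "aVR": (-0.08, -0.05, 0.10, -0.70, -0.20),
    "aVL": (0.04, -0.05, 0.35, -0.15, 0.10),
    "aVF": (0.08, -0.06, 0.60, -0.10, 0.15),
    "V1":  (0.05, -0.02, 0.20, -1.10, 0.10),
    "V2":  (0.06, -0.02, 0.40, -1.40, 0.30),
    "V3":  (0.07, -0.04, 0.70, -0.90, 0.35),
    "V4":  (0.08, -0.06, 1.30, -0.50, 0.35),
    "V5":  (0.10, -0.08, 1.50, -0.30, 0.30),
    "V6":  (0.10, -0.08, 1.30, -0.15, 0.25),
}

_WAVE_NAMES = ("P", "Q", "R", "S", "T")
_WAVE_TIMING = {
    "P": (_P_OFFSET, _P_WIDTH),
    "Q": (_Q_OFFSET, _Q_WIDTH),
    "R": (_R_OFFSET, _R_WIDTH),
    "S": (_S_OFFSET, _S_WIDTH),
    "T": (_T_OFFSET, _T_WIDTH),
}


def _default_lead_waves() -> dict[str, dict[str, Wave]]:
    out: dict[str, dict[str, Wave]] = {}
    for lead, amps in _DEFAULT_AMPLITUDES.items():
        out[lead] = {
            name: (amp, *(_WAVE_TIMING[name]))
            for name, amp in zip(_WAVE_NAMES, amps)
        }
    return out


@dataclass
class BeatMorphology:
    """Per-lead Gaussian wave parameters plus rhythm and noise settings.

    ``lead_waves[lead][wave] = (amplitude_mV, offset_s, sigma_s)``; the R
    fiducial is the time origin of each beat. Q and S amplitudes must be
    non-positive, R non-negative, and the P/QRS/T offsets ordered.
    """

    lead_waves: dict[str, dict[str, Wave]] = field(default_factory=_default_lead_waves)
    heart_rate_bpm: float = 60.0
    rr_jitter_sd_s: float = 0.0
    noise_sd_mv: float = 0.02
    baseline_wander_amp_mv: float = 0.05
    baseline_wander_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart rate must be positive")
        for quantity in (self.rr_jitter_sd_s, self.noise_sd_mv,
                         self.baseline_wander_amp_mv, self.baseline_wander_hz):
            if quantity < 0:
                raise ValueError("jitter, noise and wander parameters must be non-negative")
        for lead, waves in self.lead_waves.items():
            for wname, (amp, off, width) in waves.items():
                if width <= 0:
                    raise ValueError(f"{lead}/{wname}: width must be positive")
                if wname in ("Q", "S") and amp > 0:
                    raise ValueError(f"{lead}/{wname}: Q/S amplitudes must be <= 0")
                if wname == "R" and amp < 0:
                    raise ValueError(f"{lead}/R: R amplitude must be >= 0")
            offsets = {w: waves[w][1] for w in waves}
            if "P" in offsets and "R" in offsets and not offsets["P"] < offsets["R"]:
                raise ValueError(f"{lead}: P must precede the QRS")
            if "T" in offsets and "R" in offsets and not offsets["T"] > offsets["R"]:
                raise ValueError(f"{lead}: T must follow the QRS")

    @classmethod
    def default(cls, **overrides) -> "BeatMorphology":
        return cls(**overrides)

    def with_rs(self, lead: str, r_mv: float | None = None,
                s_mv: float | None = None) -> "BeatMorphology":
        """Copy of this morphology with one lead's R and/or S amplitude replaced.

        ``s_mv`` is given as a signed value (non-positive).
        """
        waves = {ld: dict(w) for ld, w in self.lead_waves.items()}
        if r_mv is not None:
            _, off, width = waves[lead]["R"]
            waves[lead]["R"] = (r_mv, off, width)
        if s_mv is not None:
            _, off, width = waves[lead]["S"]
            waves[lead]["S"] = (s_mv, off, width)
        return replace(self, lead_waves=waves)

    def scale_qrs_width(self, factor: float) -> "BeatMorphology":
        """Widen (factor > 1) or narrow the QRS by scaling Q/R/S offsets and widths."""
        waves = {ld: dict(w) for ld, w in self.lead_waves.items()}
        for ld in waves:
            for wname in ("Q", "R", "S"):
                amp, off, width = waves[ld][wname]
                waves[ld][wname] = (amp, off * factor, width * factor)
        return replace(self, lead_waves=waves)


@dataclass
class GroundTruth:
    """Noise-free generator truth for one record."""

    fiducial_times_s: np.ndarray            # (n_beats,)
    lead_names: list[str]
    r_amp_mv: np.ndarray                    # (n_beats, n_leads), >= 0
    s_amp_mv: np.ndarray                    # (n_beats, n_leads), magnitudes >= 0

    @property
    def n_beats(self) -> int:
        return len(self.fiducial_times_s)

    def fiducial_samples(self, sampling_rate_hz: float) -> np.ndarray:
        return np.round(self.fiducial_times_s * sampling_rate_hz).astype(int)


def generate_record(morphology: BeatMorphology | None = None,
                    duration_s: float = 10.0,
                    sampling_rate_hz: float = 500.0,
                    seed: int = 0,
                    record_id: str = "synthetic",
                    sex: str = "unknown") -> tuple[ECGRecord, GroundTruth]:
    """Generate one 12-lead record and its ground truth.

    Beat fiducials follow ``t_k = RR/2 + k*RR + jitter_k``: at 60 bpm over
    10 s with zero jitter that is exactly ten beats at 0.5, 1.5, ... 9.5 s.
    The same seed always reproduces the identical signal matrix.
    """
    morphology = morphology or BeatMorphology.default()
    rng = np.random.default_rng(seed)
    rr = 60.0 / morphology.heart_rate_bpm
    if duration_s < rr:
        raise ValueError(f"duration {duration_s} s too short for one beat at "
                         f"{morphology.heart_rate_bpm} bpm")
    n_samples = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n_samples) / sampling_rate_hz

    n_beats = int(np.floor((duration_s - rr / 2) / rr)) + 1
    fiducials = rr / 2 + rr * np.arange(n_beats)
    if morphology.rr_jitter_sd_s > 0:
        fiducials = fiducials + rng.normal(0, morphology.rr_jitter_sd_s, n_beats)
        fiducials = np.sort(np.clip(fiducials, 0.0, duration_s - 1 / sampling_rate_hz))

    leads = [ld for ld in CANONICAL_LEADS if ld in morphology.lead_waves]
    signals = np.zeros((len(leads), n_samples))
    r_truth = np.zeros((n_beats, len(leads)))
    s_truth = np.zeros((n_beats, len(leads)))

    for li, lead in enumerate(leads):
        waves = morphology.lead_waves[lead]
        sig = np.zeros(n_samples)
        for amp, off, width in waves.values():
            if amp == 0:
                continue
            centers = fiducials + off
            # sum of Gaussians, vectorised over beats
            sig += (amp * np.exp(-0.5 * ((t[None, :] - centers[:, None]) / width) ** 2)).sum(axis=0)
        signals[li] = sig
        r_truth[:, li] = max(waves["R"][0], 0.0)
        s_truth[:, li] = abs(min(waves["S"][0], 0.0))

    if morphology.baseline_wander_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signals += morphology.baseline_wander_amp_mv * np.sin(
            2 * np.pi * morphology.baseline_wander_hz * t + phase)
    if morphology.noise_sd_mv > 0:
        signals += rng.normal(0, morphology.noise_sd_mv, signals.shape)

    record = ECGRecord(record_id, sampling_rate_hz, list(leads), signals, sex=sex)
    truth = GroundTruth(fiducials, list(leads), r_truth, s_truth)
    return record, truth


# ---------------------------------------------------------------------------
# Cohorts with a planted LVMI-voltage relationship
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Configuration for a synthetic ECG-echo cohort.

    ``voltage_effect`` is the slope (mV per g/m²) linking LVMI to the
    magnitudes of S(V1-V3) and R(V4-V6) around ``lvmi_reference``. Class-
    conditional LVMI distributions default to Normal(130, 20) for the LVH
    class and Normal(80, 15) otherwise, truncated at 30 g/m². LVH labels are
    assigned from the realised LVMI via the sex-specific cutoffs.
    """

    n_subjects: int = 200
    lvh_prevalence: float = 0.406
    lvmi_mean_lvh: float = 130.0
    lvmi_sd_lvh: float = 20.0
    lvmi_mean_normal: float = 80.0
    lvmi_sd_normal: float = 15.0
    lvmi_floor: float = 30.0
    lvmi_reference: float = 100.0
    voltage_effect: float = 0.01
    amplitude_noise_sd_mv: float = 0.15
    sex_ratio_female: float = 0.5
    cutoff_male: float = 95.0
    cutoff_female: float = 115.0
    duration_s: float = 10.0
    sampling_rate_hz: float = 500.0
    heart_rate_bpm: float = 60.0
    noise_sd_mv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.lvh_prevalence <= 1.0:
            raise ValueError(f"lvh_prevalence must lie in [0, 1], got {self.lvh_prevalence}")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ValueError("sex_ratio_female must lie in [0, 1]")
        if self.amplitude_noise_sd_mv < 0:
            raise ValueError("amplitude_noise_sd_mv must be non-negative")


@dataclass
class CohortMember:
    """One generated subject: waveform record, truth, and echo-style label."""

    record: ECGRecord
    truth: GroundTruth
    sex: str
    lvmi_g_per_m2: float
    lvh_label: bool


_S_EFFECT_LEADS = ("V1", "V2", "V3")
_R_EFFECT_LEADS = ("V4", "V5", "V6")


def _subject_morphology(spec: CohortSpec, lvmi: float,
                        rng: np.random.Generator) -> BeatMorphology:
    delta = spec.voltage_effect * (lvmi - spec.lvmi_reference)
    morph = BeatMorphology.default(
        heart_rate_bpm=spec.heart_rate_bpm, noise_sd_mv=spec.noise_sd_mv)
    waves = {ld: dict(w) for ld, w in morph.lead_waves.items()}
    for lead, lead_w in waves.items():
        r_amp, r_off, r_width = lead_w["R"]
        s_amp, s_off, s_width = lead_w["S"]
        if lead in _R_EFFECT_LEADS:
            r_amp += delta
        if lead in _S_EFFECT_LEADS:
            s_amp -= delta
        r_amp += rng.normal(0, spec.amplitude_noise_sd_mv)
        s_amp += rng.normal(0, spec.amplitude_noise_sd_mv)
        lead_w["R"] = (max(r_amp, 0.0), r_off, r_width)
        lead_w["S"] = (min(s_amp, 0.0), s_off, s_width)
    return replace(morph, lead_waves=waves)


def generate_cohort(spec: CohortSpec) -> list[CohortMember]:
    """Generate a cohort of paired records and echo-style LVH labels.

    Each subject's latent class (LVH with probability ``lvh_prevalence``)
    selects the LVMI distribution; the realised LVMI drives precordial
    voltage through ``voltage_effect`` and the label through the sex-specific
    LVMI cutoffs (strict ``>``). Fully reproducible under ``spec.seed``.
    """
    members: list[CohortMember] = []
    for idx in range(spec.n_subjects):
        rng = np.random.default_rng((spec.seed, idx))
        sex = "female" if rng.uniform() < spec.sex_ratio_female else "male"
        is_lvh_class = rng.uniform() < spec.lvh_prevalence
        mean, sd = ((spec.lvmi_mean_lvh, spec.lvmi_sd_lvh) if is_lvh_class
                    else (spec.lvmi_mean_normal, spec.lvmi_sd_normal))
        lvmi = max(rng.normal(mean, sd), spec.lvmi_floor)
        cutoff = spec.cutoff_female if sex == "female" else spec.cutoff_male
        label = lvmi > cutoff

        morph = _subject_morphology(spec, lvmi, rng)
        record_seed = int(rng.integers(0, 2**31 - 1))
        record, truth = generate_record(
            morph, duration_s=spec.duration_s, sampling_rate_hz=spec.sampling_rate_hz,
            seed=record_seed, record_id=f"synth{idx:04d}", sex=sex)
        members.append(CohortMember(record, truth, sex, float(lvmi), bool(label)))
    return members
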