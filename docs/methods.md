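# Methods

## Scope and pipeline

`ecglvh` automates four ECG voltage criteria for left ventricular
hypertrophy and scores them against an echocardiographic reference. The
per-record pipeline is: QRS detection on a cross-lead complex signal →
per-beat, per-lead R/S amplitude measurement against a PR-segment baseline
→ per-beat criterion values → reduction to one ECG-level statistic (MMCV)
→ binary call at a display-calibrated threshold. Cohort-level evaluation
adds confusion metrics, the McNemar test, ROC/AUROC on the MMCV, and the
Pearson correlation of MMCV with LV mass index (LVMI).

Everything internal is in millivolts. Thresholds are configured in display
millimetres and converted once at configuration time
(mm / calibration, default 10 mm/mV), so 20 mm ↔ 2 mV. Signals live in a
leads-by-samples matrix in a canonical order (I, II, III, aVR, aVL, aVF,
V1–V6); readers reorder on load and criteria index leads by name only.

## QRS detection

The detector follows the combined-adaptive-threshold design built on a
cross-lead complex signal. Per lead: a moving average spanning exactly one
power-line period (default 50 Hz; 10 samples at 500 Hz, which nulls the
mains frequency), a 28 ms moving average against high-frequency noise, and
an absolute first difference; the per-lead results are averaged and
smoothed over 40 ms. Three thresholds gate detection:

* **M** (steep slope): 0.6 × the running complex-lead maximum during the
  first 5 s; after each detection, re-estimated from the detection region
  (capped at 1.1× the buffer value when it would jump >1.5×), averaged
  over a 5-deep buffer, held for the 200 ms refractory, then decayed
  linearly to 60 % of the buffer mean by 1.2 s after the beat.
* **F** (integrating): initialised to the mean of the first 350 ms;
  each sample adds (max of the newest 50 ms − max of the oldest 50 ms of a
  sliding 350 ms window) / 150, floored at zero.
* **R** (beat expectation): zero until two-thirds of the mean of the last
  five RR intervals has elapsed, then an increasingly negative term
  (same slope as the M decay, capped at −0.4 × the M buffer mean) that
  lowers the combined threshold for an overdue beat.

A detection fires when the complex lead exceeds M + F + R outside the
refractory period; the fiducial is the complex-lead peak of the detection
region. All three terms scale linearly with the input, so detection is
invariant to global amplitude scaling (verified for factors 0.5–2). The
first and last 0.5 s are ineligible for fiducials (filter transients and
truncated measurement windows); detection-performance scoring therefore
restricts both reference beats and detections to the interior region, the
standard convention when a detector declares an analysable region.
Flat or near-flat records (complex-lead peak < 0.005 mV — an order of
magnitude above the residue of pure measurement noise, far below any real
QRS) return an empty, flagged beat set rather than raising.

Advisory QC flags: `TOO_FEW_BEATS` (< 3), `LOW_SIGNAL`, and `WIDE_QRS`
(median QRS duration > 120 ms) as a proxy for the bundle-branch-block and
paced-rhythm exclusions that clinical pipelines make from machine
interpretation statements, which waveform files do not carry. Flags are
advisory; `evaluate_record` hard-fails only on too-few-beats unless
overridden, and the CLI skips flagged records into an explicit
skipped-records summary.

## Amplitude measurement

R and S are the extremal positive and negative deviations from baseline
within a fixed window around the fiducial (−60 ms, +80 ms), clipped at
zero — deliberately not sequence-order Q/R/S labelling, because every
criterion consumes only maximal deflections and this collapses RSR′ and QS
morphologies safely. The baseline is the median of the PR segment
(−120 ms to −60 ms before the fiducial), falling back (flagged) to the
whole-lead median when the window leaves the record. Beats whose windows
cross record edges are dropped, never padded. QRS duration is the span
between the first and last crossings of 10 % of the beat-local peak of the
cross-lead difference signal within ±100 ms of the fiducial. Duration uses
the difference signal *before* its final 40 ms smoothing: that moving
average widens every feature by its own span and would bias a width
estimate; first-to-last crossing (rather than one contiguous region)
bridges the zero-derivative dips at wave apices.

The measurement contract is checked against generator ground truth:
noise-free records reproduce true amplitudes within 0.05 mV (observed
worst case ≈ 0.031 mV, dominated by Gaussian-tail overlap between Q/S and
R at the fiducial), and constant-offset and positive-scaling invariances
hold to the same tolerance.

## Criteria and the MMCV statistic

Per beat: WS takes S(Vi)+R(Vi+1) for the five adjacent precordial pairs;
Sokolow–Lyon S(V1)+R(V5) and S(V1)+R(V6) as two combinations;
Cornell R(aVL)+S(V3); Peguero–Lo Presti the deepest S across all measured
leads plus S(V4), with V4 allowed to serve as both terms, per the original
definition. The MMCV reduces a beats × combinations matrix by the median
over beats (mean of the middle two for even counts) then the maximum over
combinations; it is invariant to beat reordering and duplication and
monotone in every entry. Reducing Sokolow–Lyon's two combinations by the
max is equivalent to the textbook S(V1)+max(R V5, R V6) at the record
level.

Calls: WS uses a strict `>` (the criterion's word is *exceeding*; a value
of exactly 2 mV is negative); the comparators use `≥` at their literature
cutoffs (35 mm; 28/20 mm; 28/23 mm male/female), all configurable. Unknown
sex falls back to the stricter male cutoff with a warning. The WS sex
adjustment defaults to lowering the female threshold by 10 mm, the
direction that raises sensitivity in females; a config switch raises the
male threshold instead. Binary calls and ROC both use the MMCV, keeping
the two internally consistent.

## Echo reference

Devereux LV mass from IVSd, LVIDd, PWTd in cm:
`0.8 × 1.04 × [(IVSd+LVIDd+PWTd)³ − LVIDd³] + 0.6` g. BSA defaults to
Mosteller (`√(h·w/3600)`), the most common convention in echo labs, with
Du Bois selectable. LVMI = mass / BSA; LVH is a strict `>` against
sex-specific cutoffs, default 95 g/m² (male) / 115 g/m² (female) with a
`"guideline"` preset for the transposed orientation (115/95) since
published guidelines place the higher cutoff in males.

## Evaluation statistics

Confusion metrics are definitional; the odds ratio applies the
Haldane–Anscombe 0.5 correction (flagged) when any cell is zero. McNemar
uses chi² = (b−c)²/(b+c) on the discordant pairs without continuity
correction, with the exact two-sided binomial p-value below 25 discordant
pairs and the degenerate b+c=0 case returning (0, 1). The ROC is a
descending-score threshold sweep with ties grouped; the AUROC is computed
through the Mann–Whitney rank identity (midranks), which agrees with
brute-force pair counting to the last bit for tie-free input and credits
ties one half. No confidence intervals are emitted by default; a seeded
percentile bootstrap for the AUROC is available.

## Synthetic data

Each lead is a train of Gaussian P/Q/R/S/T waves plus sinusoidal baseline
wander and white noise — an ECGSYN-style simplification with per-lead
amplitudes set independently, adequate because the criteria consume only
R/S magnitudes. The default template mimics normal R-wave progression
(S 1.1/1.4/0.9 mV in V1–V3; R 1.3/1.5/1.3 mV in V4–V6), 60 bpm, 0.02 mV
noise, 0.05 mV wander at 0.25 Hz; Q/R/S offsets and widths were chosen so
the measured QRS duration sits near 90–100 ms. Beats follow
t = RR/2 + k·RR plus optional jitter, and the ground truth records the
configured amplitudes and fiducials.

Cohorts plant a monotone LVMI–voltage relationship: per subject, a latent
LVH class (default prevalence 0.406, matching the reference clinical
cohort's observed rate) selects the LVMI distribution — Normal(130, 20)
for LVH, Normal(80, 15) otherwise, floored at 30 g/m² — and the realised
LVMI shifts S(V1–V3) and R(V4–V6) by `voltage_effect` (default
0.01 mV per g/m²) around a 100 g/m² reference, with 0.15 mV between-subject
amplitude noise on every lead. Labels come from the realised LVMI against
the sex-specific cutoffs, so borderline subjects can cross class lines
exactly as echo-labelled patients do. Each subject draws from an RNG
stream keyed by (seed, index), so growing a cohort never reshuffles
existing subjects.

What the generator does *not* emulate: arrhythmia, bundle branch block and
pacing morphologies, electrode artefacts, respiration-modulated amplitudes,
and the dipole physics linking leads. Passing tests therefore demonstrate
that the pipeline recovers what it measures and discriminates a planted
monotone voltage–mass relationship — not that any criterion achieves a
particular performance on clinical ECGs, where the voltage–mass coupling
is far weaker and confounded (clinically reported AUROCs for these
criteria sit in the 0.55–0.65 band).

## Problem sizes and numerical choices

Detector performance and discrimination experiments use 200-subject
cohorts of 10 s, 500 Hz records — large enough that a binomial fluctuation
of the quoted rates is negligible, small enough to keep a full run in tens
of seconds. The null-cohort AUROC band [0.35, 0.65] is the ±3·SE envelope
of a chance AUROC at this size; the planted experiment uses
voltage_effect = 0.02 mV/(g/m²) (≈1 mV class-mean separation) at 0.05 mV
amplitude noise. Sampling rates below 100 Hz are rejected outright —
QRS amplitude error grows unboundedly as morphology becomes unresolvable.
WFDB output quantises at 5 µV (gain 200 adu/mV, format 16); the CSV
dialect stores 6 decimal places. Ties in the complex-lead argmax resolve
to the earliest sample; all RNG flows through `numpy.random.default_rng`
with explicit seeds.

## Known limitations

* The WFDB reader covers the subset this package writes (single segment,
  one format-16 signal file); other formats need conversion.
* The Christov constants are the published reference values exposed in
  `ChristovParams`; they were not re-tuned for pathological rhythms, and
  the detector is validated only on the generator's morphology family.
* The supplementary repolarisation features sometimes added to visual LVH
  reading (ST depression, T-wave inversion, left atrial enlargement) are
  out of scope, as are survival models; the cohort manifest carries enough
  columns for users to fit those externally.
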