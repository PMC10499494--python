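# ecglvh

Voltage-criteria detection of left ventricular hypertrophy (LVH) from
12-lead ECGs, for researchers who want an automated, auditable waveform
pipeline rather than eyeballed calls: QRS detection, per-beat R/S amplitude
measurement, four published voltage criteria, an echocardiographic
reference standard, and the statistics to score one against the other —
plus a synthetic 12-lead ECG generator so the whole chain is testable
without access to clinical data.

## The criteria

All four criteria combine R-wave and S-wave magnitudes (mV, measured from
an isoelectric baseline) and compare against a cutoff stated in display
millimetres at the conventional 10 mm/mV calibration:

* **Witteles–Somani (WS)** — the visual sign is QRS overlap between
  adjacent precordial leads; the automated rule is
  S(V<sub>i</sub>) + R(V<sub>i+1</sub>) > 20 mm (2 mV) for any adjacent
  pair V1–V2 … V5–V6. An optional sex adjustment shifts the threshold by
  10 mm (2 large boxes).
* **Sokolow–Lyon** — S(V1) + R(V5 or V6) ≥ 35 mm.
* **Cornell** — R(aVL) + S(V3) ≥ 28 mm (male) / 20 mm (female).
* **Peguero–Lo Presti** — deepest S in any lead + S(V4) ≥ 28 mm (male) /
  23 mm (female).

Each criterion is reduced to one ECG-level statistic, the **MMCV**: the
median over heartbeats within each lead combination, then the maximum over
combinations. Binary calls threshold the MMCV; ROC analysis sweeps it.

Beats are found with the Christov combined-adaptive-threshold detector
(cross-lead "complex lead" with steep-slope, integrating and
beat-expectation thresholds). The reference label comes from
echocardiography: LV mass by the Devereux formula
`0.8 × 1.04 × [(IVSd + LVIDd + PWTd)³ − LVIDd³] + 0.6`, indexed to
Mosteller body surface area, with LVH defined as LVMI > 95 g/m² in males
and > 115 g/m² in females (configurable preset for the transposed
guideline orientation).

## Worked example

```python
from ecglvh import BeatMorphology, evaluate_record, generate_record

morph = (BeatMorphology.default()
         .with_rs("V2", s_mv=-1.4)   # deep anterior S
         .with_rs("V3", r_mv=1.1))   # tall neighbouring R
record, _ = generate_record(morph, seed=7, record_id="overlap", sex="male")
for name, res in evaluate_record(record).results.items():
    print(name, round(res.mmcv_mv, 2), res.positive)
```

prints

```
WS 2.51 True
SOKOLOW_LYON 2.6 False
CORNELL 1.26 False
PEGUERO_LO_PRESTI 1.87 False
```

The engineered S(V2)+R(V3) pair sums to ≈2.5 mV — visually, overlapping
QRS complexes in V2/V3 — so WS is positive at its 2 mV threshold while the
comparators stay below their higher cutoffs. More narrative walkthroughs
live in `examples/` (simulation + detection, criteria, echo labels, cohort
evaluation), and a thin CLI (`ecglvh simulate | analyze | evaluate`) wraps
the same functions for shell use.

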