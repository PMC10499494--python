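"""Voltage criteria: hand-computed sums, MMCV oracle, thresholds, end-to-end."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecglvh import (CORNELL, PEGUERO_LO_PRESTI, SOKOLOW_LYON, WS,
                    AmplitudeMatrix, BeatMorphology, QCError, ThresholdConfig,
                    classify, compute_criterion, cornell_per_beat,
                    evaluate_record, generate_record, mmcv, peguero_per_beat,
                    sokolow_per_beat, ws_per_beat)

LEADS = ["I", "II", "III", "aVR", "aVL", "aVF",
         "V1", "V2", "V3", "V4", "V5", "V6"]


def amp_matrix(r: dict[str, list[float]] | None = None,
               s: dict[str, list[float]] | None = None,
               n_beats: int = 1) -> AmplitudeMatrix:
    """Build an AmplitudeMatrix from sparse per-lead beat values."""
    r_m = np.zeros((n_beats, len(LEADS)))
    s_m = np.zeros((n_beats, len(LEADS)))
    for lead, vals in (r or {}).items():
        r_m[:, LEADS.index(lead)] = vals
    for lead, vals in (s or {}).items():
        s_m[:, LEADS.index(lead)] = vals
    return AmplitudeMatrix(r_m, s_m, np.zeros_like(r_m),
                           np.full(n_beats, 90.0), list(LEADS))


def mmcv_oracle(values: np.ndarray) -> float:
    """Exhaustive median/max, independent of numpy's median."""
    best = -np.inf
    for col in np.asarray(values, dtype=float).T:
        ordered = sorted(col)
        n = len(ordered)
        med = (ordered[n // 2] if n % 2 else
               0.5 * (ordered[n // 2 - 1] + ordered[n // 2]))
        best = max(best, med)
    return best


class TestPerBeatDefinitions:
    def test_ws_single_pair_sum(self):
        amps = amp_matrix(r={"V3": [0.9]}, s={"V2": [1.2]})
        values, labels = ws_per_beat(amps)
        assert labels == ["V1-V2", "V2-V3", "V3-V4", "V4-V5", "V5-V6"]
        assert values[0, labels.index("V2-V3")] == pytest.approx(2.1)

    def test_ws_hand_row(self):
        """s(V1)=1.1, r(V2)=0.5, s(V2)=0.9, r(V3)=0.9, rest zero:
        row follows S(Vi)+R(Vi+1) pair by pair."""
        amps = amp_matrix(r={"V2": [0.5], "V3": [0.9]},
                          s={"V1": [1.1], "V2": [0.9]})
        values, _ = ws_per_beat(amps)
        np.testing.assert_allclose(values[0], [1.6, 1.8, 0.0, 0.0, 0.0])

    def test_ws_all_zero(self):
        values, _ = ws_per_beat(amp_matrix())
        assert np.all(values == 0.0)

    def test_sokolow_row_and_call(self):
        amps = amp_matrix(r={"V5": [1.6], "V6": [1.2]}, s={"V1": [2.0]})
        values, labels = sokolow_per_beat(amps)
        np.testing.assert_allclose(values[0], [3.6, 3.2])
        statistic = mmcv(values)
        assert statistic == pytest.approx(3.6)
        assert classify(statistic, SOKOLOW_LYON)  # 3.6 >= 3.5 default cutoff

    def test_cornell_sex_specific(self):
        amps = amp_matrix(r={"aVL": [1.0]}, s={"V3": [1.9]})
        values, _ = cornell_per_beat(amps)
        assert values[0, 0] == pytest.approx(2.9)
        assert classify(2.9, CORNELL, "male")
        with pytest.warns(UserWarning, match="male cutoff"):
            assert classify(2.9, CORNELL, "unknown")
        assert not classify(0.0, CORNELL, "male")

    def test_peguero_deepest_s_elsewhere(self):
        amps = amp_matrix(s={"V2": [1.7], "V4": [1.0]})
        values, _ = peguero_per_beat(amps)
        assert values[0, 0] == pytest.approx(2.7)

    def test_peguero_v4_counts_twice(self):
        """When V4 carries the deepest S it serves as both terms."""
        amps = amp_matrix(s={"V4": [1.5], "V1": [1.0]})
        values, _ = peguero_per_beat(amps)
        assert values[0, 0] == pytest.approx(3.0)


class TestMMCV:
    def test_hand_example(self):
        assert mmcv(np.array([[1, 4], [2, 5], [3, 6]])) == 5.0

    def test_single_value_identity(self):
        assert mmcv(np.array([[2.2]])) == pytest.approx(2.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mmcv(np.empty((0, 2)))

    @given(arrays(float, st.tuples(st.integers(1, 4), st.integers(1, 3)),
                  elements=st.sampled_from([0.0, 0.25, 0.5, 1.0, 2.0, 2.5])))
    @settings(max_examples=300, deadline=None)
    def test_oracle_equivalence(self, values):
        """MMCV equals the exhaustive median/max on small grids."""
        assert mmcv(values) == pytest.approx(mmcv_oracle(values), abs=1e-12)

    @given(arrays(float, st.tuples(st.integers(1, 4), st.integers(1, 3)),
                  elements=st.floats(0, 5, allow_nan=False)),
           st.integers(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_beat_reorder_and_duplication_invariance(self, values, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(values.shape[0])
        assert mmcv(values[perm]) == pytest.approx(mmcv(values))
        assert mmcv(np.vstack([values, values])) == pytest.approx(mmcv(values))

    @given(arrays(float, st.tuples(st.integers(1, 4), st.integers(1, 3)),
                  elements=st.floats(0, 5, allow_nan=False)))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, values):
        """Elementwise-increasing any entry never decreases the MMCV."""
        bumped = values + 0.25
        assert mmcv(bumped) >= mmcv(values)


class TestClassification:
    def test_ws_boundary_is_negative(self):
        """'Exceeding' 20 mm means a strict inequality: 2.0 mV is negative."""
        assert not classify(2.0, WS)
        assert classify(2.0 + 1e-2, WS)

    def test_ws_sex_adjusted_lowers_female_threshold(self):
        cfg = ThresholdConfig(ws_sex_adjusted=True)
        assert cfg.threshold_mv(WS, "female") == pytest.approx(1.0)
        assert cfg.threshold_mv(WS, "male") == pytest.approx(2.0)
        assert classify(1.2, WS, "female", cfg)
        assert not classify(1.2, WS, "male", cfg)

    def test_ws_sex_adjusted_raise_male_direction(self):
        cfg = ThresholdConfig(ws_sex_adjusted=True, ws_adjust_direction="raise_male")
        assert cfg.threshold_mv(WS, "male") == pytest.approx(3.0)
        assert cfg.threshold_mv(WS, "female") == pytest.approx(2.0)

    def test_thresholds_respect_calibration(self):
        cfg = ThresholdConfig(calibration_mm_per_mv=5.0)
        assert cfg.threshold_mv(WS) == pytest.approx(4.0)

    def test_result_internal_consistency(self):
        """positive <=> mmcv vs threshold for every emitted result."""
        amps = amp_matrix(r={"V3": [0.9, 1.3, 1.1]}, s={"V2": [1.2, 1.0, 1.4]},
                          n_beats=3)
        for criterion in (WS, SOKOLOW_LYON, CORNELL, PEGUERO_LO_PRESTI):
            res = compute_criterion(criterion, amps, sex="male")
            strict = ThresholdConfig().strict[criterion]
            expected = (res.mmcv_mv > res.threshold_mv if strict
                        else res.mmcv_mv >= res.threshold_mv)
            assert res.positive == expected
            assert res.mmcv_mv == pytest.approx(res.per_combination_median_mv.max())


class TestEndToEnd:
    def test_engineered_overlap_positive_and_scaling_negative(self):
        """A record built with s(V2)+r(V3) ~ 2.5 mV is WS positive; halving
        every amplitude drops it below threshold."""
        morph = (BeatMorphology.default(noise_sd_mv=0.005)
                 .with_rs("V2", s_mv=-1.4).with_rs("V3", r_mv=1.1))
        record, _ = generate_record(morph, seed=21)
        res = evaluate_record(record, criteria=(WS,))
        assert res.results[WS].positive
        assert res.results[WS].mmcv_mv == pytest.approx(2.5, abs=0.1)

        halved = (BeatMorphology.default(noise_sd_mv=0.005)
                  .with_rs("V2", s_mv=-0.7).with_rs("V3", r_mv=0.55))
        for lead in halved.lead_waves:
            waves = {w: (a / 2 if w not in ("V2", "V3") else a, o, wd)
                     for w, (a, o, wd) in halved.lead_waves[lead].items()}
            halved.lead_waves[lead] = waves
        record2, _ = generate_record(halved, seed=21)
        res2 = evaluate_record(record2, criteria=(WS,))
        assert not res2.results[WS].positive

    def test_qc_failure_raises_unless_overridden(self, flat_record):
        with pytest.raises(QCError):
            evaluate_record(flat_record)

    def test_unknown_criterion_rejected(self, clean_record):
        record, _ = clean_record
        with pytest.raises(ValueError, match="romhilt"):
            evaluate_record(record, criteria=("romhilt",))

    def test_deterministic_for_fixed_input(self, clean_record):
        record, _ = clean_record
        a = evaluate_record(record, criteria=(WS,)).results[WS]
        b = evaluate_record(record, criteria=(WS,)).results[WS]
        assert a.mmcv_mv == b.mmcv_mv and a.positive == b.positive
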