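"""Evaluation statistics: confusion metrics, McNemar, ROC/AUROC, Pearson."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecglvh import (confusion_metrics, evaluate_criterion, mcnemar, pearson,
                    roc_and_auroc)


def auroc_oracle(scores, labels):
    """Brute-force Mann-Whitney pair counting: ties credited one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_definitional_rates(self):
        calls = np.r_[np.ones(30), np.zeros(70), np.ones(34), np.zeros(66)] > 0
        labels = np.r_[np.ones(100), np.zeros(100)] > 0
        rep = confusion_metrics(calls, labels)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (30, 70, 34, 66)
        assert rep.sensitivity == pytest.approx(0.30)
        assert rep.specificity == pytest.approx(0.66)
        assert rep.n == rep.tp + rep.fp + rep.tn + rep.fn == 200

    def test_perfect_agreement_with_zero_cells_corrected(self):
        calls = np.array([True, True, False, False])
        rep = confusion_metrics(calls, calls)
        assert rep.accuracy == 1.0
        assert rep.odds_ratio_corrected
        # Haldane-Anscombe: (2.5 * 2.5) / (0.5 * 0.5)
        assert rep.odds_ratio == pytest.approx(25.0)

    def test_total_disagreement(self):
        calls = np.array([True, False, True, False])
        rep = confusion_metrics(calls, ~calls)
        assert rep.accuracy == 0.0

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                    max_size=60), st.integers(0, 1000))
    @settings(max_examples=100, deadline=None)
    def test_counts_sum_and_permutation_invariance(self, pairs, seed):
        calls, labels = map(np.array, zip(*pairs))
        rep = confusion_metrics(calls, labels)
        assert rep.tp + rep.fp + rep.tn + rep.fn == len(pairs)
        perm = np.random.default_rng(seed).permutation(len(pairs))
        rep2 = confusion_metrics(calls[perm], labels[perm])
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (rep2.tp, rep2.fp, rep2.tn, rep2.fn)


class TestMcNemar:
    def test_formula_arithmetic(self):
        """b=30, c=10 discordant pairs give chi2 = 400/40 = 10."""
        calls = np.r_[np.ones(30), np.zeros(10), np.ones(5)] > 0
        labels = np.r_[np.zeros(30), np.ones(10), np.ones(5)] > 0
        chi2, p, exact = mcnemar(calls, labels)
        assert chi2 == pytest.approx(10.0)
        assert not exact
        assert 0 < p < 0.01

    def test_symmetric_discordance_is_null(self):
        calls = np.array([True, False, True, False] * 10)
        labels = np.array([False, True, False, True] * 10)
        chi2, p, _ = mcnemar(calls, labels)
        assert chi2 == 0.0
        assert p == 1.0

    def test_degenerate_no_discordance(self):
        calls = np.array([True, False, True])
        chi2, p, exact = mcnemar(calls, calls)
        assert (chi2, p, exact) == (0.0, 1.0, True)

    def test_small_counts_use_exact_binomial(self):
        calls = np.r_[np.ones(6), np.zeros(2)] > 0
        labels = np.r_[np.zeros(6), np.ones(2)] > 0
        chi2, p, exact = mcnemar(calls, labels)
        assert exact
        # two-sided binomial: 2 * P(X <= 2 | n=8, 1/2)
        import math
        assert p == pytest.approx(2 * sum(
            math.comb(8, k) for k in (0, 1, 2)) / 2 ** 8, rel=1e-9)

    def test_type_one_error_rate_near_nominal(self):
        """Independent calls vs labels: rejection rate at alpha=0.05 stays in
        [0.01, 0.12] over 200 seeded replicates (n=200 each)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(200):
            calls = rng.uniform(size=200) < 0.5
            labels = rng.uniform(size=200) < 0.5
            _, p, _ = mcnemar(calls, labels)
            rejections += p < 0.05
        assert 0.01 <= rejections / 200 <= 0.12


class TestROC:
    def test_perfect_separation(self):
        _, _, auroc = roc_and_auroc([0.9, 0.8, 0.2, 0.1],
                                    [True, True, False, False])
        assert auroc == 1.0

    def test_all_ties_is_chance(self):
        _, _, auroc = roc_and_auroc([1.0] * 6, [True, False] * 3)
        assert auroc == pytest.approx(0.5)

    def test_hand_counted_pairs(self):
        _, _, auroc = roc_and_auroc([3, 2, 1, 0], [True, False, True, False])
        assert auroc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            roc_and_auroc([1.0, 2.0], [True, True])

    def test_sweep_equals_pairwise_oracle(self):
        """Threshold-sweep AUROC equals brute-force Mann-Whitney counting,
        exactly without ties and to 1e-12 with ties (500 seeded vectors)."""
        rng = np.random.default_rng(77)
        for trial in range(500):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            if trial % 2:
                scores = rng.choice([0.0, 0.5, 1.0, 1.5], size=n)  # heavy ties
                if len(set(scores[labels])) == 0 or labels.all() or not labels.any():
                    continue
            else:
                scores = rng.normal(size=n)
            _, _, auroc = roc_and_auroc(scores, labels)
            assert auroc == pytest.approx(auroc_oracle(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = rng.uniform(size=60) < 0.4
        _, _, a0 = roc_and_auroc(scores, labels)
        _, _, a1 = roc_and_auroc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a0, abs=1e-12)

    def test_roc_points_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(9)
        points, _, _ = roc_and_auroc(rng.normal(size=40), rng.uniform(size=40) < 0.5)
        fpr, tpr = map(np.array, zip(*points))
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert (fpr[0], tpr[0]) == (0.0, 0.0) and (fpr[-1], tpr[-1]) == (1.0, 1.0)


class TestPearson:
    def test_exact_linearity(self):
        scores = np.arange(10.0)
        assert pearson(scores, 2 * scores + 1) == pytest.approx(1.0)
        assert pearson(scores, -scores) == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones(5), np.arange(5.0))


class TestFullReport:
    def test_combined_report_fields(self):
        rng = np.random.default_rng(3)
        lvmi = rng.uniform(60, 160, 100)
        scores = 0.02 * lvmi + rng.normal(0, 0.1, 100)
        labels = lvmi > 100
        calls = scores > 2.0
        rep = evaluate_criterion(scores, calls, labels, lvmi=lvmi)
        assert rep.n == 100
        assert 0.9 < rep.auroc <= 1.0
        assert 0.9 < rep.pearson_r <= 1.0
        assert np.isfinite(rep.mcnemar_p)

    def test_json_serialization(self, tmp_path):
        rep = evaluate_criterion([1.0, 2.0, 3.0, 4.0],
                                 [False, False, True, True],
                                 [False, True, False, True])
        path = tmp_path / "rep.json"
        rep.to_json(path)
        import json
        data = json.loads(path.read_text())
        assert data["n"] == 4 and "auroc" in data
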