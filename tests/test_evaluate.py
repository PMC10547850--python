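"""Evaluation statistics against independent enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hepajac.evaluate import (
    paired_comparison,
    regional_agreement,
    roc_auc,
    voxelwise_pearson,
)


def _auc_pair_counting(scores, labels):
    """O(n^2) oracle: P(score_pos > score_neg) + 1/2 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _wilcoxon_sign_enumeration(diffs):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p = 2.0 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


class TestVoxelwisePearson:
    def _mask(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:6, 2:6, 2:6] = True
        return m

    def test_affine_relation_gives_unit_r(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((8, 8, 8))
        mask = self._mask()
        assert voxelwise_pearson(a, 2 * a + 3, mask) == pytest.approx(1.0)
        assert voxelwise_pearson(a, -a, mask) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        a = np.zeros((8, 8, 8))
        b = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        idx = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)] + [
            (i, j, 1) for i in range(2) for j in range(3)
        ]
        vals_a = [1, 2, 3, 4, 1, 2, 3, 4, 2, 3]
        vals_b = [1, 3, 2, 4, 1, 3, 2, 4, 3, 2]
        for (i, j, k), va, vb in zip(idx, vals_a, vals_b):
            mask[i, j, k] = True
            a[i, j, k], b[i, j, k] = va, vb
        expect = np.corrcoef(vals_a, vals_b)[0, 1]
        assert voxelwise_pearson(a, b, mask) == pytest.approx(expect)

    def test_zero_variance_flagged(self):
        mask = self._mask()
        with pytest.raises(ValueError):
            voxelwise_pearson(np.ones((8, 8, 8)), np.zeros((8, 8, 8)), mask)


class TestPairedComparison:
    def test_identical_lists_degenerate_p_one(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(0, 1, 12)
        pc = paired_comparison(r, r.copy())
        assert pc.wilcoxon_p == 1.0
        assert pc.n_zero_diffs == 12

    def test_all_positive_diffs_exact_p(self):
        base = np.linspace(0.1, 0.5, 5)
        pc = paired_comparison(base + np.array([1, 2, 3, 4, 5]) / 10.0, base)
        assert pc.wilcoxon_p == pytest.approx(2 / 32)

    def test_exact_p_matches_sign_enumeration(self):
        rng = np.random.default_rng(2)
        for n in (6, 8, 10):
            for _ in range(5):
                diffs = rng.standard_normal(n)
                while np.unique(np.abs(diffs)).size < n or np.any(diffs == 0):
                    diffs = rng.standard_normal(n)
                base = rng.uniform(0, 1, n)
                pc = paired_comparison(base + diffs, base)
                assert pc.wilcoxon_p == pytest.approx(_wilcoxon_sign_enumeration(diffs))

    def test_shapiro_statistic_bounded(self):
        rng = np.random.default_rng(3)
        pc = paired_comparison(rng.uniform(0, 1, 20), rng.uniform(0, 1, 20))
        for w, p in (pc.shapiro_pred, pc.shapiro_dose):
            assert 0 < w <= 1 and 0 <= p <= 1

    def test_summary_table_shape(self):
        rng = np.random.default_rng(4)
        pc = paired_comparison(rng.uniform(0, 1, 10), rng.uniform(0, 1, 10))
        s = pc.summary()
        assert list(s.distribution) == ["predicted_vs_dir", "dose_vs_dir_opposite"]


class TestRegionalAgreement:
    def _rows(self, vals, tag):
        return pd.DataFrame(
            {"case_id": [f"c{i}" for i in range(len(vals))], "region": tag,
             "mean_dv_pct": vals}
        )

    def test_perfect_agreement(self):
        t = self._rows([-10.0, 0.0, 12.0, -25.0], "seg2")
        out = regional_agreement(t, t)
        assert out.iloc[0].pearson_r == pytest.approx(1.0)
        assert out.iloc[0].r2_identity == pytest.approx(1.0)

    def test_halved_predictions_keep_r_but_lose_r2(self):
        truth = np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
        out = regional_agreement(self._rows(truth / 2, "seg2"), self._rows(truth, "seg2"))
        row = out.iloc[0]
        assert row.pearson_r == pytest.approx(1.0)
        # closed form: 1 - sum((t/2 - t)^2)/sum(t^2) = 0.75
        assert row.r2_identity == pytest.approx(0.75)

    def test_constant_prediction_degenerate(self):
        truth = np.array([-20.0, -10.0, 0.0, 10.0])
        out = regional_agreement(self._rows([0, 0, 0, 0], "seg2"), self._rows(truth, "seg2"))
        row = out.iloc[0]
        assert np.isnan(row.pearson_r)
        assert row.r2_identity <= 0 + 1e-12


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_printed_example(self):
        # positives {0.9, 0.3} vs negatives {0.7, 0.2, 0.1}: 5 of 6 pairs won
        assert roc_auc([0.9, 0.3, 0.7, 0.2, 0.1], [1, 1, 0, 0, 0]) == pytest.approx(5 / 6)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 12))
            scores = rng.integers(0, 5, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                _auc_pair_counting(scores, labels)
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])
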