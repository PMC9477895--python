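"""Association statistics against independent oracles.

Each statistic is checked against a brute-force oracle built from first
principles in this file (pair enumeration for AUC, full permutation for
Spearman, sign enumeration for Wilcoxon, normal equations for OLS,
closed-form 2×2 identities for phi and the logistic odds ratio) — never
against the implementation's own code path.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from iopchart import (classify_progression, cutoff_metrics, linear_assoc,
                      logistic_or, paired_eye_phi, roc_curve, spearman,
                      wilcoxon_paired)
from iopchart.errors import (DegenerateLabels, InsufficientData,
                             SeparationWarning, StatisticUndefined)

# ---------------------------------------------------------------- oracles


def auc_pair_oracle(flags, scores):
    """Mann–Whitney probability by explicit pair enumeration, ties = 1/2."""
    pos = [s for f, s in zip(flags, scores) if f]
    neg = [s for f, s in zip(flags, scores) if not f]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def midranks(v):
    """Average ranks computed from scratch by sorting."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_perm_oracle(x, y):
    """(rho, exact two-sided p) by full permutation of y."""
    def corr(a, b):
        a = np.asarray(a) - np.mean(a)
        b = np.asarray(b) - np.mean(b)
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = corr(midranks(x), midranks(y))
    ry = midranks(y)
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(corr(midranks(x), list(perm))) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


def wilcoxon_enum_oracle(x, y):
    """Exact two-sided signed-rank p by enumerating every sign pattern."""
    d = [a - b for a, b in zip(x, y) if a != b]
    ranks = midranks([abs(v) for v in d])
    w = sum(r for r, v in zip(ranks, d) if v > 0)
    mean_w = sum(ranks) / 2.0
    count = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        total += 1
        w_perm = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w_perm - mean_w) >= abs(w - mean_w) - 1e-12:
            count += 1
    return count / total


# ------------------------------------------------------------- ROC / AUC


class TestRoc:
    def test_perfect_separation(self):
        _, auc = roc_curve([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0])
        assert auc == pytest.approx(1.0)

    def test_all_ties_is_chance(self):
        _, auc = roc_curve([0, 1, 0, 1], [5.0] * 4)
        assert auc == pytest.approx(0.5)

    def test_small_example_pair_enumeration(self):
        # 4 pos×neg pairs: 3>2, 3>0, 1>0 win; 1<2 loses -> 3/4
        flags, scores = [1, 1, 0, 0], [3.0, 1.0, 2.0, 0.0]
        _, auc = roc_curve(flags, scores)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(auc_pair_oracle(flags, scores))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        flags = rng.random(n) < 0.5
        if flags.all() or not flags.any():
            flags[0] = ~flags[0]
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
        _, auc = roc_curve(flags, scores)
        assert auc == pytest.approx(auc_pair_oracle(flags, scores), abs=1e-12)

    def test_degenerate_labels(self):
        with pytest.raises(DegenerateLabels):
            roc_curve([1, 1, 1], [1.0, 2.0, 3.0])


class TestCutoffs:
    def test_counting_example(self):
        flags = [1, 1, 1, 1, 0, 0]
        tmax = [16, 14, 23, 15, 13, 25]
        res = cutoff_metrics(flags, tmax, 15)
        assert res.sensitivity == pytest.approx(0.75)  # 3 of 4 ≥ 15
        assert res.specificity == pytest.approx(0.5)

    def test_extreme_cutoffs(self):
        flags, tmax = [1, 0], [10.0, 20.0]
        low = cutoff_metrics(flags, tmax, 0)
        assert low.sensitivity == 1.0 and low.specificity == 0.0
        high = cutoff_metrics(flags, tmax, 99)
        assert high.sensitivity == 0.0 and high.specificity == 1.0

    def test_monotone_in_cutoff_and_roc_consistency(self, rng):
        """Sensitivity never rises and specificity never falls as the
        cutoff grows, and ROC points reproduce the cutoff metrics."""
        flags = rng.random(60) < 0.5
        flags[0], flags[1] = True, False
        tmax = rng.integers(8, 30, 60).astype(float)
        prev_sens, prev_spec = 1.1, -0.1
        for cutoff in range(8, 31):
            r = cutoff_metrics(flags, tmax, cutoff)
            assert r.sensitivity <= prev_sens + 1e-12
            assert r.specificity >= prev_spec - 1e-12
            prev_sens, prev_spec = r.sensitivity, r.specificity
        points, _ = roc_curve(flags, tmax)
        for cutoff in (15.0, 22.0):
            r = cutoff_metrics(flags, tmax, cutoff)
            assert any(np.isclose(fpr, 1 - r.specificity)
                       and np.isclose(tpr, r.sensitivity)
                       for fpr, tpr in points)


# ------------------------------------------------------------- Spearman


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).estimate == 1.0
        assert spearman([1, 2, 3, 4], [9, 7, 5, 3]).estimate == -1.0

    def test_tied_data_vs_permutation_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        res = spearman(x, y)
        rho, p = spearman_perm_oracle(x, y)
        assert res.estimate == pytest.approx(rho, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_small_n_exact_p_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        x = rng.integers(0, 6, n).astype(float)
        y = rng.integers(0, 6, n).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            x[0], y[0] = x[0] + 7, y[0] + 7
        res = spearman(x, y)
        rho, p = spearman_perm_oracle(list(x), list(y))
        assert res.estimate == pytest.approx(rho, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_large_n_agrees_with_scipy(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.estimate == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_undefined_on_constant(self):
        with pytest.raises(StatisticUndefined):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


# ------------------------------------------------------ paired-eye phi


class TestPhi:
    @staticmethod
    def _flags_from_table(a, b, c, d):
        left = [1] * (a + b) + [0] * (c + d)
        right = [1] * a + [0] * b + [1] * c + [0] * d
        return left, right

    def test_perfect_concordance(self):
        left, right = self._flags_from_table(5, 0, 0, 5)
        assert paired_eye_phi(left, right).estimate == pytest.approx(1.0)

    def test_independence(self):
        left, right = self._flags_from_table(25, 25, 25, 25)
        assert paired_eye_phi(left, right).estimate == pytest.approx(0.0)

    def test_hand_evaluated_table(self):
        left, right = self._flags_from_table(20, 10, 5, 15)
        res = paired_eye_phi(left, right)
        expected = (20 * 15 - 10 * 5) / np.sqrt(30 * 20 * 25 * 25)
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        assert res.estimate == pytest.approx(0.408, abs=0.001)

    def test_chi2_identity_and_scipy_agreement(self):
        left, right = self._flags_from_table(18, 7, 9, 16)
        res = paired_eye_phi(left, right)
        n = 50
        chi2_ref = sps.chi2_contingency(np.array([[18, 7], [9, 16]]),
                                        correction=False)
        assert res.ancillary["chi2"] == pytest.approx(n * res.estimate ** 2)
        assert res.ancillary["chi2"] == pytest.approx(chi2_ref.statistic)
        assert res.p_value == pytest.approx(chi2_ref.pvalue, rel=1e-9)

    def test_variance_inflation_deflates_chi2(self):
        left, right = self._flags_from_table(20, 10, 5, 15)
        plain = paired_eye_phi(left, right)
        adj = paired_eye_phi(left, right, variance_inflation=2.0)
        assert adj.estimate == plain.estimate
        assert adj.ancillary["chi2"] == pytest.approx(
            plain.ancillary["chi2"] / 2.0)
        assert adj.p_value > plain.p_value

    def test_zero_margin_undefined(self):
        with pytest.raises(StatisticUndefined):
            paired_eye_phi([1, 1, 1], [1, 0, 1])


# ------------------------------------------------- logistic / linear


class TestLogistic:
    def test_binary_covariate_closed_form(self):
        """Saturated binary-covariate logistic: OR = ad/bc exactly."""
        x = [0] * 30 + [1] * 30
        y = [1] * 20 + [0] * 10 + [1] * 10 + [0] * 20
        res = logistic_or(y, x)
        assert res.estimate == pytest.approx(0.25, abs=1e-3)

    def test_null_recovery(self, rng):
        x = rng.normal(size=2000)
        y = rng.random(2000) < 0.5
        res = logistic_or(y, x)
        assert 0.9 <= res.estimate <= 1.1

    def test_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.astype(bool)
        with pytest.warns(SeparationWarning):
            res = logistic_or(y, x)
        assert np.isinf(res.estimate) and res.ancillary["separation"]


class TestLinear:
    def test_exact_line(self):
        res = linear_assoc([2, 4, 6, 8], [1, 2, 3, 4])
        assert res.estimate == pytest.approx(2.0)
        assert res.p_value < 1e-10

    def test_orthogonal_constant_response(self):
        res = linear_assoc([5, 5, 5, 5], [1, 2, 3, 4])
        assert res.estimate == pytest.approx(0.0)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=25)
        y = 1.5 * x + rng.normal(size=25)
        res = linear_assoc(y, x)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.estimate == pytest.approx(beta[1], abs=1e-10)
        assert res.ancillary["intercept"] == pytest.approx(beta[0], abs=1e-10)

    def test_zero_variance_covariate(self):
        with pytest.raises(StatisticUndefined):
            linear_assoc([1, 2, 3], [4, 4, 4])


# ---------------------------------------------------------- Wilcoxon


class TestWilcoxon:
    def test_all_positive_six_pairs(self):
        x = [5, 6, 7, 8, 9, 10]
        y = [1, 2, 3, 4, 5, 6]
        res = wilcoxon_paired(x, y)
        assert res.p_value == pytest.approx(2 / 64)  # 2 of 2^6 patterns

    def test_identical_vectors_undefined(self):
        with pytest.raises(StatisticUndefined):
            wilcoxon_paired([1, 2, 3], [1, 2, 3])

    def test_normal_approx_close_to_enumeration_at_n15(self, rng):
        x = rng.normal(0.4, 1.0, 15)
        y = np.zeros(15)
        res = wilcoxon_paired(x, y)
        assert res.p_value == pytest.approx(wilcoxon_enum_oracle(x, y),
                                            abs=0.01)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_small_n_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        x = rng.integers(-4, 8, n).astype(float)
        y = np.zeros(n)
        if np.all(x == 0):
            x[0] = 1.0
        res = wilcoxon_paired(x, y)
        assert res.p_value == pytest.approx(wilcoxon_enum_oracle(x, y),
                                            abs=1e-12)


# ------------------------------------------------------- progression


class TestProgression:
    def test_rule_application(self):
        rec = classify_progression({"TS": -2.0, "T": -0.3, "TI": -0.4},
                                   {"TS": 0.01}, normative_slope=-0.5,
                                   alpha=0.05)
        assert rec.progressor and rec.worst_quadrant == "TS"

    def test_mild_thinning_not_progression(self):
        rec = classify_progression({s: -0.1 for s in ("G", "TS", "T", "TI")})
        assert not rec.progressor

    def test_insignificant_slope_ignored(self):
        rec = classify_progression({"TS": -2.0}, {"TS": 0.2})
        assert not rec.progressor

    def test_tie_break_order(self):
        rec = classify_progression({"TS": -1.0, "TI": -1.0, "T": -0.2})
        assert rec.worst_quadrant == "TS"

    def test_no_sectors_rejected(self):
        with pytest.raises(InsufficientData):
            classify_progression({})


# --------------------------------------------- null calibration sweep


class TestTypeIError:
    """Empirical size of the tests at nominal 0.05 under the null."""

    def test_spearman_and_wilcoxon_calibrated(self):
        rng = np.random.default_rng(2024)
        reps = 2000
        hits_s = hits_w = 0
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            hits_s += spearman(x, y).p_value < 0.05
            hits_w += wilcoxon_paired(x, y).p_value < 0.05
        assert 0.03 <= hits_s / reps <= 0.07
        assert 0.03 <= hits_w / reps <= 0.07

    def test_logistic_calibrated(self):
        rng = np.random.default_rng(99)
        reps = 400
        hits = 0
        for _ in range(reps):
            x = rng.normal(size=120)
            y = rng.random(120) < 0.5
            if y.all() or not y.any():
                continue
            hits += logistic_or(y, x).p_value < 0.05
        assert 0.02 <= hits / reps <= 0.08
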