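"""Progression and association analytics for paired-eye IOP cohorts.

Implements the analysis battery used on digitized 24-h profiles: a
transparent RNFL-slope progression rule (sector progresses when its
thinning rate falls below a normative age-related decline), cut-off
sensitivity/specificity and ROC curves for peak-IOP criteria, Spearman
rank correlation, the paired-eye phi coefficient with a pluggable
inter-ocular dependency adjustment, binomial logistic regression (odds
ratio per unit of the covariate), ordinary linear regression, and the
paired Wilcoxon signed-rank test.

All p-values are reported unadjusted for multiplicity; report builders
flag the number of tests performed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import (DegenerateLabels, InsufficientData, SeparationWarning,
                     StatisticUndefined)

#: Peripapillary OCT sectors: global, temporal-superior, temporal,
#: temporal-inferior.  Worst-quadrant selection considers the three
#: quadrants only (G is a composite), ties broken in the order TS, TI, T.
SECTORS = ("G", "TS", "T", "TI")
QUADRANTS = ("TS", "TI", "T")

#: Default normative RNFL slope, µm/year: ordinary age-related thinning.
DEFAULT_NORMATIVE_SLOPE = -0.5


@dataclass
class AssociationResult:
    """One association statistic with its p-value and sample size."""

    statistic: str
    estimate: float
    p_value: float
    n: int
    ancillary: dict = field(default_factory=dict)


@dataclass
class CutoffResult:
    """Sensitivity/specificity of calling progression when T_max ≥ cutoff."""

    cutoff: float
    sensitivity: float
    specificity: float
    source: str = "24H"  # or "OP-IOP"


@dataclass
class ProgressionRecord:
    """Per-eye progression classification from sector RNFL slopes."""

    sector_slopes: dict[str, float]
    sector_progressing: dict[str, bool]
    progressor: bool
    worst_quadrant: str | None


def classify_progression(sector_slopes: dict[str, float],
                         sector_pvalues: dict[str, float] | None = None,
                         normative_slope: float = DEFAULT_NORMATIVE_SLOPE,
                         alpha: float = 0.05) -> ProgressionRecord:
    """Apply the normative-slope progression rule.

    A sector progresses when its slope is below ``normative_slope`` and,
    if a per-sector p-value is supplied, that p-value is below ``alpha``.
    The eye is a progressor when at least one sector progresses.  The
    worst quadrant is the most negative slope among TS/TI/T.
    """
    slopes = {s: v for s, v in sector_slopes.items() if v is not None}
    if not slopes:
        raise InsufficientData("no sector slopes supplied")
    pvals = sector_pvalues or {}
    progressing = {}
    for sector, slope in slopes.items():
        significant = sector not in pvals or pvals[sector] < alpha
        progressing[sector] = bool(slope < normative_slope and significant)
    quads = [q for q in QUADRANTS if q in slopes]
    worst = None
    if quads:
        best_slope = min(slopes[q] for q in quads)
        worst = next(q for q in QUADRANTS if q in slopes and slopes[q] == best_slope)
    return ProgressionRecord(sector_slopes=dict(slopes),
                             sector_progressing=progressing,
                             progressor=any(progressing.values()),
                             worst_quadrant=worst)


def _check_two_classes(flags: np.ndarray) -> None:
    if flags.all() or not flags.any():
        raise DegenerateLabels("need at least one case in each class")


def cutoff_metrics(progressor_flags, t_max_values, cutoff: float,
                   source: str = "24H") -> CutoffResult:
    """Sensitivity and specificity of the criterion ``T_max ≥ cutoff``."""
    flags = np.asarray(progressor_flags, dtype=bool)
    tmax = np.asarray(t_max_values, dtype=float)
    if flags.shape != tmax.shape:
        raise ValueError("flags and values must be paired")
    _check_two_classes(flags)
    sens = float(np.mean(tmax[flags] >= cutoff))
    spec = float(np.mean(tmax[~flags] < cutoff))
    return CutoffResult(cutoff=float(cutoff), sensitivity=sens,
                        specificity=spec, source=source)


def roc_curve(progressor_flags, scores) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC for a continuous score.

    Thresholds sweep the unique score values (predict positive when
    score ≥ threshold).  The trapezoid AUC equals the Mann–Whitney
    probability with ties counted one half.
    """
    flags = np.asarray(progressor_flags, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(flags)
    order = np.argsort(-scores, kind="stable")
    flags_sorted = flags[order]
    scores_sorted = scores[order]
    n_pos, n_neg = int(flags.sum()), int((~flags).sum())
    tps = np.cumsum(flags_sorted)
    fps = np.cumsum(~flags_sorted)
    # keep only the last index of each tied score block
    last = np.r_[np.flatnonzero(np.diff(scores_sorted)), len(scores_sorted) - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


def spearman(x, y) -> AssociationResult:
    """Spearman rank correlation (mid-ranks for ties).

    The p-value comes from the exact permutation distribution for n ≤ 8
    and from the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientData("Spearman needs n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise StatisticUndefined("zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc ** 2).sum())
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            ryp = np.asarray(perm)
            r = float(rxc @ (ryp - ryp.mean()) /
                      (denom * np.sqrt(((ryp - ryp.mean()) ** 2).sum())))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return AssociationResult("spearman_rho", rho, min(1.0, p), n)


def paired_eye_phi(left_flags, right_flags,
                   variance_inflation: float = 1.0) -> AssociationResult:
    """Phi coefficient of paired left/right binary outcomes.

    ``chi2 = n·phi² / variance_inflation``; the inflation factor is the
    pluggable inter-ocular dependency adjustment (1 = unadjusted).  The
    p-value uses the chi-square distribution with one degree of freedom.
    """
    left = np.asarray(left_flags, dtype=bool)
    right = np.asarray(right_flags, dtype=bool)
    if left.shape != right.shape:
        raise ValueError("flag vectors must be paired")
    n = len(left)
    if n < 2:
        raise InsufficientData("need n >= 2 pairs")
    a = int(np.sum(left & right))
    b = int(np.sum(left & ~right))
    c = int(np.sum(~left & right))
    d = int(np.sum(~left & ~right))
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise StatisticUndefined("degenerate 2x2 table (zero margin)")
    phi = (a * d - b * c) / np.sqrt(np.prod([float(m) for m in margins]))
    chi2 = n * phi ** 2 / variance_inflation
    p = float(sps.chi2.sf(chi2, df=1))
    return AssociationResult("phi", float(phi), p, n,
                             ancillary={"table": [[a, b], [c, d]], "chi2": chi2,
                                        "variance_inflation": variance_inflation})


def logistic_or(outcome_flags, covariate) -> AssociationResult:
    """Binomial logistic regression of a binary outcome on one covariate.

    Reports the odds ratio per covariate unit (exp of the ML slope) with
    its Wald p-value.  Complete separation yields an infinite odds ratio
    and a ``SeparationWarning``.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome_flags, dtype=float)
    x = np.asarray(covariate, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    _check_two_classes(y.astype(bool))
    if np.var(x) == 0:
        raise StatisticUndefined("covariate has zero variance")
    # complete separation: some threshold splits the classes perfectly
    if max(x[y == 0].max(), -np.inf) < min(x[y == 1].min(), np.inf) \
            or x[y == 1].max() < x[y == 0].min():
        warnings.warn("complete separation; odds ratio is infinite",
                      SeparationWarning)
        return AssociationResult("odds_ratio", float("inf"), 0.0, len(y),
                                 ancillary={"separation": True})
    design = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, design).fit(disp=0, maxiter=50, tol=1e-8)
    slope = float(fit.params[1])
    return AssociationResult(
        "odds_ratio", float(np.exp(slope)), float(fit.pvalues[1]), len(y),
        ancillary={"beta": slope, "se": float(fit.bse[1]),
                   "ci": [float(np.exp(v)) for v in fit.conf_int()[1]],
                   "separation": False})


def linear_assoc(response, covariate) -> AssociationResult:
    """Ordinary least squares of a continuous response on one covariate."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    if len(x) < 3:
        raise InsufficientData("linear regression needs n >= 3")
    if np.var(x) == 0:
        raise StatisticUndefined("covariate has zero variance")
    res = sps.linregress(x, y)
    return AssociationResult("beta", float(res.slope), float(res.pvalue), len(x),
                             ancillary={"intercept": float(res.intercept),
                                        "r": float(res.rvalue),
                                        "se": float(res.stderr)})


def _wilcoxon_exact_p(ranks: np.ndarray, w_pos: float) -> float:
    """Two-sided exact p by enumerating all sign assignments of the ranks."""
    n = len(ranks)
    total = 1 << n
    mean_w = ranks.sum() / 2.0
    dev = abs(w_pos - mean_w)
    count = 0
    for signs in range(total):
        w = sum(ranks[i] for i in range(n) if signs >> i & 1)
        if abs(w - mean_w) >= dev - 1e-12:
            count += 1
    return count / total


def wilcoxon_paired(x, y) -> AssociationResult:
    """Paired Wilcoxon signed-rank test (zero differences dropped).

    Exact two-sided p by sign enumeration for n ≤ 12 after dropping
    zeros; otherwise the normal approximation with continuity correction
    and tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    d = x - y
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise StatisticUndefined("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 12:
        p = _wilcoxon_exact_p(ranks, w_pos)
    else:
        mean_w = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        var_w = (n * (n + 1) * (2 * n + 1) - (counts ** 3 - counts).sum() / 2.0) / 24.0
        z = (w_pos - mean_w - 0.5 * np.sign(w_pos - mean_w)) / np.sqrt(var_w)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return AssociationResult("wilcoxon_w", w_pos, min(1.0, p), n)
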