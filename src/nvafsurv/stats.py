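"""Paired diagnostic accuracy, agreement, and ordinal concordance statistics.

Implements the statistical battery for comparing two surveillance modes
against a gold standard on the same subjects:

* 2x2 accuracy metrics with the F score;
* McNemar's test (and the exact binomial sign test for sparse discordance)
  for paired sensitivity/specificity comparisons;
* the Leisenring-Alonzo-Pepe generalized score statistic for comparing
  positive and negative predictive values in a paired design;
* Cohen's kappa and the two-way random-effects ICC(2,1), each with
  subject-resampling percentile bootstrap confidence intervals;
* the C index and Somers' D (D = 2C - 1) for ordinal 0-9 risk scores, with
  delete-one jackknife standard errors and a paired Z comparison of two
  predictors' concordance with the same gold scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps


class TestMethod(Enum):
    MCNEMAR = "mcnemar"
    EXACT_BINOMIAL = "exact_binomial"
    GENERALIZED_SCORE = "generalized_score"


#: Below this many discordant pairs the exact binomial replaces McNemar.
EXACT_TEST_CUTOFF = 25


@dataclass
class DxMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def f_score(self) -> float:
        return f_score(self.sensitivity, self.ppv)


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    method: TestMethod
    discordant_b: int = 0
    discordant_c: int = 0
    degenerate: bool = False


@dataclass
class AgreementStats:
    estimate: float
    ci: tuple[float, float]
    n_boot: int
    degenerate: bool = False


@dataclass
class ConcordanceResult:
    c_index: float
    somers_d: float
    se_d: float


@dataclass
class ConcordanceComparison:
    z: float
    p_value: float
    delta_d: float = 0.0
    degenerate: bool = False


def f_score(sensitivity: float, ppv: float) -> float:
    """Harmonic mean of sensitivity (recall) and PPV (precision)."""
    if sensitivity + ppv == 0 or np.isnan(sensitivity) or np.isnan(ppv):
        return 0.0
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def _binarize(values, threshold):
    arr = np.asarray(values)
    if threshold is None:
        return arr.astype(bool)
    return arr >= threshold


def paired_confusion(gold, test, threshold: float | None = None) -> DxMetrics:
    """2x2 metrics of one test against the gold labels.

    Binary inputs are used as-is; ordinal scores are dichotomized at
    ``threshold`` (>= threshold is positive), e.g. >=2 for CHA2DS2-VASc and
    >=3 for HAS-BLED.
    """
    g = _binarize(gold, threshold)
    t = _binarize(test, threshold)
    if g.size == 0:
        raise ValueError("empty input")
    if g.shape != t.shape:
        raise ValueError("gold and test labels differ in length")
    return DxMetrics(
        tp=int(np.sum(g & t)), fp=int(np.sum(~g & t)),
        fn=int(np.sum(g & ~t)), tn=int(np.sum(~g & ~t)))


def discordant_counts(gold, test1, test2, among: str = "positive",
                      threshold: float | None = None) -> tuple[int, int]:
    """(b, c) discordant pairs for a paired sensitivity or specificity test.

    ``among="positive"`` restricts to gold-positive subjects (sensitivity):
    b = test2 correct where test1 wrong, c = the reverse. ``"negative"``
    restricts to gold negatives (specificity).
    """
    g = _binarize(gold, threshold)
    t1 = _binarize(test1, threshold)
    t2 = _binarize(test2, threshold)
    if among == "positive":
        mask, correct1, correct2 = g, t1, t2
    elif among == "negative":
        mask, correct1, correct2 = ~g, ~t1, ~t2
    else:
        raise ValueError("among must be 'positive' or 'negative'")
    b = int(np.sum(mask & correct2 & ~correct1))
    c = int(np.sum(mask & correct1 & ~correct2))
    return b, c


def mcnemar_test(b: int, c: int,
                 continuity_correction: bool = False) -> PairedTestResult:
    """McNemar chi-square on the discordant pair counts, df = 1."""
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if b + c == 0:
        raise ValueError("McNemar undefined with no discordant pairs")
    diff = abs(b - c) - (1 if continuity_correction else 0)
    diff = max(diff, 0)
    stat = diff ** 2 / (b + c)
    p = float(sps.chi2.sf(stat, df=1))
    return PairedTestResult(float(stat), p, TestMethod.MCNEMAR, b, c)


def exact_binomial_test(b: int, c: int) -> PairedTestResult:
    """Two-sided sign test on the discordant split: doubled smaller binomial
    tail at p = 1/2, capped at 1."""
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    n = b + c
    if n == 0:
        return PairedTestResult(0.0, 1.0, TestMethod.EXACT_BINOMIAL, 0, 0,
                                degenerate=True)
    k = min(b, c)
    p = min(1.0, 2.0 * float(sps.binom.cdf(k, n, 0.5)))
    return PairedTestResult(float(k), p, TestMethod.EXACT_BINOMIAL, b, c)


def paired_proportion_test(b: int, c: int,
                           exact_cutoff: int = EXACT_TEST_CUTOFF
                           ) -> PairedTestResult:
    """Exact binomial when discordance is sparse (b + c < cutoff), else McNemar."""
    if b + c == 0:
        return exact_binomial_test(b, c)
    if b + c < exact_cutoff:
        return exact_binomial_test(b, c)
    return mcnemar_test(b, c)


def _gee_score(outcome: np.ndarray, z: np.ndarray,
               subject: np.ndarray) -> PairedTestResult:
    """Working-independence GEE score test for a binary marginal model with
    a single test-indicator covariate, empirical (subject-clustered)
    variance, evaluated under the null of a common mean."""
    mu = outcome.mean()
    zbar = z.mean()
    resid = (z - zbar) * (outcome - mu)
    u = resid.sum()
    # cluster by subject
    order = np.argsort(subject, kind="stable")
    s_sorted = subject[order]
    r_sorted = resid[order]
    cuts = np.flatnonzero(np.r_[True, s_sorted[1:] != s_sorted[:-1]])
    cluster_sums = np.add.reduceat(r_sorted, cuts)
    v = float(np.sum(cluster_sums ** 2))
    if v == 0.0:
        return PairedTestResult(0.0, 1.0, TestMethod.GENERALIZED_SCORE,
                                degenerate=(u != 0.0))
    stat = float(u * u / v)
    return PairedTestResult(stat, float(sps.chi2.sf(stat, df=1)),
                            TestMethod.GENERALIZED_SCORE)


def compare_predictive_values(gold, test1, test2,
                              threshold: float | None = None
                              ) -> tuple[PairedTestResult, PairedTestResult]:
    """Generalized score statistics comparing the two tests' PPVs and NPVs.

    Each subject contributes one record per test whose result selects it
    into the comparison: test-positive records for the PPV contrast (outcome
    = diseased) and test-negative records for the NPV contrast (outcome =
    not diseased). The score statistic is asymptotically chi-square with one
    degree of freedom under equal predictive values.
    """
    g = _binarize(gold, threshold).astype(float)
    t1 = _binarize(test1, threshold)
    t2 = _binarize(test2, threshold)
    n = g.size
    if n == 0:
        raise ValueError("empty input")
    subj = np.arange(n)

    def build(select1, select2, outcome):
        rows_s, rows_z, rows_y = [], [], []
        for z_val, sel in ((0, select1), (1, select2)):
            idx = np.flatnonzero(sel)
            rows_s.append(subj[idx])
            rows_z.append(np.full(idx.size, z_val, dtype=float))
            rows_y.append(outcome[idx])
        return (np.concatenate(rows_s), np.concatenate(rows_z),
                np.concatenate(rows_y))

    if not (t1.any() or t2.any()):
        raise ValueError("PPV comparison undefined: no subject tests positive")
    s, z, y = build(t1, t2, g)
    ppv_res = _gee_score(y, z, s)
    if not ((~t1).any() or (~t2).any()):
        raise ValueError("NPV comparison undefined: no subject tests negative")
    s, z, y = build(~t1, ~t2, 1.0 - g)
    npv_res = _gee_score(y, z, s)
    return ppv_res, npv_res


def permute_predictive_value_test(gold, test1, test2, which: str = "ppv",
                                  n_perm: int = 10000,
                                  seed: int | None = None) -> float:
    """Permutation reference for the generalized score statistic: randomly
    swap the paired test assignments within subjects."""
    rng = np.random.default_rng(seed)
    g = np.asarray(gold, dtype=bool)
    t1 = np.asarray(test1, dtype=bool)
    t2 = np.asarray(test2, dtype=bool)
    idx = 0 if which == "ppv" else 1
    obs = compare_predictive_values(g, t1, t2)[idx].statistic
    n = g.size
    count = 0
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        p1 = np.where(swap, t2, t1)
        p2 = np.where(swap, t1, t2)
        try:
            stat = compare_predictive_values(g, p1, p2)[idx].statistic
        except ValueError:
            stat = 0.0
        if stat >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def cohens_kappa(r1, r2, n_boot: int = 10000,
                 seed: int | None = None) -> AgreementStats:
    """Cohen's kappa with a subject-resampling percentile bootstrap CI."""
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least 2 subjects")

    def kappa(x, y) -> float:
        cats = np.union1d(x, y)
        n = x.size
        po = float(np.mean(x == y))
        pe = float(sum((np.mean(x == c)) * (np.mean(y == c)) for c in cats))
        if pe >= 1.0 - 1e-12:
            return float("nan")
        return (po - pe) / (1.0 - pe)

    point = kappa(a, b)
    degenerate = bool(np.isnan(point))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n = a.size
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        reps[i] = kappa(a[idx], b[idx])
    valid = reps[~np.isnan(reps)]
    if valid.size:
        ci = (float(np.percentile(valid, 2.5)),
              float(np.percentile(valid, 97.5)))
    else:
        ci = (float("nan"), float("nan"))
    return AgreementStats(point, ci, n_boot, degenerate)


def icc_two_way_random(ratings, n_boot: int = 10000,
                       seed: int | None = None) -> AgreementStats:
    """ICC(2,1): two-way random-effects, single-rater, absolute agreement.

    ``ratings`` is an n_subjects x n_raters matrix with no missing cells;
    the CI is a subject-resampling percentile bootstrap.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be n_subjects x n_raters with n,k >= 2")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    def icc(m: np.ndarray) -> tuple[float, bool]:
        n, k = m.shape
        grand = m.mean()
        row_means = m.mean(axis=1)
        col_means = m.mean(axis=0)
        ssr = k * float(np.sum((row_means - grand) ** 2))
        ssc = n * float(np.sum((col_means - grand) ** 2))
        sst = float(np.sum((m - grand) ** 2))
        sse = sst - ssr - ssc
        msr = ssr / (n - 1)
        msc = ssc / (k - 1)
        mse = sse / ((n - 1) * (k - 1))
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom <= 0 or msr <= 0:
            return 0.0, True
        return (msr - mse) / denom, False

    point, degenerate = icc(x)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        reps[i], _ = icc(x[idx])
    ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return AgreementStats(point, ci, n_boot, degenerate)


def _pair_counts(pred: np.ndarray, gold: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject row sums of concordant / discordant / gold-untied pairs."""
    gd = np.sign(gold[:, None] - gold[None, :])
    pd_ = np.sign(pred[:, None] - pred[None, :])
    untied = gd != 0
    conc = untied & (pd_ == gd)
    disc = untied & (pd_ == -gd)
    return (conc.sum(axis=1).astype(float), disc.sum(axis=1).astype(float),
            untied.sum(axis=1).astype(float))


def ordinal_concordance(pred, gold) -> ConcordanceResult:
    """C index and Somers' D of an ordinal predictor against ordinal gold.

    Over all pairs with differing gold values: concordant when the predictor
    ordering matches; predictor ties count half. D = 2C - 1 identically.
    ``se_d`` is the delete-one jackknife standard error.
    """
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gold, dtype=float)
    if p.shape != g.shape or p.ndim != 1:
        raise ValueError("pred and gold must be equal-length vectors")
    c_i, d_i, t_i = _pair_counts(p, g)
    t_total = t_i.sum() / 2.0
    if t_total == 0:
        raise ValueError("all gold values equal: concordance undefined")
    c_total = c_i.sum() / 2.0
    d_total = d_i.sum() / 2.0
    somers = (c_total - d_total) / t_total
    c_index = (c_total + 0.5 * (t_total - c_total - d_total)) / t_total
    d_jack = _jackknife_d(c_i, d_i, t_i, c_total, d_total, t_total)
    n = p.size
    se = float(np.sqrt((n - 1) / n * np.sum((d_jack - d_jack.mean()) ** 2)))
    return ConcordanceResult(float(c_index), float(somers), se)


def _jackknife_d(c_i, d_i, t_i, c_total, d_total, t_total) -> np.ndarray:
    c_del = c_total - c_i
    d_del = d_total - d_i
    t_del = t_total - t_i
    with np.errstate(invalid="ignore", divide="ignore"):
        d_jack = np.where(t_del > 0, (c_del - d_del) / np.maximum(t_del, 1e-300),
                          0.0)
    return d_jack


def compare_concordance(pred1, pred2, gold) -> ConcordanceComparison:
    """Paired Z test for the difference of two Somers' D values against the
    same gold, with the correlation handled by a paired delete-one jackknife
    of the difference."""
    p1 = np.asarray(pred1, dtype=float)
    p2 = np.asarray(pred2, dtype=float)
    g = np.asarray(gold, dtype=float)
    if not (p1.shape == p2.shape == g.shape) or g.ndim != 1:
        raise ValueError("inputs must be three equal-length vectors")
    c1, d1, t1 = _pair_counts(p1, g)
    c2, d2, t2 = _pair_counts(p2, g)
    t_total = t1.sum() / 2.0
    if t_total == 0:
        raise ValueError("all gold values equal: concordance undefined")
    D1 = (c1.sum() / 2 - d1.sum() / 2) / t_total
    D2 = (c2.sum() / 2 - d2.sum() / 2) / t_total
    delta = D1 - D2
    j1 = _jackknife_d(c1, d1, t1, c1.sum() / 2, d1.sum() / 2, t_total)
    j2 = _jackknife_d(c2, d2, t2, c2.sum() / 2, d2.sum() / 2, t_total)
    dj = j1 - j2
    n = g.size
    se = float(np.sqrt((n - 1) / n * np.sum((dj - dj.mean()) ** 2)))
    if se == 0.0:
        if abs(delta) < 1e-15:
            return ConcordanceComparison(0.0, 1.0, 0.0)
        return ConcordanceComparison(float("inf"), 0.0, float(delta),
                                     degenerate=True)
    z = float(delta / se)
    return ConcordanceComparison(z, float(2.0 * sps.norm.sf(abs(z))),
                                 float(delta))
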