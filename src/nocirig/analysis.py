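"""Quantitative analyses of stimulus delivery and withdrawal behavior.

The analyses here answer the questions a nocifensive-testing study asks of
its session logs:

* How stable is stimulus delivery?  (SNR in dB of a delivered-power trace;
  coefficient of variation across trials or testers.)
* Do two latency-measurement methods agree?  (Bland-Altman: paired
  differences vs. averages, tests of fixed and proportional bias, a 95 %
  prediction band, and the predicted difference at chosen latencies.)
* How does latency depend on stimulus intensity?  (Fast/slow
  classification at 75 ms, chi-square test of proportions across
  intensities, and power-law fits ``y = a * x**b`` obtained as linear
  regressions on log-log axes.)
* What is the withdrawal threshold?  (Logistic psychometric function in
  log-intensity; threshold is the intensity at 50 % response
  probability.)
* Do two groups differ in their latency distributions?  (Two-sample
  Kolmogorov-Smirnov on pooled trials, plus per-animal coefficients of
  variation compared by t test.)
* Are post-stimulus behaviors (licking, guarding, flinching) associated
  with withdrawal latency?  (Logistic or linear regression with a
  case-resampling bootstrap confidence interval.)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "AgreementReport",
    "PowerLawFit",
    "PsychometricFit",
    "BehaviorTrial",
    "AssociationResult",
    "DistributionComparison",
    "snr_db",
    "coefficient_of_variation",
    "bland_altman",
    "classify_fast_slow",
    "chi2_proportions",
    "fit_power_law",
    "fit_psychometric",
    "compare_latency_distributions",
    "behavior_latency_association",
]


# ---------------------------------------------------------------------------
# stimulus-delivery stability
# ---------------------------------------------------------------------------


def snr_db(values: Sequence[float]) -> float:
    """Signal-to-noise ratio ``10*log10(mean^2 / SD^2)`` in dB.

    SD uses the n-1 denominator.  A zero-variance input has undefined
    (infinite) SNR and raises; a zero mean returns -inf.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero variance")
    m = float(np.mean(x))
    if m == 0:
        return -math.inf
    return 10.0 * math.log10(m**2 / sd**2)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV = SD / mean (sample SD, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    m = float(np.mean(x))
    if m == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(np.std(x, ddof=1) / m)


# ---------------------------------------------------------------------------
# method agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman agreement between two latency-measurement methods.

    Differences are ``method1 - method2``; ``mean_diff`` with its
    one-sample t test addresses fixed bias, the least-squares line of
    difference on average addresses proportional bias.  ``prediction_band``
    maps a query average to the t-based 95 % prediction interval for a new
    difference; ``predicted_diff`` are the regression-line values at the
    requested query averages.
    """

    differences: np.ndarray
    averages: np.ndarray
    mean_diff: float
    t_fixed: float
    p_fixed: float
    slope: float
    intercept: float
    t_slope: float
    p_slope: float
    query_avgs: np.ndarray
    predicted_diff: np.ndarray
    prediction_band: np.ndarray  # (len(query), 2) lower/upper
    degenerate: bool = False


def bland_altman(
    pairs: Sequence[tuple[float, float]],
    query_avgs: Sequence[float] = (),
) -> AgreementReport:
    """Bland-Altman analysis of paired measurements.

    Plots (conceptually) the per-pair difference against the per-pair
    average, tests the mean difference against zero (fixed bias), fits the
    difference on the average by ordinary least squares (proportional
    bias), and evaluates the fitted line and its 95 % prediction band at
    ``query_avgs``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 finite pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    diff = arr[:, 0] - arr[:, 1]
    avg = arr.mean(axis=1)
    n = diff.size
    mean_diff = float(diff.mean())
    t_fixed, p_fixed = st.ttest_1samp(diff, 0.0)
    q = np.asarray(query_avgs, dtype=float)
    degenerate = bool(np.allclose(avg, avg[0]))
    if degenerate:
        warnings.warn("all averages equal; proportional-bias slope undefined", stacklevel=2)
        nanq = np.full(q.size, math.nan)
        return AgreementReport(
            diff, avg, mean_diff, float(t_fixed), float(p_fixed),
            math.nan, math.nan, math.nan, math.nan,
            q, nanq, np.full((q.size, 2), math.nan), degenerate=True,
        )
    res = st.linregress(avg, diff)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = diff - (intercept + slope * avg)
    dof = n - 2
    s = math.sqrt(float(np.sum(resid**2)) / dof) if dof > 0 else math.nan
    xbar = float(avg.mean())
    sxx = float(np.sum((avg - xbar) ** 2))
    pred = intercept + slope * q
    if dof > 0 and q.size:
        tcrit = st.t.ppf(0.975, dof)
        se = s * np.sqrt(1.0 + 1.0 / n + (q - xbar) ** 2 / sxx)
        band = np.column_stack([pred - tcrit * se, pred + tcrit * se])
    else:
        band = np.full((q.size, 2), math.nan)
    return AgreementReport(
        diff, avg, mean_diff, float(t_fixed), float(p_fixed),
        slope, intercept, float(res.slope / res.stderr) if res.stderr else math.nan,
        float(res.pvalue), q, pred, band,
    )


# ---------------------------------------------------------------------------
# fast/slow classification and proportions
# ---------------------------------------------------------------------------


def classify_fast_slow(
    latencies: Sequence[float],
    cutoff: float = 75.0,
    groups: Optional[Sequence] = None,
) -> tuple[np.ndarray, Optional[pd.DataFrame]]:
    """Label each latency fast (< cutoff) or slow (>= cutoff).

    Withdrawal latencies to optogenetic pulses are bimodal; the 75 ms
    boundary separates the fast (A-fiber-mediated) from the slow
    (C-fiber-mediated) mode.  A latency exactly at the boundary is classed
    slow.  With ``groups`` (one label per latency, e.g. stimulus
    intensity), also return the group x {fast, slow} contingency table
    suitable for :func:`chi2_proportions`; a table where one class is
    empty is flagged with a warning since the chi-square test would be
    degenerate.
    """
    lat = np.asarray(latencies, dtype=float)
    if np.any(lat <= 0):
        raise ValueError("latencies must be positive")
    labels = np.where(lat < cutoff, "fast", "slow")
    table = None
    if groups is not None:
        if len(groups) != lat.size:
            raise ValueError("groups must match latencies in length")
        table = pd.crosstab(pd.Series(groups, name="group"), pd.Series(labels, name="speed"))
        for cls in ("fast", "slow"):
            if cls not in table.columns:
                table[cls] = 0
        table = table[["fast", "slow"]]
        if (table.sum(axis=0) == 0).any():
            warnings.warn("degenerate table: one speed class is empty", stacklevel=2)
    return labels, table


def chi2_proportions(table) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity, no continuity correction.

    ``table`` is an r x c array of non-negative integer counts;
    df = (r-1)(c-1).  A zero expected count makes the statistic undefined
    and raises.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    expected = st.contingency.expected_freq(counts)
    if np.any(expected == 0):
        raise ValueError("zero expected count; chi-square undefined")
    chi2, p, dof, _ = st.chi2_contingency(counts, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# stimulus-response fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of ``y = a * x**b`` by least squares on log10-log10 axes."""

    a: float
    b: float
    x_range: tuple[float, float]
    r_squared: float
    residual_sd: float  # SD of log10 residuals

    def predict(self, x) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.b


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Fit latency-vs-intensity data with a power law.

    On log-log axes the power law is a straight line; the fit is ordinary
    least squares of ``log10 y`` on ``log10 x`` with ``a = 10**intercept``
    and ``b = slope``.  Requires strictly positive data.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(xa <= 0) or np.any(ya <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    lx, ly = np.log10(xa), np.log10(ya)
    if np.allclose(lx, lx[0]):
        raise ValueError("all x equal; exponent undefined")
    res = st.linregress(lx, ly)
    resid = ly - (res.intercept + res.slope * lx)
    sd = float(np.std(resid, ddof=2)) if xa.size > 2 else math.nan
    return PowerLawFit(
        a=float(10**res.intercept),
        b=float(res.slope),
        x_range=(float(xa.min()), float(xa.max())),
        r_squared=float(res.rvalue**2),
        residual_sd=sd,
    )


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic psychometric function in log10 intensity.

    ``threshold`` is the intensity at 50 % withdrawal probability.
    ``extrapolated`` flags a threshold outside the tested intensity range;
    ``separated`` flags perfectly separated data, where the threshold is
    taken as the geometric midpoint between the bracketing intensities and
    the slope is unidentified.
    """

    intensities: np.ndarray
    response_prob: np.ndarray  # observed per-intensity response rates
    coef_intercept: float
    coef_slope: float  # per log10-intensity unit
    threshold: float
    extrapolated: bool
    separated: bool

    def predict(self, intensity) -> np.ndarray:
        z = self.coef_intercept + self.coef_slope * np.log10(np.asarray(intensity, float))
        return 1.0 / (1.0 + np.exp(-z))


def fit_psychometric(
    intensities: Sequence[float], outcomes: Sequence[int]
) -> PsychometricFit:
    """Fit a logistic sigmoid to per-trial withdrawal outcomes.

    ``intensities`` are the per-trial stimulus intensities (strictly
    positive), ``outcomes`` the binary withdrawal indicators.  The model is
    a maximum-likelihood logistic regression on log10 intensity; the
    threshold is the intensity at fitted p = 0.5.  All-0 or all-1 outcomes
    leave the threshold undefined and raise.
    """
    xi = np.asarray(intensities, dtype=float)
    yi = np.asarray(outcomes, dtype=float)
    if xi.size != yi.size:
        raise ValueError("intensities and outcomes must align")
    if np.any(xi <= 0):
        raise ValueError("intensities must be strictly positive")
    if not set(np.unique(yi)).issubset({0.0, 1.0}):
        raise ValueError("outcomes must be binary")
    levels = np.unique(xi)
    if levels.size < 2:
        raise ValueError("need at least 2 distinct intensities")
    if yi.min() == yi.max():
        raise ValueError("all outcomes identical; threshold undefined")
    lx = np.log10(xi)
    prob = np.array([yi[xi == v].mean() for v in levels])
    # perfect separation: every sub-threshold trial 0, every supra trial 1
    max0 = lx[yi == 0].max()
    min1 = lx[yi == 1].min()
    if max0 < min1:
        mid = 0.5 * (max0 + min1)
        return PsychometricFit(
            levels, prob, math.nan, math.inf, float(10**mid),
            extrapolated=not (levels.min() <= 10**mid <= levels.max()),
            separated=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(yi, sm.add_constant(lx))
        fit = model.fit(disp=0, method="lbfgs", maxiter=200)
    b0, b1 = float(fit.params[0]), float(fit.params[1])
    if b1 == 0:
        raise ValueError("flat psychometric function; threshold undefined")
    thr = float(10 ** (-b0 / b1))
    return PsychometricFit(
        levels, prob, b0, b1, thr,
        extrapolated=not (levels.min() <= thr <= levels.max()),
        separated=False,
    )


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionComparison:
    """Two-group latency-distribution comparison.

    ``ks_d``/``ks_p`` compare the pooled-trial empirical CDFs; the CV
    lists hold one intra-unit (per-animal) coefficient of variation per
    unit, compared by two-sample t test.
    """

    ks_d: float
    ks_p: float
    cvs_a: np.ndarray
    cvs_b: np.ndarray
    t_cv: float
    p_cv: float


def compare_latency_distributions(
    group_a: Mapping[str, Sequence[float]],
    group_b: Mapping[str, Sequence[float]],
) -> DistributionComparison:
    """Compare latency distributions of two groups of animals.

    Each group maps unit (animal) IDs to that animal's trial latencies.
    Pooled trials feed a two-sample Kolmogorov-Smirnov test; per-unit CVs
    (units with fewer than 2 trials are excluded with a warning) feed a
    two-sample t test of intra-animal variability.
    """

    def _collect(group, name):
        pooled, cvs = [], []
        for unit, vals in group.items():
            v = np.asarray(vals, dtype=float)
            if v.size < 2:
                warnings.warn(
                    f"unit {unit!r} in group {name} has <2 trials; excluded from CVs",
                    stacklevel=3,
                )
                pooled.extend(v.tolist())
                continue
            pooled.extend(v.tolist())
            cvs.append(coefficient_of_variation(v))
        return np.asarray(pooled), np.asarray(cvs)

    pooled_a, cvs_a = _collect(group_a, "A")
    pooled_b, cvs_b = _collect(group_b, "B")
    if cvs_a.size < 1 or cvs_b.size < 1:
        raise ValueError("each group needs at least one unit with >=2 trials")
    ks = st.ks_2samp(pooled_a, pooled_b, method="asymp")
    tt = st.ttest_ind(cvs_a, cvs_b)
    return DistributionComparison(
        float(ks.statistic), float(ks.pvalue), cvs_a, cvs_b,
        float(tt.statistic), float(tt.pvalue),
    )


# ---------------------------------------------------------------------------
# behavior-latency association
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorTrial:
    """Withdrawal latency plus post-stimulus behavior scores for one trial.

    Flags mark whether licking / guarding / flinching occurred after the
    withdrawal; durations (s) quantify time spent in each behavior.
    """

    trial_id: str
    latency: float
    lick: bool = False
    guard: bool = False
    flinch: bool = False
    lick_duration: float = 0.0
    guard_duration: float = 0.0
    flinch_duration: float = 0.0

    def __post_init__(self) -> None:
        if min(self.lick_duration, self.guard_duration, self.flinch_duration) < 0:
            raise ValueError("durations must be non-negative")


@dataclass(frozen=True)
class AssociationResult:
    """Regression of a post-stimulus behavior on withdrawal latency."""

    mode: str  # "logistic" or "linear"
    slope: float
    intercept: float
    p_value: float
    ci_lower: float
    ci_upper: float
    n: int
    n_boot: int
    separated: bool = False


def behavior_latency_association(
    trials: Sequence[BehaviorTrial],
    behavior: str,
    mode: str = "logistic",
    n_boot: int = 2000,
    seed: int = 0,
) -> AssociationResult:
    """Is a post-stimulus behavior predicted by withdrawal latency?

    ``mode='logistic'`` regresses the occurrence flag of ``behavior``
    (``lick``/``guard``/``flinch``) on latency; ``mode='linear'``
    regresses the behavior's duration on latency.  The confidence
    interval is a case-resampling bootstrap (percentile, 95 %, seeded).
    Complete separation in the logistic fit is flagged; the CI then rests
    on the bootstrap alone.
    """
    if mode not in ("logistic", "linear"):
        raise ValueError("mode must be 'logistic' or 'linear'")
    if len(trials) < 10:
        raise ValueError("need at least 10 trials")
    lat = np.array([t.latency for t in trials], dtype=float)
    if mode == "logistic":
        y = np.array([float(getattr(t, behavior)) for t in trials])
        if y.min() == y.max():
            raise ValueError("both outcome classes must be present")
    else:
        y = np.array([getattr(t, f"{behavior}_duration") for t in trials], dtype=float)

    def _fit(latv, yv):
        X = sm.add_constant(latv)
        if mode == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yv, X).fit(disp=0, method="lbfgs", maxiter=200)
        else:
            res = sm.OLS(yv, X).fit()
        return res

    res = _fit(lat, y)
    slope = float(res.params[1])
    intercept = float(res.params[0])
    p = float(res.pvalues[1])
    separated = False
    if mode == "logistic":
        # complete separation: a latency threshold splits the classes cleanly
        lo, hi = lat[y == 0], lat[y == 1]
        if lo.size and hi.size and (lo.max() < hi.min() or hi.max() < lo.min()):
            separated = True
            p = math.nan
    rng = np.random.default_rng(seed)
    boots = []
    n = lat.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if mode == "logistic" and yb.min() == yb.max():
            continue  # resample without both classes carries no slope information
        try:
            boots.append(float(_fit(lat[idx], yb).params[1]))
        except Exception:
            continue
    if boots:
        ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5])
    else:
        ci_lo = ci_hi = math.nan
    return AssociationResult(
        mode, slope, intercept, p, float(ci_lo), float(ci_hi), n, len(boots), separated
    )
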