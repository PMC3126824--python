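"""Statistical pipeline for Visual Response data.

Implements the analysis chain used on per-maze VR values: a Lilliefors
normality screen that routes each comparison to a parametric or
non-parametric test, one-sample tests of VR against zero, two-sample
strain comparisons, one-way ANOVA with Tukey HSD compact letter
displays, pairwise Pearson correlation tables, and the ordinary
least-squares meta-analysis fits of VR against peak spectral power.

Lilliefors p-values are obtained by Monte Carlo simulation of the null
distribution of the test statistic (sample size matched, internally
seeded, cached per sample size) rather than from approximation tables,
so results are reproducible and table-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatReport",
    "MetaFit",
    "lilliefors_test",
    "test_vs_zero",
    "compare_groups",
    "anova_letter_groups",
    "correlation_table",
    "meta_fit",
]

logger = logging.getLogger(__name__)

_LILLIEFORS_MC = 50_000          # null replicates per sample size
_LILLIEFORS_SEED = 20_319        # internal seed for the cached null tables
_NORMALITY_GATE_ALPHA = 0.05     # screening level before t vs rank tests


@dataclass(frozen=True)
class StatReport:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    group_labels: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.significant != (self.p_value < self.alpha):
            raise ValueError("significance flag inconsistent with p-value and alpha")


@dataclass(frozen=True)
class MetaFit:
    """An OLS fit of VR against peak spectral power.

    ``coefficients`` are ordered highest degree first. ``correlation_r``
    is the Pearson correlation between fitted and observed responses
    (for the linear model this equals |r| of x and y up to sign).
    """

    model: str
    coefficients: np.ndarray
    correlation_r: float
    p_value: float
    n_points: int
    coef_stderr: np.ndarray = field(default=None)  # type: ignore[assignment]
    coef_ci95: np.ndarray = field(default=None)    # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = {"quadratic": 3, "linear": 2}
        if self.model not in expected:
            raise ValueError("model must be 'quadratic' or 'linear'")
        if len(self.coefficients) != expected[self.model]:
            raise ValueError(f"{self.model} fit needs {expected[self.model]} coefficients")
        if not math.isnan(self.correlation_r) and abs(self.correlation_r) > 1 + 1e-12:
            raise ValueError("|correlation_r| cannot exceed 1")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Normality screening
# ---------------------------------------------------------------------------

def _lilliefors_statistic(values: np.ndarray) -> float:
    """KS distance between the sample ECDF and a normal with fitted moments."""
    n = values.size
    z = np.sort((values - values.mean()) / values.std(ddof=1))
    cdf = sps.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_mc: int = _LILLIEFORS_MC) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the statistic at sample size n."""
    rng = np.random.default_rng(_LILLIEFORS_SEED + n)
    x = rng.standard_normal((n_mc, n))
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((x - mu) / sd, axis=1)
    cdf = sps.norm.cdf(z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
    return np.sort(d)


def lilliefors_test(values: Sequence[float], alpha: float = _NORMALITY_GATE_ALPHA,
                    n_mc: int = _LILLIEFORS_MC) -> StatReport:
    """Lilliefors (KS with estimated mean and s.d.) test of normality.

    The p-value is ``(1 + #{null stats >= observed}) / (n_mc + 1)`` against
    a cached Monte-Carlo null at the same sample size. A constant sample
    is degenerate: normality is rejected by convention (and logged).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("Lilliefors test needs at least 5 observations")
    if np.ptp(values) == 0:
        logger.warning("Lilliefors: constant sample, rejecting normality by convention")
        return StatReport("lilliefors", math.inf, 0.0, alpha, True)
    d = _lilliefors_statistic(values)
    null = _lilliefors_null(values.size, n_mc)
    p = (1 + int(null.size - np.searchsorted(null, d, side="left"))) / (null.size + 1)
    p = min(1.0, p)
    return StatReport("lilliefors", d, p, alpha, p < alpha)


def _looks_normal(values: np.ndarray) -> bool:
    # Small samples cannot be screened; default to the parametric branch.
    if values.size < 5 or np.ptp(values) == 0:
        return True
    return not lilliefors_test(values).significant


# ---------------------------------------------------------------------------
# VR-vs-zero and strain comparisons
# ---------------------------------------------------------------------------

def test_vs_zero(per_maze_vr: Sequence[float], alpha: float = 0.01) -> StatReport:
    """Is the mean per-maze VR different from zero?

    Normal-looking samples (Lilliefors screen at 0.05) get a one-sample
    t-test; others get the Wilcoxon signed-rank test, the one-sample
    analogue of the rank-based two-sample comparison.
    """
    values = np.asarray(per_maze_vr, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 per-maze VR values")
    if np.all(values == 0):
        return StatReport("t_vs_zero", 0.0, 1.0, alpha, False)
    if _looks_normal(values):
        stat, p = sps.ttest_1samp(values, 0.0)
        name = "t_vs_zero"
    else:
        stat, p = sps.wilcoxon(values)
        name = "wilcoxon_vs_zero"
    p = float(p)
    return StatReport(name, float(stat), p, alpha, p < alpha)


test_vs_zero.__test__ = False  # keep pytest from collecting the API name


def compare_groups(a: Sequence[float], b: Sequence[float], alpha: float = 0.01) -> StatReport:
    """Two-sample strain comparison: Welch t-test, or Mann–Whitney U when
    either sample fails the normality screen."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if _looks_normal(a) and _looks_normal(b):
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        name = "welch_t"
        if math.isnan(p):  # both groups constant and equal
            stat, p = 0.0, 1.0
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney_u"
    p = float(p)
    return StatReport(name, float(stat), p, alpha, p < alpha)


# ---------------------------------------------------------------------------
# ANOVA with compact letter display
# ---------------------------------------------------------------------------

def _compact_letters(labels: List[str], means: Dict[str, float],
                     different: set) -> Dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one letter covering every group and splits it for each
    significantly different pair; groups share a letter iff they are not
    significantly different.
    """
    letters: List[set] = [set(labels)]
    for (i, j) in sorted(different):
        for current in [s for s in letters if i in s and j in s]:
            letters.remove(current)
            for split in (current - {i}, current - {j}):
                if split and not any(split <= other for other in letters):
                    letters.append(split)
        letters = [s for s in letters
                   if not any(s < other for other in letters if other is not s)]
    # Order letters by the best (largest-mean) group they contain.
    letters.sort(key=lambda s: (-max(means[g] for g in s), sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {g: "".join(alphabet[k] for k, s in enumerate(letters) if g in s)
            for g in labels}


def anova_letter_groups(groups: Sequence[Tuple[str, Sequence[float]]],
                        alpha: float = 0.01) -> StatReport:
    """One-way ANOVA followed by Tukey HSD all-pairs letter assignment.

    Groups sharing a letter are not significantly different. When the
    omnibus ANOVA is not significant every group shares letter "a".
    """
    groups = [(str(label), np.asarray(v, dtype=float)) for label, v in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(v.size < 2 for _, v in groups):
        raise ValueError("every group needs at least 2 observations")
    labels = [label for label, _ in groups]
    means = {label: float(v.mean()) for label, v in groups}
    fstat, p = sps.f_oneway(*(v for _, v in groups))
    if math.isnan(p):  # all values identical across groups
        fstat, p = 0.0, 1.0
    p = float(p)
    if p >= alpha:
        letters = {g: "a" for g in labels}
        return StatReport("anova_tukey", float(fstat), p, alpha, False, letters)
    data = np.concatenate([v for _, v in groups])
    cat = np.concatenate([[label] * v.size for label, v in groups])
    tukey = pairwise_tukeyhsd(data, cat, alpha=alpha)
    different = set()
    res = tukey.summary().data[1:]
    for row in res:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
        if reject:
            different.add(tuple(sorted((g1, g2))))
    letters = _compact_letters(labels, means, different)
    return StatReport("anova_tukey", float(fstat), p, alpha, True, letters)


# ---------------------------------------------------------------------------
# Correlation tables and meta-analysis fits
# ---------------------------------------------------------------------------

def correlation_table(series: Sequence[Tuple[str, Sequence[float], Sequence[float]]],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson correlations, one row per labelled (x, y) pair.

    Zero-variance inputs yield an undefined r, reported as missing and
    logged. Columns: label, r, p, significant (p < alpha).
    """
    rows = []
    for label, x, y in series:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 3:
            raise ValueError(f"{label!r}: paired vectors of equal length >= 3 required")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("correlation %r undefined: zero variance", label)
            rows.append((label, math.nan, math.nan, False))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((label, float(r), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["label", "r", "p", "significant"])


def meta_fit(x: Sequence[float], y: Sequence[float], model: str = "linear") -> MetaFit:
    """OLS fit of VR (y) against peak spectral power (x).

    ``model`` selects a degree-1 or degree-2 polynomial. The reported
    correlation is the Pearson r between fitted and observed y, which for
    the linear model equals the magnitude of the x–y correlation.
    """
    degree = {"quadratic": 2, "linear": 1}.get(model)
    if degree is None:
        raise ValueError("model must be 'quadratic' or 'linear'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size <= degree + 1:
        raise ValueError("need more points than coefficients")
    design = np.vander(x, degree + 1)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise ValueError("design is rank deficient (all x equal?)")
    res = sm.OLS(y, design).fit()
    fitted = res.fittedvalues
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        logger.warning("meta_fit correlation undefined: constant fitted or observed y")
        r, p = math.nan, math.nan
    else:
        r, p = sps.pearsonr(fitted, y)
    return MetaFit(model=model, coefficients=np.asarray(res.params),
                   correlation_r=float(r), p_value=float(p), n_points=int(x.size),
                   coef_stderr=np.asarray(res.bse),
                   coef_ci95=np.asarray(res.conf_int(alpha=0.05)))
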