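"""Statistics for the GCR assays.

* G-test of marker-retention counts against the wild-type expected
  retention proportion (df = 1, no Williams correction — the convention
  that reproduces the published retention p-values from their counts).
* Two-tailed Mann-Whitney U for comparing per-culture rate distributions
  (exact for small untied samples, normal approximation with tie
  correction otherwise), with the 0.01 significance threshold used for
  assay comparisons.
* Lea-Coulson method-of-the-median fluctuation-rate estimation: solve
  ``r_med / m - ln(m) = 1.24`` for the expected mutations per culture m,
  then rate = m / cells per culture.  An all-below-median-zero experiment
  yields an upper bound (reported with a "<" convention).
* Fold increase relative to a reference rate, rounded to two significant
  figures for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .fluctuation import FluctuationExperiment

SIGNIFICANCE_THRESHOLD = 0.01
LEA_COULSON_CONSTANT = 1.24


@dataclass
class GTestResult:
    g: float
    df: int
    p_value: float


@dataclass
class RateEstimate:
    rate: float
    is_upper_bound: bool
    cultures: int
    m: float  # expected mutations per culture (Lea-Coulson m)

    def formatted(self) -> str:
        prefix = "<" if self.is_upper_bound else ""
        return f"{prefix}{self.rate:.2e}"


def g_test_retention(
    retaining: int, total: int, expected_proportion: float
) -> GTestResult:
    """Two-category G-test of observed retention against an expected rate.

    G = 2 * sum O * ln(O/E) with 0*ln(0) = 0, df = 1, p from the
    chi-square tail; no Williams correction.
    """
    if total < 1:
        raise ValueError("total must be at least 1")
    if not 0 <= retaining <= total:
        raise ValueError("retaining count must be within the total")
    if not 0 < expected_proportion < 1:
        raise ValueError("expected proportion must be strictly between 0 and 1")
    observed = np.array([retaining, total - retaining], dtype=float)
    expected = np.array(
        [total * expected_proportion, total * (1 - expected_proportion)]
    )
    keep = observed > 0
    g = 2.0 * float(np.sum(observed[keep] * np.log(observed[keep] / expected[keep])))
    g = max(g, 0.0)
    p = float(sps.chi2.sf(g, df=1))
    return GTestResult(g=g, df=1, p_value=min(max(p, np.nextafter(0, 1)), 1.0))


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U with midrank ties.

    Exact p by enumeration when min(nA, nB) <= 8 and there are no ties;
    normal approximation with tie correction otherwise.  Returns (U for
    sample A, two-tailed p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample must contain at least 3 values")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _lea_coulson_m(median_count: float) -> float:
    """Solve r_med/m - ln(m) = 1.24 for m (monotone decreasing in m)."""

    def f(log_m: float) -> float:
        m = math.exp(log_m)
        return median_count / m - math.log(m) - LEA_COULSON_CONSTANT

    return math.exp(optimize.brentq(f, -50.0, 50.0, xtol=1e-12))


def estimate_gcr_rate(experiment: FluctuationExperiment) -> RateEstimate:
    """Lea-Coulson method-of-the-median rate estimate.

    When the median mutant count is 0 the rate is an upper bound,
    computed at a nominal median of 0.5 mutants (the "<" convention used
    for rates from cultures without mutants).
    """
    counts = np.asarray(experiment.counts)
    median = float(np.median(counts))
    upper = median == 0.0
    m = _lea_coulson_m(0.5 if upper else median)
    return RateEstimate(
        rate=m / experiment.cells_per_culture,
        is_upper_bound=upper,
        cultures=len(counts),
        m=m,
    )


def fold_increase(rate: float, reference_rate: float) -> float:
    """Rate ratio vs a reference, rounded to 2 significant figures."""
    if rate <= 0 or reference_rate <= 0:
        raise ValueError("rates must be positive")
    ratio = rate / reference_rate
    digits = 1 - math.floor(math.log10(ratio))
    return round(ratio, digits)
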