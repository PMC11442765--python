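"""Assay characterization statistics.

Repeatability (Pearson correlation, Bland-Altman agreement), tumor-vs-normal
rank testing, spike-in calibration regression, limit of blank / limit of
detection (Armbruster-style, one-sided 95th percentile constant 1.645), a
two-sample power approximation with Bonferroni correction, and the qPCR
delta-Ct estimate of the undigested DNA fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

_Z_95_ONE_SIDED = 1.645  # one-sided 95th percentile of the standard normal


# ---------------------------------------------------------------------------
# Repeatability


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


def agreement_limits(bias: float, sd: float) -> tuple[float, float]:
    """95% limits of agreement: bias -/+ 1.96 * SD of the differences."""
    return bias - 1.96 * sd, bias + 1.96 * sd


def bland_altman(run1, run2) -> BlandAltmanResult:
    """Agreement between two runs of the same samples.

    Differences are run1 - run2; bias is their mean, SD the sample
    standard deviation (n - 1).
    """
    a = np.asarray(run1, dtype=float)
    b = np.asarray(run2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("runs must be paired (equal length)")
    if a.size < 2:
        raise ValueError("need at least two paired values")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = agreement_limits(bias, sd)
    return BlandAltmanResult(bias=bias, sd=sd, loa_low=lo, loa_high=hi, n=a.size)


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Rank test


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x vs y with ties counted half."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    rx = ranks[: len(x)].sum()
    return rx - len(x) * (len(x) + 1) / 2.0


def mann_whitney_u(group1, group2) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact permutation p-value (enumeration of all label assignments, which
    handles ties) when the combined sample size is at most 10; otherwise the
    normal approximation with continuity and tie correction.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    if n1 + n2 <= 10:
        pooled = np.concatenate([x, y])
        mu = n1 * n2 / 2.0
        dev = abs(u - mu)
        hits = 0
        total = comb(n1 + n2, n1)
        idx = np.arange(n1 + n2)
        for pick in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        return float(u), hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u), float(res.pvalue)


# ---------------------------------------------------------------------------
# Spike-in calibration


@dataclass(frozen=True)
class SpikeinRegression:
    slope: float
    intercept: float
    r: float
    calculated_pct: np.ndarray

    def invert(self, value) -> np.ndarray:
        """Calculated spike percentage for a measured normalized count."""
        if self.slope == 0:
            raise ValueError("zero slope: calibration cannot be inverted")
        return (np.asarray(value, dtype=float) - self.intercept) / self.slope


def spikein_regression(expected_pct, values) -> SpikeinRegression:
    """Classical calibration: regress response on expected spike percentage.

    The calculated percentage of any sample is (value - intercept) / slope.
    """
    e = np.asarray(expected_pct, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.unique(e).size < 2:
        raise ValueError("need at least two distinct expected fractions")
    fit = stats.linregress(e, v)
    if fit.slope == 0:
        raise ValueError("zero slope: calibration cannot be inverted")
    calc = (v - fit.intercept) / fit.slope
    return SpikeinRegression(
        slope=float(fit.slope), intercept=float(fit.intercept), r=float(fit.rvalue),
        calculated_pct=calc,
    )


# ---------------------------------------------------------------------------
# Limit of blank / limit of detection


@dataclass(frozen=True)
class LodResult:
    lob: float
    lod: float
    slope: float
    intercept: float
    lod_methylation_pct: float


def lob_lod(blank, low_level, calibration: tuple[float, float]) -> LodResult:
    """Armbruster-style detection limits on the normalized-count scale.

    LOB = mean(blank) + 1.645 * SD(blank); LOD = LOB + 1.645 * SD(low-level
    replicates); the methylation percentage at the LOD comes from the
    calibration line (slope, intercept) of the dilution series.
    """
    b = np.asarray(blank, dtype=float)
    l = np.asarray(low_level, dtype=float)
    if b.size < 2 or l.size < 2:
        raise ValueError("need at least two replicates of blank and low-level samples")
    slope, intercept = calibration
    if slope == 0:
        raise ValueError("zero calibration slope")
    lob = float(b.mean() + _Z_95_ONE_SIDED * b.std(ddof=1))
    lod = float(lob + _Z_95_ONE_SIDED * l.std(ddof=1))
    return LodResult(
        lob=lob,
        lod=lod,
        slope=slope,
        intercept=intercept,
        lod_methylation_pct=float((lod - intercept) / slope),
    )


# ---------------------------------------------------------------------------
# Power


@dataclass(frozen=True)
class PowerSpec:
    n1: int
    n2: int
    mu1: float
    sd1: float
    mu2: float
    sd2: float
    n_tests: int = 1
    alpha_family: float = 0.05

    def __post_init__(self) -> None:
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


def power_two_sample(spec: PowerSpec) -> float:
    """Two-sided unequal-variance normal-approximation power.

    Per-test alpha is Bonferroni-corrected (alpha_family / n_tests);
    power = Phi(delta - z_{1-a/2}) + Phi(-delta - z_{1-a/2}) with
    delta = |mu1 - mu2| / sqrt(sd1^2/n1 + sd2^2/n2).
    """
    alpha = spec.alpha_family / spec.n_tests
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    delta = abs(spec.mu1 - spec.mu2) / np.sqrt(
        spec.sd1**2 / spec.n1 + spec.sd2**2 / spec.n2
    )
    return float(stats.norm.sf(z - delta) + stats.norm.sf(z + delta))


# ---------------------------------------------------------------------------
# qPCR digestion efficiency


def undigested_fraction_from_dct(ct_digested: float, ct_undigested: float) -> tuple[float, float]:
    """Fraction of molecules escaping digestion from a qPCR delta-Ct.

    delta-Ct = Ct(digested) - Ct(undigested); the surviving fraction is
    2^(-delta-Ct) and its reciprocal the '1 in N' molecules figure.
    """
    if ct_digested < 0 or ct_undigested < 0:
        raise ValueError("Ct values must be non-negative")
    dct = ct_digested - ct_undigested
    if dct < 0:
        warnings.warn(
            "digested sample amplifies earlier than undigested control (negative delta-Ct)",
            stacklevel=2,
        )
    fraction = 2.0 ** (-dct)
    return fraction, 2.0**dct
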