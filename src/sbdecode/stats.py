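"""Univariate benchmarks and inferential statistics for decoding results.

Covers the grand-mean threshold classifier with directional hypotheses
(oscillatory power below / complexity above the pooled mean in self-boundary
dissolution), Cohen's d effect sizes, exact two-sided binomial tests against
chance, Fisher's method for combining per-participant p-values,
Benjamini-Hochberg FDR applied separately per hypothesis family, and
Spearman correlations with a default Bayes factor for covariates such as
lifetime meditation hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import integrate, special, stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UnivariateResult",
    "StatsReport",
    "CorrelationResult",
    "univariate_threshold_accuracy",
    "boundary_sweep",
    "cohens_d",
    "binomial_vs_chance",
    "fisher_combine",
    "bh_fdr",
    "build_stats_report",
    "ParticipantSummary",
    "participant_summary",
    "covariate_correlation",
]

LOW_IS_POSITIVE = "low_is_positive"
HIGH_IS_POSITIVE = "high_is_positive"


@dataclass
class UnivariateResult:
    """Per-region grand-mean threshold accuracy and Cohen's d."""

    accuracy: pd.Series
    cohens_d: pd.Series
    direction: str


@dataclass
class CorrelationResult:
    spearman_rho: float
    p: float
    bayes_factor: float  # BF10: evidence for a correlation over its absence
    n_after_outlier_removal: int


def univariate_threshold_accuracy(
    positive: NDArray[np.float64],
    other: NDArray[np.float64],
    direction: str = LOW_IS_POSITIVE,
) -> float:
    """Accuracy of the grand-mean threshold classifier.

    The decision boundary is the mean over *all* observations pooled across
    both classes; ``direction`` states the a priori hypothesis, e.g.
    ``low_is_positive`` when the positive class is expected to fall below
    the boundary (as for oscillatory power in dissolution). Values exactly
    on the boundary count as half-correct; zero-variance input therefore
    scores 0.5 by convention.
    """
    positive = np.asarray(positive, dtype=float)
    other = np.asarray(other, dtype=float)
    if positive.size == 0 or other.size == 0:
        raise ValueError("both classes must be non-empty")
    if direction not in (LOW_IS_POSITIVE, HIGH_IS_POSITIVE):
        raise ValueError(f"unknown direction {direction!r}")
    boundary = np.concatenate([positive, other]).mean()
    return _threshold_accuracy(positive, other, boundary, direction)


def _threshold_accuracy(
    positive: NDArray[np.float64],
    other: NDArray[np.float64],
    boundary: float,
    direction: str,
) -> float:
    if direction == LOW_IS_POSITIVE:
        correct = np.sum(positive < boundary) + np.sum(other > boundary)
    else:
        correct = np.sum(positive > boundary) + np.sum(other < boundary)
    ties = np.sum(positive == boundary) + np.sum(other == boundary)
    return float((correct + 0.5 * ties) / (positive.size + other.size))


def boundary_sweep(
    positive: NDArray[np.float64],
    other: NDArray[np.float64],
    direction: str = LOW_IS_POSITIVE,
    grid: NDArray[np.float64] | None = None,
) -> tuple[float, float, float]:
    """Exhaustive accuracy over candidate boundaries.

    Returns ``(best boundary, best accuracy, improvement over the grand-mean
    boundary)``. With a grid containing the grand mean the improvement is
    ≥ 0 by construction.
    """
    positive = np.asarray(positive, dtype=float)
    other = np.asarray(other, dtype=float)
    if grid is None:
        pooled = np.concatenate([positive, other])
        grid = np.quantile(pooled, np.linspace(0.01, 0.99, 99))
        grid = np.append(grid, pooled.mean())
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("boundary grid is empty")
    accs = np.array(
        [_threshold_accuracy(positive, other, b, direction) for b in grid]
    )
    best = int(np.argmax(accs))
    grand = univariate_threshold_accuracy(positive, other, direction)
    return float(grid[best]), float(accs[best]), float(accs[best] - grand)


def cohens_d(x: NDArray[np.float64], y: NDArray[np.float64]) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def binomial_vs_chance(k_correct: int, n: int) -> float:
    """Exact two-sided binomial test of k/n against chance (0.5).

    Two-sidedness by the minimum-likelihood rule: the p-value sums the
    probability of every outcome no more likely than the observed one.
    """
    if not 0 <= k_correct <= n or n < 1:
        raise ValueError("need 0 ≤ k ≤ n and n ≥ 1")
    return float(sstats.binomtest(k_correct, n, 0.5, alternative="two-sided").pvalue)


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's method: chi2 = −2·Σ ln p on 2k degrees of freedom.

    Zero p-values are clipped to the smallest positive float with a warning
    (−ln 0 is infinite).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        import warnings

        warnings.warn("clipping p = 0 to the smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    chi2 = float(-2.0 * np.sum(np.log(p)))
    return chi2, float(sstats.chi2.sf(chi2, df=2 * p.size))


def bh_fdr(p_values, family_labels) -> NDArray[np.float64]:
    """Benjamini-Hochberg step-up adjustment, run independently per family.

    The univariate and multivariate tests form distinct hypothesis families;
    adding tests to one family never changes the other's adjusted values.
    """
    p = np.asarray(list(p_values), dtype=float)
    fam = np.asarray(list(family_labels))
    if p.shape != fam.shape:
        raise ValueError("p_values and family_labels must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.empty_like(p)
    for label in np.unique(fam):
        sel = fam == label
        adjusted[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return adjusted


@dataclass
class StatsReport:
    """All tests with raw and family-wise FDR-adjusted p-values."""

    tests: pd.DataFrame  # test_id, family, p_raw, p_adjusted, significant
    alpha: float = 0.05


def build_stats_report(tests: pd.DataFrame, alpha: float = 0.05) -> StatsReport:
    """Adjust a (test_id, family, p_raw) table within each family."""
    allowed = {"univariate", "multivariate"}
    bad = set(tests["family"]) - allowed
    if bad:
        raise ValueError(f"unknown family labels: {sorted(bad)}")
    out = tests.copy()
    out["p_adjusted"] = bh_fdr(out["p_raw"], out["family"])
    out["significant"] = out["p_adjusted"] < alpha
    return StatsReport(tests=out, alpha=alpha)


@dataclass
class ParticipantSummary:
    """Across-participant aggregation of per-participant decoding tests."""

    per_participant_p: pd.Series
    fisher_chi2: float
    fisher_p: float
    mean_accuracy: float
    ci95: tuple[float, float]


def participant_summary(results) -> ParticipantSummary:
    """Binomial test per participant, Fisher combination, mean ± 95% CI.

    ``results`` maps participant id → a DecodeResult or ``(k_correct,
    n_eval)`` pair. The confidence interval is a t-interval on the
    participant-mean accuracies.
    """
    if len(results) < 2:
        raise ValueError("need results from at least 2 participants")
    ps, accs = {}, []
    for pid, res in dict(results).items():
        k, n = (res.k_correct, res.n_eval) if hasattr(res, "k_correct") else res
        ps[pid] = binomial_vs_chance(int(k), int(n))
        accs.append(k / n)
    chi2, fisher_p = fisher_combine(list(ps.values()))
    accs = np.asarray(accs)
    mean = float(accs.mean())
    sem = float(accs.std(ddof=1) / np.sqrt(accs.size))
    half = float(sstats.t.ppf(0.975, df=accs.size - 1)) * sem
    return ParticipantSummary(
        per_participant_p=pd.Series(ps, name="p"),
        fisher_chi2=chi2,
        fisher_p=fisher_p,
        mean_accuracy=mean,
        ci95=(mean - half, mean + half),
    )


# -- correlation with covariates ----------------------------------------


def _log_density_r(r: float, rho: NDArray[np.float64], n: int) -> NDArray[np.float64]:
    """Log sampling density of the Pearson correlation r given ρ and n
    (Hotelling's exact form with a Gaussian hypergeometric term)."""
    rho = np.asarray(rho, dtype=float)
    log_c = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        + ((n - 4) / 2.0) * np.log1p(-(r**2))
    )
    return (
        log_c
        + ((n - 1) / 2.0) * np.log1p(-(rho**2))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))
    )


def correlation_bf10(r: float, n: int, prior_width: float = 1.0) -> float:
    """Default Bayes factor for a correlation (stretched-beta prior).

    BF10 integrates the exact sampling density of r over a stretched
    beta(1/width, 1/width) prior on ρ (width 1 = uniform on (−1, 1)) and
    divides by the density under ρ = 0. Values < 1 favour the absence of a
    correlation.
    """
    if n < 4:
        raise ValueError("Bayes factor needs n ≥ 4")
    a = 1.0 / prior_width

    def integrand(rho: float) -> float:
        prior = sstats.beta.pdf((rho + 1.0) / 2.0, a, a) / 2.0
        return float(np.exp(_log_density_r(r, np.array(rho), n))) * prior

    marginal, _ = integrate.quad(integrand, -1.0, 1.0, limit=200)
    null = float(np.exp(_log_density_r(r, np.array(0.0), n)))
    return marginal / null


def covariate_correlation(
    metric: NDArray[np.float64],
    covariate: NDArray[np.float64],
    prior_width: float = 1.0,
    iqr_multiplier: float = 1.5,
) -> CorrelationResult:
    """Spearman correlation with IQR outlier removal and a default BF.

    Pairs falling outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] on *either* variable
    are removed first. The Bayes factor applies the default correlation BF
    to the rank-transformed data, matching the Spearman test statistic.
    """
    metric = np.asarray(metric, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if metric.shape != covariate.shape:
        raise ValueError("metric and covariate must be paired")

    def inliers(x: NDArray[np.float64]) -> NDArray[np.bool_]:
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        return (x >= q1 - iqr_multiplier * iqr) & (x <= q3 + iqr_multiplier * iqr)

    keep = inliers(metric) & inliers(covariate)
    m, c = metric[keep], covariate[keep]
    if m.size < 5:
        raise ValueError("fewer than 5 participants after outlier removal")
    if np.unique(m).size < 2 or np.unique(c).size < 2:
        raise ValueError("correlation undefined for a constant variable")
    rho, p = sstats.spearmanr(m, c)
    r_rank = float(np.corrcoef(sstats.rankdata(m), sstats.rankdata(c))[0, 1])
    # BF integrand is singular at |r| = 1; nudge inside the open interval
    r_rank = float(np.clip(r_rank, -1 + 1e-10, 1 - 1e-10))
    bf = correlation_bf10(r_rank, m.size, prior_width=prior_width)
    return CorrelationResult(
        spearman_rho=float(rho),
        p=float(p),
        bayes_factor=bf,
        n_after_outlier_removal=int(m.size),
    )
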