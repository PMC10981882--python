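"""Cohort-level statistics: medians/IQRs, within-range proportions,
normality gating and one-sample tests against the 5.00 mm effective range.

Quantiles default to the weighted-average rule at plotting position
p*(n+1) (numpy's ``"weibull"`` method, the default of the stats package the
summaries are meant to be comparable with); alternatives are selectable.

The one-sample Wilcoxon signed-rank test drops zero differences, uses
mid-ranks for ties, enumerates the exact two-sided p when n <= 15 with no
ties, and otherwise applies the normal approximation with tie and continuity
corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import AccuracyResult

__all__ = [
    "MetricSample",
    "MetricSummary",
    "CohortSummary",
    "DegenerateSampleError",
    "summarize",
    "quartiles",
    "shapiro_wilk",
    "one_sample_wilcoxon",
    "one_sample_t",
    "choose_test",
    "scatter_coordinates",
    "cohort_table",
]

METRIC_NAMES = ("euclidean", "lateral", "depth")


class DegenerateSampleError(ValueError):
    """Sample cannot support the requested statistic."""


@dataclass(frozen=True)
class MetricSample:
    """Named vector of per-trial distances (mm)."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if len(v) < 1:
            raise ValueError("sample must contain at least one value")
        if not np.all(np.isfinite(v)):
            raise ValueError("sample contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class MetricSummary:
    metric: str
    n: int
    median_mm: float
    q1_mm: float
    q3_mm: float
    iqr_mm: float
    pct_within: float  # exact fraction * 100
    pct_within_int: int  # rounded as printed
    shapiro_w: float
    shapiro_p: float
    test_used: str  # "one-sample t" | "one-sample Wilcoxon signed-rank"
    test_statistic: float
    test_p: float


@dataclass
class CohortSummary:
    metrics: dict[str, MetricSummary]
    n_trials: int
    threshold_mm: float = 5.0
    n_subjects: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m in self.metrics.values():
            rows.append(
                {
                    "metric": m.metric,
                    "n": m.n,
                    "median_mm": m.median_mm,
                    "iqr_mm": m.iqr_mm,
                    "q1_mm": m.q1_mm,
                    "q3_mm": m.q3_mm,
                    "pct_within_5mm": m.pct_within_int,
                    "pct_within_exact": m.pct_within,
                    "shapiro_w": m.shapiro_w,
                    "shapiro_p": m.shapiro_p,
                    "test_used": m.test_used,
                    "test_statistic": m.test_statistic,
                    "test_p": m.test_p,
                }
            )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = [
            "| Metric | Median (mm) | IQR (Q1 - Q3) (mm) | % <{:.2f} mm | p |".format(self.threshold_mm),
            "|---|---|---|---|---|",
        ]
        for m in self.metrics.values():
            lines.append(
                f"| {m.metric} | {m.median_mm:.2f} | {m.iqr_mm:.2f} "
                f"({m.q1_mm:.2f} - {m.q3_mm:.2f}) | {m.pct_within_int} | {m.test_p:.3g} |"
            )
        return "\n".join(lines)


def quartiles(values: np.ndarray, method: str = "weibull") -> tuple[float, float, float]:
    """(q1, median, q3) under the chosen empirical quantile convention."""
    q1, med, q3 = np.quantile(np.asarray(values, float), [0.25, 0.5, 0.75], method=method)
    return float(q1), float(med), float(q3)


def summarize(
    sample: MetricSample, threshold_mm: float = 5.0, quantile_method: str = "weibull"
) -> dict:
    """Median, quartiles, IQR and the strict-< within-threshold percentage."""
    q1, med, q3 = quartiles(sample.values, quantile_method)
    frac = float(np.count_nonzero(sample.values < threshold_mm)) / sample.n
    return {
        "median_mm": med,
        "q1_mm": q1,
        "q3_mm": q3,
        "iqr_mm": q3 - q1,
        "pct_within": 100.0 * frac,
        # round half up: 33/40 = 82.5% prints as 83
        "pct_within_int": int(np.floor(100.0 * frac + 0.5)),
    }


def shapiro_wilk(sample: MetricSample) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation, via scipy)."""
    v = sample.values
    if sample.n < 3 or sample.n > 5000:
        raise DegenerateSampleError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise DegenerateSampleError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(v)
    return float(w), float(min(max(p, np.nextafter(0, 1)), 1.0))


def _exact_wilcoxon_sf_cdf(ranks: np.ndarray, w_plus: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) by dynamic-programming enumeration over all
    2^n sign assignments (integer ranks, no ties)."""
    ranks = ranks.astype(np.int64)
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus))
    cdf = float(counts[: w + 1].sum())
    sf = float(counts[w:].sum())
    return cdf, sf


def one_sample_wilcoxon(
    sample: MetricSample | np.ndarray, mu_mm: float = 5.0
) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of median == ``mu_mm``.

    Returns ``(W_plus, two_sided_p)``. Zero differences are dropped; exact
    enumeration is used for n <= 15 without ties, otherwise the normal
    approximation with tie and continuity corrections.
    """
    v = sample.values if isinstance(sample, MetricSample) else np.asarray(sample, float)
    d = v - mu_mm
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all differences are zero; Wilcoxon p = 1 by convention", stacklevel=2)
        return 0.0, 1.0
    absd = np.abs(d)
    ranks = sps.rankdata(absd)  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n
    if n <= 15 and not has_ties:
        cdf, sf = _exact_wilcoxon_sf_cdf(ranks, w_plus)
        p = min(1.0, 2.0 * min(cdf, sf))
        return w_plus, p
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts).sum())) / 48.0
    if var <= 0:
        warnings.warn("zero variance after tie correction; Wilcoxon p = 1", stacklevel=2)
        return w_plus, 1.0
    diff = w_plus - mean
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return w_plus, p


def one_sample_t(sample: MetricSample | np.ndarray, mu_mm: float = 5.0) -> tuple[float, int, float]:
    """One-sample t-test of mean == ``mu_mm``: returns ``(t, df, two_sided_p)``."""
    v = sample.values if isinstance(sample, MetricSample) else np.asarray(sample, float)
    n = len(v)
    if n < 2:
        raise DegenerateSampleError("t-test requires n >= 2")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise DegenerateSampleError("t-test undefined for zero-variance sample")
    t = (float(np.mean(v)) - mu_mm) / (sd / np.sqrt(n))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


def choose_test(shapiro_p: float, alpha: float = 0.05) -> str:
    """Normality gate: Wilcoxon when Shapiro-Wilk rejects at ``alpha``."""
    if not (0 < shapiro_p <= 1):
        raise ValueError("shapiro_p must lie in (0, 1]")
    return "one-sample Wilcoxon signed-rank" if shapiro_p < alpha else "one-sample t"


def scatter_coordinates(results: Sequence[AccuracyResult]) -> np.ndarray:
    """(n, 2) array of (lateral_signed_mm, depth_signed_mm), one row per trial."""
    if len(results) == 0:
        raise ValueError("results must be nonempty")
    return np.array([[r.lateral_signed_mm, r.depth_signed_mm] for r in results])


def _summarize_one(
    name: str,
    values: np.ndarray,
    threshold_mm: float,
    alpha: float,
    quantile_method: str,
) -> MetricSummary:
    sample = MetricSample(name, values)
    summ = summarize(sample, threshold_mm, quantile_method)
    try:
        w, sh_p = shapiro_wilk(sample)
        test = choose_test(sh_p, alpha)
    except DegenerateSampleError as exc:
        warnings.warn(
            f"{name}: normality not testable ({exc}); falling back to Wilcoxon",
            stacklevel=2,
        )
        w, sh_p = float("nan"), float("nan")
        test = "one-sample Wilcoxon signed-rank"
    if test == "one-sample t":
        stat, _, p = one_sample_t(sample, threshold_mm)
    else:
        stat, p = one_sample_wilcoxon(sample, threshold_mm)
    return MetricSummary(
        metric=name,
        n=sample.n,
        median_mm=summ["median_mm"],
        q1_mm=summ["q1_mm"],
        q3_mm=summ["q3_mm"],
        iqr_mm=summ["iqr_mm"],
        pct_within=summ["pct_within"],
        pct_within_int=summ["pct_within_int"],
        shapiro_w=w,
        shapiro_p=sh_p,
        test_used=test,
        test_statistic=float(stat),
        test_p=float(p),
    )


def cohort_table(
    results: Sequence[AccuracyResult],
    threshold_mm: float = 5.0,
    alpha: float = 0.05,
    quantile_method: str = "weibull",
    n_subjects: int | None = None,
) -> CohortSummary:
    """Per-metric summary (unsigned distances) with the normality-gated
    one-sample test against ``threshold_mm``."""
    if len(results) == 0:
        raise ValueError("results must be nonempty")
    columns = {
        "euclidean": np.array([r.euclidean_mm for r in results]),
        "lateral": np.array([r.lateral_mm for r in results]),
        "depth": np.array([r.depth_mm for r in results]),
    }
    metrics = {
        name: _summarize_one(name, vals, threshold_mm, alpha, quantile_method)
        for name, vals in columns.items()
    }
    return CohortSummary(
        metrics=metrics,
        n_trials=len(results),
        threshold_mm=threshold_mm,
        n_subjects=n_subjects,
    )
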