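"""Group comparison and correlation layer.

Two-sample comparisons use Student's pooled-variance t (df = n_a + n_b - 2),
with Welch's t emitted alongside as an auxiliary column; correlations are
sample Pearson r with the usual t-transform p-value. No multiple-comparison
correction is applied to the primary p-values; a Holm-adjusted column is
added as a clearly-labeled extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GROUP_SMOKER",
    "GROUP_NONSMOKER",
    "SubjectRecord",
    "ComparisonRow",
    "CorrelationRow",
    "two_sample_t",
    "welch_t",
    "pooled_t_from_summary",
    "pearson",
    "comparison_table",
    "correlation_table",
    "comparison_frame",
    "correlation_frame",
]

GROUP_SMOKER = "smoker"
GROUP_NONSMOKER = "nonsmoker"


@dataclass
class SubjectRecord:
    """Per-subject group label, behavioral covariates and metric grid.

    ``metrics`` maps (band_name, metric_name) to a value; ``covariates``
    holds optional numeric entries such as ftnd, cigarettes_per_day,
    pack_years and onset_age (missing values may be absent or NaN).
    """

    subject_id: str
    group: str
    covariates: dict[str, float] = field(default_factory=dict)
    metrics: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in (GROUP_SMOKER, GROUP_NONSMOKER):
            raise ValueError(
                f"group must be {GROUP_SMOKER!r} or {GROUP_NONSMOKER!r}, "
                f"got {self.group!r}"
            )


@dataclass
class ComparisonRow:
    band: str
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    t_welch: float
    p_welch: float
    p_holm: float
    significant: bool


@dataclass
class CorrelationRow:
    metric: str
    covariate: str
    r: float
    p: float
    n: int
    significant: bool


def _check_group(values: np.ndarray, name: str) -> None:
    if values.size < 2:
        raise ValueError(f"group {name} needs >= 2 values, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"group {name} contains non-finite values")


def two_sample_t(values_a, values_b) -> tuple[float, float]:
    """Student's pooled-variance two-sided t-test.

    Returns (t, p) with t = (mean_a - mean_b) / SE and
    df = n_a + n_b - 2. Raises when either group has fewer than two
    values or when the pooled variance is zero (t undefined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    _check_group(a, "a")
    _check_group(b, "b")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def welch_t(values_a, values_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (auxiliary to the pooled test)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    _check_group(a, "a")
    _check_group(b, "b")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pooled_t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, float]:
    """Closed-form pooled t from group summary statistics.

    Useful for recomputing a reported t-value from a table of means and
    standard deviations.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance: t undefined")
    se = math.sqrt(pooled_var * (1 / n_a + 1 / n_b))
    t = (mean_a - mean_b) / se
    p = 2 * sps.t.sf(abs(t), df)
    return t, float(p)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _group_values(
    subjects: list[SubjectRecord], group: str, band: str, metric: str
) -> np.ndarray:
    return np.array(
        [s.metrics[(band, metric)] for s in subjects if s.group == group],
        dtype=float,
    )


def comparison_table(
    subjects: list[SubjectRecord],
    bands: list[str],
    metrics: list[str],
    alpha: float = 0.05,
) -> list[ComparisonRow]:
    """One pooled-t row per (band, metric), smoker minus nonsmoker.

    Group summaries use the n-1 denominator SD. The primary p-values are
    uncorrected; ``p_holm`` is a Holm step-down adjustment across all rows.
    """
    groups = {s.group for s in subjects}
    for g in (GROUP_SMOKER, GROUP_NONSMOKER):
        if g not in groups:
            raise ValueError(f"group {g!r} absent from subjects")
    rows: list[ComparisonRow] = []
    for band in bands:
        for metric in metrics:
            a = _group_values(subjects, GROUP_SMOKER, band, metric)
            b = _group_values(subjects, GROUP_NONSMOKER, band, metric)
            try:
                t, p = two_sample_t(a, b)
                tw, pw = welch_t(a, b)
            except ValueError:
                # zero pooled variance: t undefined, signaled as NaN
                t = p = tw = pw = float("nan")
            rows.append(
                ComparisonRow(
                    band=band,
                    metric=metric,
                    mean_a=float(a.mean()),
                    sd_a=float(a.std(ddof=1)),
                    mean_b=float(b.mean()),
                    sd_b=float(b.std(ddof=1)),
                    t=t,
                    p=p,
                    t_welch=tw,
                    p_welch=pw,
                    p_holm=np.nan,
                    significant=bool(p < alpha),
                )
            )
    pvals = np.array([r.p for r in rows], dtype=float)
    finite = np.isfinite(pvals)
    holm = np.full(len(rows), np.nan)
    if finite.any():
        holm[finite] = multipletests(pvals[finite], method="holm")[1]
    for row, ph in zip(rows, holm):
        row.p_holm = float(ph)
    return rows


def correlation_table(
    smokers: list[SubjectRecord],
    band: str,
    metrics: list[str],
    covariates: list[str],
    alpha: float = 0.05,
) -> list[CorrelationRow]:
    """Pearson r for every (metric, covariate) pair within one group.

    Subjects with a missing (absent or NaN) covariate are dropped pairwise;
    the per-row n records how many remained. Raises when a covariate is
    missing for everyone.
    """
    rows: list[CorrelationRow] = []
    for covariate in covariates:
        available = [
            s
            for s in smokers
            if covariate in s.covariates
            and np.isfinite(s.covariates[covariate])
        ]
        if not available:
            raise ValueError(f"covariate {covariate!r} missing for all subjects")
        for metric in metrics:
            x = np.array(
                [s.metrics[(band, metric)] for s in available], dtype=float
            )
            y = np.array(
                [s.covariates[covariate] for s in available], dtype=float
            )
            r, p = pearson(x, y)
            rows.append(
                CorrelationRow(
                    metric=metric,
                    covariate=covariate,
                    r=r,
                    p=p,
                    n=len(available),
                    significant=bool(p < alpha),
                )
            )
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a tidy DataFrame in table column order."""
    return pd.DataFrame(
        [
            {
                "band": r.band,
                "metric": r.metric,
                "mean_smoker": r.mean_a,
                "sd_smoker": r.sd_a,
                "mean_nonsmoker": r.mean_b,
                "sd_nonsmoker": r.sd_b,
                "t": r.t,
                "p": r.p,
                "t_welch": r.t_welch,
                "p_welch": r.p_welch,
                "p_holm": r.p_holm,
                "significant": r.significant,
            }
            for r in rows
        ]
    )


def correlation_frame(rows: list[CorrelationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "covariate": r.covariate,
                "r": r.r,
                "p": r.p,
                "n": r.n,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
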