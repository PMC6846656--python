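"""Replicate-rate statistics for per-experiment aggregate mutation rates.

Each experiment contributes a numerator (C->T supermutant count) and a
denominator (total sequenced C templates); the per-experiment rate is
their ratio.  Replicate groups are summarised as mean +/- population SD
(divide-by-n), compared with the classical pooled-variance two-tailed
Student's t-test (sample variances, divide-by-(n-1)), and expressed as
fold changes of group means.

Note the deliberately mixed SD conventions: the displayed "+/- SD" uses
the population form while the t-test uses sample variances.  This is
statistically unconventional but is the pair of conventions that jointly
reproduces the published summary values, so both are fixed here and
exercised by the test suite.  Means are always taken over full-precision
count-derived rates; rounding happens only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RATE_SCALE = 1e5  # rates are displayed as x 10^-5


@dataclass
class ReplicateSummary:
    label: str
    rates: np.ndarray  # full-precision per-experiment rates
    n: int
    mean: float
    sd: float  # population SD (ddof=0)

    @property
    def display(self) -> str:
        """Mean +/- SD on the x1e-5 scale, one decimal."""
        return f"{self.mean * RATE_SCALE:.1f} ± {self.sd * RATE_SCALE:.1f}"


def experiment_rates(records: pd.DataFrame) -> np.ndarray:
    """Per-experiment rates from numerator/denominator columns."""
    num = records["numerator"].to_numpy(dtype=float)
    den = records["denominator"].to_numpy(dtype=float)
    if np.any(num > den) or np.any(den <= 0):
        raise ValueError("invalid counts: need 0 <= numerator <= denominator, denominator > 0")
    return num / den


def replicate_summary(records: pd.DataFrame, label: str | None = None) -> ReplicateSummary:
    """Mean and population SD of count-derived rates for one group.

    ``records`` needs ``numerator`` and ``denominator`` columns (one row
    per independent experiment).  SD uses the divide-by-n convention, so
    a single replicate has SD 0.
    """
    if len(records) < 1:
        raise ValueError("need at least one record")
    rates = experiment_rates(records)
    if label is None:
        label = str(records["group"].iloc[0]) if "group" in records else ""
    return ReplicateSummary(label=label, rates=rates, n=len(rates),
                            mean=float(rates.mean()), sd=float(rates.std(ddof=0)))


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def two_sample_t(a, b, welch: bool = False) -> TTestResult:
    """Two-tailed two-sample Student's t-test on rate vectors.

    Default is the classical pooled equal-variance form with
    df = nA + nB - 2.  ``welch=True`` switches to Welch's unequal-
    variance test.  A zero pooled variance is degenerate: p is 1 when
    the means agree, else 0 (difference certain under the model).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if max(len(a), len(b)) < 2:
        raise ValueError("need at least 2 observations in one group")
    if not welch:
        pooled = ((len(a) - 1) * a.var(ddof=1) if len(a) > 1 else 0.0) + \
                 ((len(b) - 1) * b.var(ddof=1) if len(b) > 1 else 0.0)
        if pooled == 0.0:
            same = np.isclose(a.mean(), b.mean())
            return TTestResult(t=0.0 if same else np.inf, df=len(a) + len(b) - 2,
                               p=1.0 if same else 0.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = len(a) + len(b) - 2 if not welch else int(res.df)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def fold_change(summary_a: ReplicateSummary, summary_b: ReplicateSummary) -> float:
    """Ratio of group means (A over B); display-round to one decimal."""
    if summary_b.mean <= 0:
        raise ValueError("reference group mean must be positive")
    return summary_a.mean / summary_b.mean


def summarize_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Group-wise summary table from an experiment manifest.

    Manifest columns: group, strand, replicate, denominator, numerator.
    Output mirrors the published per-experiment layout: one row per
    experiment with its rate, plus the group mean +/- SD.
    """
    rows = []
    for (group, strand), sub in manifest.groupby(["group", "strand"], sort=False):
        summ = replicate_summary(sub, label=group)
        for i, (_, rec) in enumerate(sub.iterrows()):
            rate = rec["numerator"] / rec["denominator"]
            rows.append({
                "group": group, "strand": strand, "replicate": rec["replicate"],
                "denominator": int(rec["denominator"]), "numerator": int(rec["numerator"]),
                "rate_1e5": round(rate * RATE_SCALE, 1),
                "mean_1e5": round(summ.mean * RATE_SCALE, 1) if i == len(sub) - 1 else np.nan,
                "sd_1e5": round(summ.sd * RATE_SCALE, 1) if i == len(sub) - 1 else np.nan,
            })
    return pd.DataFrame(rows)
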