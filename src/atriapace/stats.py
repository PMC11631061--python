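"""Paired cohort statistics.

Normality of the paired differences is gated with Shapiro-Wilk at
alpha = 0.05: normal differences get a paired Student t-test, otherwise a
Wilcoxon signed-rank test.  Two-sided p-values throughout; effect reported
as mean +/- SD of the differences with a t-based 95% CI, and medians [IQR]
of both margins.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .exceptions import DataError, InsufficientDataError

__all__ = ["CohortStats", "cohort_stats"]


@dataclass(frozen=True)
class CohortStats:
    n: int
    shapiro_p: float
    test_name: str            # "paired t" | "wilcoxon"
    p_value: float
    mean_diff: float
    sd_diff: float
    ci95: tuple
    median_baseline: float
    iqr_baseline: tuple
    median_condition: float
    iqr_condition: tuple

    def summary(self) -> str:
        lo, hi = self.ci95
        return "\n".join([
            "Paired cohort comparison",
            "------------------------",
            f"n                  {self.n}",
            f"Shapiro-Wilk p     {self.shapiro_p:.4f} -> {self.test_name}",
            f"difference         {self.mean_diff:+.2f} +/- "
            f"{self.sd_diff:.2f} (95% CI {lo:+.2f} to {hi:+.2f})",
            f"two-sided p        {self.p_value:.4g}",
            f"baseline           {self.median_baseline:.2f} "
            f"[{self.iqr_baseline[0]:.2f}-{self.iqr_baseline[1]:.2f}]",
            f"condition          {self.median_condition:.2f} "
            f"[{self.iqr_condition[0]:.2f}-{self.iqr_condition[1]:.2f}]",
        ])


def cohort_stats(baseline, condition, alpha: float = 0.05) -> CohortStats:
    """Paired comparison of ``condition`` against ``baseline``.

    Differences are ``condition - baseline``.  Requires equal lengths of at
    least 3 with no missing values.
    """
    b = np.asarray(baseline, dtype=float)
    c = np.asarray(condition, dtype=float)
    if b.shape != c.shape or b.ndim != 1:
        raise DataError("baseline and condition must be equal-length "
                        "1-D vectors")
    if len(b) < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.any(~np.isfinite(b)) or np.any(~np.isfinite(c)):
        raise DataError("missing or non-finite values are not allowed")
    d = c - b
    if np.allclose(d, d[0]):
        # constant differences: Shapiro is undefined, t-test degenerate
        shapiro_p = 1.0
    else:
        shapiro_p = float(sst.shapiro(d).pvalue)
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if shapiro_p >= alpha:
        name = "paired t"
        if sd == 0:
            p = 1.0 if mean == 0 else 0.0
        else:
            p = float(sst.ttest_rel(c, b).pvalue)
    else:
        name = "wilcoxon"
        if np.all(d == 0):
            p = 1.0
        else:
            p = float(sst.wilcoxon(c, b, zero_method="wilcox").pvalue)
    se = sd / np.sqrt(n)
    tcrit = sst.t.ppf(0.975, n - 1)
    ci = (mean - tcrit * se, mean + tcrit * se)
    q = lambda v: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
    return CohortStats(n=n, shapiro_p=shapiro_p, test_name=name,
                       p_value=p, mean_diff=mean, sd_diff=sd, ci95=ci,
                       median_baseline=float(np.median(b)),
                       iqr_baseline=q(b),
                       median_condition=float(np.median(c)),
                       iqr_condition=q(c))
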