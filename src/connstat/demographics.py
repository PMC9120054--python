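"""Cohort demographics: summary-statistic t-tests, 2x2 chi-square, frequencies."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from connstat.io import Cohort


@dataclass(frozen=True)
class SummaryStat:
    """Mean +/- SD summary over n observations."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    @classmethod
    def from_data(cls, x) -> "SummaryStat":
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


def t_from_summary(a: SummaryStat, b: SummaryStat) -> tuple[float, int]:
    """Pooled-variance two-sample t from summary statistics.

    sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2);
    t = (m1-m2) / (sp * sqrt(1/n1 + 1/n2));  df = n1+n2-2.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    diff = a.mean - b.mean
    if sp2 == 0:
        if diff == 0:
            return 0.0, df
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    return float(t), df


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    O = np.asarray(counts, dtype=float)
    if O.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if (O < 0).any():
        raise ValueError("counts must be nonnegative")
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    total = O.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal")
    E = row @ col / total
    chi2 = float(((O - E) ** 2 / E).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def frequency_percent(k: int, n: int) -> float:
    """Display percentage 100*k/n rounded to 2 decimals."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    return round(100.0 * k / n, 2)


def _fmt_mean_sd(s: SummaryStat) -> str:
    return f"{s.mean:.2f} ± {s.sd:.2f} ({s.n})"


def table_one(cohort: Cohort) -> pd.DataFrame:
    """Group-wise demographic/clinical summary table with test statistics.

    Continuous rows use the pooled two-sample t (per-variable listwise n);
    the sex row uses the 2x2 chi-square.
    """
    mdd = [s for s in cohort.subjects if s.group == "MDD"]
    hc = [s for s in cohort.subjects if s.group == "HC"]
    if not mdd or not hc:
        raise ValueError("both groups required")
    rows = []

    def cont_row(label, getter):
        a = np.array([np.nan if getter(s) is None else getter(s) for s in mdd], dtype=float)
        b = np.array([np.nan if getter(s) is None else getter(s) for s in hc], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            return
        sa, sb = SummaryStat.from_data(a), SummaryStat.from_data(b)
        t, df = t_from_summary(sa, sb)
        p = 2.0 * stats.t.sf(abs(t), df)
        rows.append(
            {"variable": label, "mdd": _fmt_mean_sd(sa), "hc": _fmt_mean_sd(sb),
             "statistic": f"{t:.3f} ({df})", "p": p}
        )

    k_mdd = sum(1 for s in mdd if s.sex == "male")
    k_hc = sum(1 for s in hc if s.sex == "male")
    chi2, p = chi_square_2x2(
        [[k_mdd, len(mdd) - k_mdd], [k_hc, len(hc) - k_hc]]
    )
    rows.append(
        {
            "variable": "male (frequency, %)",
            "mdd": f"{k_mdd}, {frequency_percent(k_mdd, len(mdd)):.2f}%",
            "hc": f"{k_hc}, {frequency_percent(k_hc, len(hc)):.2f}%",
            "statistic": f"{chi2:.2f}",
            "p": p,
        }
    )
    cont_row("age, years", lambda s: s.age)
    cont_row("MADRS", lambda s: s.madrs)
    cont_row("QIDS-SR", lambda s: s.qids)
    cont_row("episode duration, months", lambda s: s.episode_duration)
    return pd.DataFrame(rows)
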