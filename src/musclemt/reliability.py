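"""Agreement and reliability statistics for thickness measurements.

Implements the measurement-reliability toolkit used to evaluate automatic
thickness readings against repeated or manual ones:

* ICC(A,1) — single-measure, absolute-agreement intraclass correlation from
  a two-way model, with the standard F-based confidence interval,
* SEM = s_x * sqrt(1 - ICC)   (standard error of measurement),
* MDC = SEM * 1.96 * sqrt(2)  (minimal detectable change at 95% confidence),
* Bland-Altman bias and limits of agreement,
* squared Pearson correlation (inter-class),
* a per-subject summary table (mean +/- SD, ICC with CI, SEM, MDC, MDC as a
  percentage of the mean).

When reproducing published summary tables the MDC is computed from the SEM
rounded to two decimals (``round_sem=True``), matching how such tables are
typically printed; full precision is the default in normal operation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InputError

__all__ = [
    "icc_a1",
    "sem",
    "mdc",
    "sem_mdc_from_summary",
    "bland_altman",
    "pearson_r2",
    "table1_report",
    "pp_plot",
    "bland_altman_plot",
]

logger = logging.getLogger(__name__)


def _as_table(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise InputError("ratings must be a 2-D (targets x raters) table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InputError(f"need at least 2 targets and 2 raters, got {n}x{k}")
    if not np.isfinite(x).all():
        raise InputError("ratings table contains missing or non-finite values")
    return x


def icc_a1(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """Single-measure absolute-agreement ICC from a two-way model.

    With row (target), column (rater) and error mean squares MSR, MSC, MSE
    from the two-way ANOVA decomposition,

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The confidence interval is the standard F-distribution construction for
    the absolute-agreement single-measure coefficient.
    """
    x = _as_table(values)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_total = float(((x - grand) ** 2).sum())
    if ss_total <= 1e-14:
        raise DegenerateDataError("ratings table has zero total variance")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) <= 1e-14:
        raise DegenerateDataError("degenerate ANOVA decomposition (zero denominator)")
    icc = (msr - mse) / denom

    if mse <= 1e-14 and msc <= 1e-14:
        # perfect agreement: interval collapses
        return 1.0, 1.0, 1.0

    alpha = 1.0 - confidence
    rho = min(icc, 1.0 - 1e-12)
    a = (k * rho) / (n * (1.0 - rho))
    b = 1.0 + (k * rho * (n - 1)) / (n * (1.0 - rho))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    lower = float(min(lower, icc))
    upper = float(min(max(upper, icc), 1.0))
    return float(icc), lower, upper


def sem(sd: float, icc: float) -> float:
    """Standard error of measurement: sd * sqrt(1 - ICC)."""
    if sd < 0:
        raise InputError("sd must be >= 0")
    if icc > 1:
        raise InputError("icc must be <= 1")
    return sd * math.sqrt(1.0 - icc)


def mdc(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence: SEM * 1.96 * sqrt(2)."""
    if sem_value < 0:
        raise InputError("sem_value must be >= 0")
    return sem_value * 1.96 * math.sqrt(2.0)


def sem_mdc_from_summary(sd: float, icc: float, round_sem: bool = True) -> tuple[float, float]:
    """SEM and MDC from printed summary inputs (SD, ICC).

    With ``round_sem=True`` the MDC is computed from the SEM rounded to two
    decimals, as in published summary tables.
    """
    s = sem(sd, icc)
    if round_sem:
        s = round(s, 2)
    return s, mdc(s)


def bland_altman(a, b) -> tuple[float, float, float, float]:
    """Bland-Altman agreement: (bias, sd_diff, loa_low, loa_high).

    bias = mean(a - b); limits of agreement = bias +/- 1.96 * sample SD of
    the differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("inputs must be 1-D with equal length")
    if len(a) < 2:
        raise InputError("need at least 2 paired values")
    diff = a - b
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    return bias, sd_diff, bias - 1.96 * sd_diff, bias + 1.96 * sd_diff


def pearson_r2(a, b) -> float:
    """Squared Pearson product-moment correlation, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise InputError("inputs must be 1-D with equal length >= 3")
    if a.std() <= 1e-14 or b.std() <= 1e-14:
        raise DegenerateDataError("zero variance in one of the inputs")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def table1_report(
    df: pd.DataFrame,
    subject_col: str = "subject",
    frame_col: str = "frame",
    rater_col: str = "rater",
    value_col: str = "mt_mm",
    confidence: float = 0.95,
    round_sem: bool = False,
) -> pd.DataFrame:
    """Per-subject and pooled reliability summary from long-format ratings.

    Each row of ``df`` is one (subject, frame, rater) thickness reading in
    mm.  Returns one summary row per subject plus an "Overall" row pooling
    all frames, with columns: subject, n, k, mean, sd, icc, icc_ci_low,
    icc_ci_high, sem, mdc, mdc_pct_mean.  Groups with fewer than two frames
    (or no variance) are skipped with a warning.
    """
    rows = []
    groups = [(str(s), g) for s, g in df.groupby(subject_col)]
    groups.append(("Overall", df))
    for name, g in groups:
        pivot = g.pivot_table(index=frame_col, columns=rater_col, values=value_col)
        if pivot.isna().any().any() or len(pivot) < 2 or pivot.shape[1] < 2:
            warnings.warn(f"group {name!r}: fewer than 2 complete frames/raters, skipped")
            continue
        table = pivot.to_numpy()
        try:
            icc, lo, hi = icc_a1(table, confidence)
        except DegenerateDataError:
            warnings.warn(f"group {name!r}: degenerate ratings, skipped")
            continue
        mean = float(table.mean())
        sd = float(table.std(ddof=1))
        s, m = sem_mdc_from_summary(sd, icc, round_sem=round_sem)
        rows.append(
            {
                "subject": name,
                "n": len(pivot),
                "k": pivot.shape[1],
                "mean": mean,
                "sd": sd,
                "icc": icc,
                "icc_ci_low": lo,
                "icc_ci_high": hi,
                "sem": s,
                "mdc": m,
                "mdc_pct_mean": 100.0 * m / mean if mean else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pp_plot(values, ax=None):
    """Normal P-P plot helper (visual normality check only)."""
    import matplotlib.pyplot as plt

    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    empirical = (np.arange(1, n + 1) - 0.5) / n
    theoretical = stats.norm.cdf(values, loc=values.mean(), scale=values.std(ddof=1))
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(theoretical, empirical, "o", ms=3)
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("theoretical cumulative probability")
    ax.set_ylabel("empirical cumulative probability")
    return ax


def bland_altman_plot(a, b, ax=None):
    """Scatter of pairwise means vs differences with bias and limits."""
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    bias, sd_diff, lo, hi = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot((a + b) / 2.0, a - b, "o", ms=3)
    for yv, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(yv, color="k", linestyle=style, lw=1)
    ax.set_xlabel("mean of methods (mm)")
    ax.set_ylabel("difference (mm)")
    return ax
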