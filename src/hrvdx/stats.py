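"""Test statistics recomputable from published summary numbers.

Group comparisons in case–control HRV studies are usually reported only as
``n``, mean and s.d. per group, or as contingency counts.  These routines
reconstruct the corresponding Pearson chi-square, pooled two-sample t, and
one-way ANOVA F statistics directly from such summaries, so printed
results can be checked without the raw per-subject data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "chi_square_independence",
    "t_from_summary",
    "anova_from_summary",
]


@dataclass(frozen=True)
class GroupSummary:
    """One group's ``n``, mean, and standard deviation."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    ``chi2 = sum (O - E)^2 / E`` with expected counts from the margins; no
    continuity correction; ``df = (r - 1)(c - 1)``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("every row and column total must be positive")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance (Student) two-sample t from group summaries.

    ``df = n_a + n_b - 2``; two-sided p.  Degenerate zero-variance input:
    equal means give t = 0; unequal means give an infinite t (p = 0).
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    delta = a.mean - b.mean
    if sp2 == 0.0:
        t = 0.0 if delta == 0 else float(np.inf) * np.sign(delta)
        return t, df, 0.0 if delta else 1.0
    t = float(delta / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n)))
    return t, df, float(2.0 * sps.t.sf(abs(t), df))


def anova_from_summary(groups: list[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA F reconstructed from per-group (n, mean, sd).

    Between- and within-group sums of squares follow exactly from the
    summaries: ``SSB = sum n_i (mean_i - grand)^2`` and
    ``SSW = sum (n_i - 1) sd_i^2``.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    grand = float(np.sum(ns * means) / np.sum(ns))
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    df1 = len(groups) - 1
    df2 = int(np.sum(ns)) - len(groups)
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else float(np.inf)
        return f, df1, df2, 1.0 if ssb == 0.0 else 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))
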