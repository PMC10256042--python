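"""Rest/Task/After segmentation and the nine-feature discriminant vector.

Each condition of the three-behavioural-state paradigm is summarised by
averaging the sliding spectral estimates from 30 s after its onset to its
end — the skip discards estimates whose trailing 30-s window still reaches
into the previous condition.  The summaries are then combined into the
nine predictors of the discriminant equation: the Rest level of HF, LF and
LF/HF, plus the Task/Rest and After/Rest ratios of each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import SpectralTrend

__all__ = [
    "ConditionSchedule",
    "PeriodSummary",
    "FEATURE_NAMES",
    "period_means",
    "build_features",
]

INDICES = ("lf", "hf", "lf_plus_hf", "lf_over_hf", "hr")

#: Canonical order of the discriminant features (coefficients a..i).
FEATURE_NAMES = (
    "hf_rest",
    "hf_task_rest",
    "hf_after_rest",
    "lf_rest",
    "lf_task_rest",
    "lf_after_rest",
    "ratio_rest",
    "ratio_task_rest",
    "ratio_after_rest",
)


@dataclass(frozen=True)
class ConditionSchedule:
    """Ordered, contiguous (label, onset_s, duration_s) triples."""

    periods: tuple

    def __post_init__(self) -> None:
        ps = tuple((str(l), float(o), float(d)) for l, o, d in self.periods)
        object.__setattr__(self, "periods", ps)
        for i, (label, onset, dur) in enumerate(ps):
            if dur <= 30.0:
                raise ValueError(
                    f"condition {label!r} lasts {dur:.0f} s; must exceed the 30-s skip"
                )
            if i and abs(ps[i - 1][1] + ps[i - 1][2] - onset) > 1e-9:
                raise ValueError("conditions must be contiguous and non-overlapping")

    @classmethod
    def default(cls) -> "ConditionSchedule":
        return cls((("Rest", 0.0, 60.0), ("Task", 60.0, 100.0), ("After", 160.0, 60.0)))

    @classmethod
    def from_any(cls, obj) -> "ConditionSchedule":
        if isinstance(obj, ConditionSchedule):
            return obj
        return cls(tuple(obj))

    @property
    def labels(self) -> tuple:
        return tuple(label for label, _, _ in self.periods)


@dataclass(frozen=True)
class PeriodSummary:
    """Per-condition means of LF, HF, LF+HF (ms²), LF/HF, and HR (bpm).

    ``table.loc[index, condition]`` with index in ``INDICES``.
    """

    table: pd.DataFrame

    def value(self, index: str, condition: str) -> float:
        return float(self.table.loc[index, condition])


def period_means(
    trend: SpectralTrend,
    schedule: ConditionSchedule | list,
    skip_s: float = 30.0,
) -> PeriodSummary:
    """Average the spectral trend per condition, skipping its first ``skip_s`` s.

    An estimate at time ``t`` (the trailing edge of its window) belongs to
    condition ``(label, onset, duration)`` when
    ``onset + skip_s <= t <= onset + duration``.  LF/HF estimates flagged
    undefined (NaN) are excluded from the LF/HF mean only.
    """
    schedule = ConditionSchedule.from_any(schedule)
    t = np.asarray(trend.t_s)
    cols = {}
    for label, onset, dur in schedule.periods:
        sel = (t >= onset + skip_s - 1e-9) & (t <= onset + dur + 1e-9)
        if not sel.any():
            raise ValueError(f"no spectral estimates fall in condition {label!r}")
        ratio = np.asarray(trend.lfhf_ratio)[sel]
        cols[label] = [
            float(np.mean(np.asarray(trend.lf_ms2)[sel])),
            float(np.mean(np.asarray(trend.hf_ms2)[sel])),
            float(np.mean(np.asarray(trend.lfhf_sum_ms2)[sel])),
            float(np.nanmean(ratio)) if np.any(np.isfinite(ratio)) else np.nan,
            float(np.mean(np.asarray(trend.hr_bpm)[sel])),
        ]
    return PeriodSummary(table=pd.DataFrame(cols, index=list(INDICES)))


def build_features(
    p: PeriodSummary,
    rest: str = "Rest",
    task: str = "Task",
    after: str = "After",
) -> pd.Series:
    """Nine discriminant predictors from the period summary.

    Levels are the Rest means of HF, LF and LF/HF; response features are
    the Task/Rest and After/Rest ratios of the period means (ratios of
    means, not means of per-estimate ratios).
    """
    out = {}
    for index, stem in (("hf", "hf"), ("lf", "lf"), ("lf_over_hf", "ratio")):
        r = p.value(index, rest)
        if not np.isfinite(r) or r == 0:
            raise ValueError(f"Rest mean of {index!r} is zero/undefined; ratios are undefined")
        out[f"{stem}_rest"] = r
        out[f"{stem}_task_rest"] = p.value(index, task) / r
        out[f"{stem}_after_rest"] = p.value(index, after) / r
    return pd.Series(out).reindex(list(FEATURE_NAMES))
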