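"""Fisher linear discriminant over the nine HRV features.

Two diagnostic groups are separated by the linear score

``D = a HF[Rest] + b HF[Task/Rest] + c HF[After/Rest]
    + d LF[Rest] + e LF[Task/Rest] + f LF[After/Rest]
    + g LF/HF[Rest] + h LF/HF[Task/Rest] + i LF/HF[After/Rest]
    - discriminant point``

with coefficients ``w = S_pooled^{-1} (mu_pos - mu_neg)`` and the cut at
the equal-prior midpoint, so D > 0 supports the positive (first-named)
diagnosis.  Resubstitution confusion counts, sensitivity/specificity, and
the Mahalanobis distance between the group means (with its Hotelling-T²
F test) summarise the separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .paradigm import FEATURE_NAMES

__all__ = [
    "DiscriminantModel",
    "ConfusionCounts",
    "fit_lda",
    "d_score",
    "classify_cohort",
    "sensitivity_specificity",
    "mahalanobis_separation",
]


@dataclass(frozen=True)
class DiscriminantModel:
    """Linear discriminant: 9 coefficients, the cut point, and the labels."""

    coefficients: pd.Series
    discriminant_point: float
    positive_label: str
    negative_label: str

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise ValueError("model needs at least one coefficient")
        if not np.all(np.isfinite(self.coefficients.to_numpy())) or not np.isfinite(
            self.discriminant_point
        ):
            raise ValueError("model parameters must be finite")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "discriminant_point": float(self.discriminant_point),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscriminantModel":
        p = json.loads(Path(path).read_text())
        return cls(
            coefficients=pd.Series(p["coefficients"]),
            discriminant_point=float(p["discriminant_point"]),
            positive_label=p["positive_label"],
            negative_label=p["negative_label"],
        )


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-group counts of positive (D > 0) and negative (D < 0) scores.

    Scores exactly at zero are counted positive (total, deterministic tie
    rule).  ``table.loc[group, "positive" | "negative" | "total"]``.
    """

    table: pd.DataFrame


def _features(cohort: pd.DataFrame, feature_names=FEATURE_NAMES) -> np.ndarray:
    missing = [c for c in feature_names if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing feature columns: {missing}")
    X = cohort[list(feature_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("cohort features must be finite (no missing values)")
    return X


def _pooled_cov(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    na, nb = Xa.shape[0], Xb.shape[0]
    Sa = np.cov(Xa, rowvar=False, ddof=1)
    Sb = np.cov(Xb, rowvar=False, ddof=1)
    return ((na - 1) * np.atleast_2d(Sa) + (nb - 1) * np.atleast_2d(Sb)) / (na + nb - 2)


def _solve_spd(S: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Solve S x = v with a small ridge fallback for singular pooled covariance."""
    try:
        return np.linalg.solve(S, v)
    except np.linalg.LinAlgError:
        p = S.shape[0]
        eps = 1e-6 * np.trace(S) / p
        return np.linalg.solve(S + eps * np.eye(p), v)


def fit_lda(
    cohort: pd.DataFrame,
    positive_label: str,
    negative_label: str,
    feature_names=FEATURE_NAMES,
) -> DiscriminantModel:
    """Fit the Fisher discriminant between two groups of the cohort.

    ``w = S_pooled^{-1} (mu_pos - mu_neg)``; the discriminant point is the
    projection of the mean of means, ``w . (mu_pos + mu_neg) / 2`` (equal
    priors), so the two group means score symmetrically about zero.
    """
    for label in (positive_label, negative_label):
        if (cohort["group"] == label).sum() < 2:
            raise ValueError(f"group {label!r} needs at least 2 subjects")
    Xp = _features(cohort[cohort["group"] == positive_label], feature_names)
    Xn = _features(cohort[cohort["group"] == negative_label], feature_names)
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    S = _pooled_cov(Xp, Xn)
    w = _solve_spd(S, mu_p - mu_n)
    point = float(w @ (mu_p + mu_n) / 2.0)
    return DiscriminantModel(
        coefficients=pd.Series(w, index=list(feature_names)),
        discriminant_point=point,
        positive_label=positive_label,
        negative_label=negative_label,
    )


def d_score(model: DiscriminantModel, fv) -> float | np.ndarray:
    """Discriminant score(s): coefficient dot features minus the cut point.

    ``fv`` may be a single feature Series/array or a cohort DataFrame.
    """
    names = list(model.coefficients.index)
    if isinstance(fv, pd.DataFrame):
        X = _features(fv, names)
    elif isinstance(fv, pd.Series):
        X = fv.reindex(names).to_numpy(dtype=float)
    else:
        X = np.asarray(fv, dtype=float)
    out = X @ model.coefficients.to_numpy() - model.discriminant_point
    return float(out) if np.ndim(out) == 0 else out


def classify_cohort(model: DiscriminantModel, cohort: pd.DataFrame) -> ConfusionCounts:
    """Per-group counts of positive and negative D-scores (D = 0 → positive)."""
    rows = {}
    for label, sub in cohort.groupby("group", sort=False):
        s = np.atleast_1d(d_score(model, sub))
        pos = int(np.sum(s >= 0))
        rows[label] = {"positive": pos, "negative": int(s.size - pos), "total": int(s.size)}
    return ConfusionCounts(table=pd.DataFrame(rows).T[["positive", "negative", "total"]])


def sensitivity_specificity(
    counts: ConfusionCounts, positive_label: str, negative_label: str
) -> tuple[float, float]:
    """Percent sensitivity and specificity from the confusion counts.

    Sensitivity = positive-group fraction scoring D > 0; specificity =
    negative-group fraction scoring D < 0.  Both as percentages rounded to
    one decimal.
    """
    t = counts.table
    for label in (positive_label, negative_label):
        if label not in t.index or t.loc[label, "total"] == 0:
            raise ValueError(f"no subjects for group {label!r}")
    sens = 100.0 * t.loc[positive_label, "positive"] / t.loc[positive_label, "total"]
    spec = 100.0 * t.loc[negative_label, "negative"] / t.loc[negative_label, "total"]
    return round(float(sens), 1), round(float(spec), 1)


def mahalanobis_separation(
    cohort: pd.DataFrame,
    label_a: str,
    label_b: str,
    feature_names=FEATURE_NAMES,
) -> tuple[float, float]:
    """Mahalanobis distance between two group means and its p-value.

    ``d = sqrt((mu_a - mu_b)^T S_pooled^{-1} (mu_a - mu_b))``; the p-value
    comes from the two-sample Hotelling T² statistic,
    ``T² = (n_a n_b / (n_a + n_b)) d²``, referred to an F distribution with
    ``(p, n_a + n_b - p - 1)`` degrees of freedom.
    """
    Xa = _features(cohort[cohort["group"] == label_a], feature_names)
    Xb = _features(cohort[cohort["group"] == label_b], feature_names)
    na, nb, p = Xa.shape[0], Xb.shape[0], len(feature_names)
    diff = Xa.mean(axis=0) - Xb.mean(axis=0)
    S = _pooled_cov(Xa, Xb)
    d2 = float(diff @ _solve_spd(S, diff))
    d = float(np.sqrt(max(d2, 0.0)))
    t2 = na * nb / (na + nb) * d2
    df2 = na + nb - p - 1
    if df2 <= 0:
        return d, float("nan")
    f_stat = t2 * df2 / (p * (na + nb - 2))
    p_value = float(sps.f.sf(f_stat, p, df2))
    return d, p_value
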