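"""Published summary tables used as worked-example inputs.

A case–control study of major depressive disorder (MDD), chronic fatigue
syndrome (CFS), and healthy controls reported heart-rate-variability
indices for the Rest/Task/After paradigm as group summaries (mean ± s.d.),
the sex composition of the groups, and the confusion counts of three
pairwise linear-discriminant analyses.  Raw per-subject recordings were
not published; these printed numbers are the only quantitative anchor, and
serve here as inputs for recomputing the derived statistics and for
parameterising synthetic cohorts.
"""

from __future__ import annotations

import numpy as np

from .stats import GroupSummary
from .synth import CohortSpec

__all__ = [
    "GROUP_N",
    "SEX_COUNTS",
    "HRV_SUMMARIES",
    "CONFUSION_COUNTS",
    "group_summaries",
    "cohort_spec_from_summaries",
]

GROUPS = ("Control", "MDD", "CFS")
GROUP_N = {"Control": 46, "MDD": 49, "CFS": 44}

#: Males / females per group (rows: MDD, CFS, Control).
SEX_COUNTS = {"MDD": (20, 29), "CFS": (11, 33), "Control": (20, 26)}

#: (mean, sd) of each HRV index per group and period.  Powers in ms²,
#: LF/HF unitless, HR in beats/min.
HRV_SUMMARIES = {
    "lf": {
        "Control": {"Rest": (780, 742), "Task": (517, 475), "After": (966, 799)},
        "MDD": {"Rest": (266, 320), "Task": (340, 463), "After": (572, 821)},
        "CFS": {"Rest": (601, 979), "Task": (469, 438), "After": (802, 1328)},
    },
    "hf": {
        "Control": {"Rest": (388, 368), "Task": (136, 122), "After": (438, 392)},
        "MDD": {"Rest": (77, 105), "Task": (86, 127), "After": (165, 215)},
        "CFS": {"Rest": (214, 255), "Task": (152, 165), "After": (395, 587)},
    },
    "lf_plus_hf": {
        "Control": {"Rest": (780, 742), "Task": (517, 475), "After": (966, 799)},
        "MDD": {"Rest": (266, 320), "Task": (340, 463), "After": (572, 821)},
        "CFS": {"Rest": (815, 1129), "Task": (622, 588), "After": (1196, 1656)},
    },
    "lf_over_hf": {
        "Control": {"Rest": (1.58, 1.49), "Task": (4.10, 4.11), "After": (1.71, 1.37)},
        "MDD": {"Rest": (3.34, 3.71), "Task": (4.93, 5.00), "After": (3.60, 3.73)},
        "CFS": {"Rest": (4.98, 8.99), "Task": (4.63, 3.98), "After": (3.19, 3.17)},
    },
    "hr": {
        "Control": {"Rest": (73.2, 8.51), "Task": (82.2, 9.6), "After": (72.4, 8.7)},
        "MDD": {"Rest": (80.6, 12.2), "Task": (84.4, 13.7), "After": (79.0, 11.9)},
        "CFS": {"Rest": (79.2, 10.8), "Task": (85.1, 13.1), "After": (77.6, 12.1)},
    },
}

#: Resubstitution confusion counts of the three pairwise discriminants:
#: {(positive, negative): {group: (n_D_positive, n_D_negative)}}.
CONFUSION_COUNTS = {
    ("MDD", "Control"): {"MDD": (43, 6), "Control": (11, 35)},
    ("CFS", "Control"): {"CFS": (44, 0), "Control": (4, 42)},
    ("MDD", "CFS"): {"MDD": (45, 4), "CFS": (0, 44)},
}


def group_summaries(index: str, period: str) -> list[GroupSummary]:
    """``GroupSummary`` triple (Control, MDD, CFS) for one index/period."""
    return [
        GroupSummary(g, GROUP_N[g], *HRV_SUMMARIES[index][g][period]) for g in GROUPS
    ]


def _ratio_moments(num: tuple, den: tuple) -> tuple[float, float]:
    """Delta-method moments of a ratio of independent positive variables:
    mean of means, CVs added in quadrature."""
    mean = num[0] / den[0]
    cv = float(np.hypot(num[1] / num[0], den[1] / den[0]))
    return mean, mean * cv


def cohort_spec_from_summaries(
    groups=GROUPS, n_override: int | None = None, seed: int = 0
) -> CohortSpec:
    """Nine-feature ``CohortSpec`` parameterised from the published summaries.

    Rest levels take the printed (mean, sd) directly.  The study did not
    print per-subject Task/Rest and After/Rest ratio summaries, so ratio
    features get delta-method moments from the period summaries (ratio of
    the means; coefficients of variation added in quadrature).  Features
    are drawn independently — the real within-subject correlations are
    unknown — so cohorts from this spec emulate the marginal structure of
    the published groups, not their joint structure.
    """
    spec_groups = {}
    for g in groups:
        feats = {}
        for index, stem in (("hf", "hf"), ("lf", "lf"), ("lf_over_hf", "ratio")):
            tab = HRV_SUMMARIES[index][g]
            feats[f"{stem}_rest"] = tuple(tab["Rest"])
            feats[f"{stem}_task_rest"] = _ratio_moments(tab["Task"], tab["Rest"])
            feats[f"{stem}_after_rest"] = _ratio_moments(tab["After"], tab["Rest"])
        spec_groups[g] = {"n": n_override or GROUP_N[g], "features": feats}
    return CohortSpec(groups=spec_groups, lognormal=True, seed=seed)
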