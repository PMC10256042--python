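#!/usr/bin/env python
"""Recompute the test statistics that follow from the published summary
tables alone: the sex-by-group chi-square, the pooled t for LF/HF at Rest
(MDD vs control), and the one-way group-effect ANOVA F values at Rest.

Writes results/summary_statistics.json.
"""

import json
from pathlib import Path

from hrvdx.reference_data import SEX_COUNTS, group_summaries
from hrvdx.stats import anova_from_summary, chi_square_independence, t_from_summary

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = {}

    chi2, df, p = chi_square_independence([SEX_COUNTS[g] for g in ("MDD", "CFS", "Control")])
    out["sex_by_group_chi_square"] = {"chi2": round(chi2, 3), "df": df, "p": round(p, 4)}
    print(f"sex ratio across groups: chi2({df}) = {chi2:.3f}, p = {p:.3f} (not significant)")

    summ = {s.label: s for s in group_summaries("lf_over_hf", "Rest")}
    t, df, p = t_from_summary(summ["MDD"], summ["Control"])
    out["lf_hf_rest_mdd_vs_control_t"] = {"t": round(t, 3), "df": df, "p": round(p, 4)}
    print(f"LF/HF at Rest, MDD vs control: t({df}) = {t:.3f}, p = {p:.3f} "
          "(elevated sympathovagal balance in MDD)")

    for index in ("lf", "hf", "lf_plus_hf", "lf_over_hf", "hr"):
        f, df1, df2, p = anova_from_summary(group_summaries(index, "Rest"))
        out[f"{index}_rest_group_anova"] = {
            "F": round(f, 2), "df": [df1, df2], "p": round(p, 5)
        }
        print(f"group effect on {index} at Rest: F({df1},{df2}) = {f:.2f}, p = {p:.4f}")

    (RESULTS).mkdir(exist_ok=True)
    (RESULTS / "summary_statistics.json").write_text(json.dumps(out, indent=2))
    print("\n-> results/summary_statistics.json")


if __name__ == "__main__":
    main()
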