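#!/usr/bin/env python
"""Run the full per-subject pipeline on the simulated traces: range
filtering, resampling at the mean heart rate, sliding 30-s maximum-entropy
spectra every 2 s, Rest/Task/After averaging, and the nine-feature vector.

Reads results/traces/*.csv; writes results/trends/*.csv and
results/subject_features.csv.
"""

import json
from pathlib import Path

import pandas as pd

from hrvdx.pipeline import run_subject
from hrvdx.preprocess import filter_rr_range, read_rr_csv, resample_uniform
from hrvdx.spectral import spectral_trend

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    (RESULTS / "trends").mkdir(parents=True, exist_ok=True)
    rows = {}
    for path in sorted((RESULTS / "traces").glob("*.csv")):
        name = path.stem
        rr = read_rr_csv(path)
        schedule = [
            (d["condition"], d["onset_s"], d["duration_s"])
            for d in json.loads(path.with_suffix(".schedule.json").read_text())
        ]
        clean, n_replaced = filter_rr_range(rr)
        trend = spectral_trend(resample_uniform(clean))
        trend.to_csv(RESULTS / "trends" / f"{name}.csv")
        res = run_subject(rr, schedule)
        rows[name] = res.features
        print(f"{name}: {n_replaced} beats replaced; {len(trend)} spectral estimates; "
              f"HF Task/Rest = {res.features['hf_task_rest']:.2f}, "
              f"HF After/Rest = {res.features['hf_after_rest']:.2f}")

    feats = pd.DataFrame(rows).T
    feats.index.name = "subject"
    feats.to_csv(RESULTS / "subject_features.csv")
    print("\nThe reactive profile suppresses HF under task load and rebounds "
          "afterwards (Task/Rest < 1 < After/Rest); the blunted profile "
          "keeps both ratios near 1.")


if __name__ == "__main__":
    main()
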