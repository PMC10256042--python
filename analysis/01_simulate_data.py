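#!/usr/bin/env python
"""Generate the synthetic study material: RR traces for a reactive
(control-like) and a blunted subject, a digit-sequence set, and a
three-group feature cohort parameterised from the published summaries.

Writes results/traces/*.csv (+ schedule sidecars), results/digits/*.txt,
and results/cohort.csv.
"""

from pathlib import Path

import numpy as np

from hrvdx.reference_data import cohort_spec_from_summaries
from hrvdx.synth import (
    DigitSequenceSpec,
    SyntheticTraceSpec,
    generate_cohort,
    generate_digit_sequence,
    generate_rr_trace,
    write_digit_sequence,
    write_trace,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

PROFILES = {
    # normal reactivity: HF/LF suppressed during Task, rebound at After
    "control": SyntheticTraceSpec(
        mean_rr_ms=(820, 730, 820), lf_amp_ms=(25, 12, 30), hf_amp_ms=(28, 10, 35),
        white_noise_sd_ms=2.0, seed=101,
    ),
    # blunted autonomic response: no change across conditions
    "blunted": SyntheticTraceSpec(
        mean_rr_ms=(800, 800, 800), lf_amp_ms=(20, 20, 20), hf_amp_ms=(18, 18, 18),
        white_noise_sd_ms=2.0, seed=102,
    ),
    # control-like trace with 5% artifact beats, for the cleaning stage
    "control_artifacts": SyntheticTraceSpec(
        mean_rr_ms=(820, 730, 820), lf_amp_ms=(25, 12, 30), hf_amp_ms=(28, 10, 35),
        white_noise_sd_ms=2.0, artifact_rate=0.05, seed=103,
    ),
}


def main() -> None:
    (RESULTS / "traces").mkdir(parents=True, exist_ok=True)
    (RESULTS / "digits").mkdir(parents=True, exist_ok=True)

    for name, spec in PROFILES.items():
        rr = generate_rr_trace(spec)
        write_trace(rr, RESULTS / "traces" / f"{name}.csv",
                    RESULTS / "traces" / f"{name}.schedule.json")
        print(f"{name}: {len(rr)} beats over {rr.duration_ms / 1000:.0f} s "
              f"(mean RR {np.mean(rr.rr_ms):.0f} ms)")

    for p_count in (0.0, 0.3, 1.0):
        seq = generate_digit_sequence(DigitSequenceSpec(length=100, p_count=p_count, seed=7))
        write_digit_sequence(seq, RESULTS / "digits" / f"pcount_{p_count:.1f}.txt")
    print("digit sequences written for p_count in {0.0, 0.3, 1.0} (100 digits each)")

    cohort = generate_cohort(cohort_spec_from_summaries(seed=11))
    cohort.to_csv(RESULTS / "cohort.csv", index=False)
    print(f"cohort: {len(cohort)} subjects in groups "
          f"{cohort['group'].value_counts().to_dict()} -> results/cohort.csv")


if __name__ == "__main__":
    main()
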