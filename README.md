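# hrvdx

Heart-rate-variability (HRV) analysis of a three-behavioural-state
paradigm — initial rest (**Rest**, ~60 s), a random-number-generation task
(**Task**, 100 s), and post-task rest (**After**, 60 s) — and
linear-discriminant scoring of the resulting autonomic profiles. The
package is aimed at researchers studying autonomic dysregulation in major
depressive disorder (MDD) and chronic fatigue syndrome (CFS), where the
baseline HRV level, its suppression under task load, and its post-task
recovery together carry diagnostic information that no single resting
measurement provides.

## What it computes

**Spectral HRV.** R–R interval series are cleaned (beats outside
273–1500 ms replaced by the average of their valid neighbours), resampled
at the mean heart rate, and analysed with the maximum-entropy method:
Burg's autoregressive estimator fitted to the trailing 30-s window every
2 s. Band powers are the integrals of the one-sided AR spectrum over

- LF (low frequency): 0.04–0.15 Hz — baroreflex-related modulation,
- HF (high frequency): 0.15–0.40 Hz — respiratory (parasympathetic)
  modulation,

plus their sum LF+HF, ratio LF/HF, and the heart rate (60000/RR). Each
condition is summarised by the mean over estimates from 30 s after its
onset to its end.

**Discriminant score.** Per subject, nine predictors — the Rest levels of
HF, LF and LF/HF plus their Task/Rest and After/Rest ratios — enter a
Fisher linear discriminant

```
D = a·HF[Rest] + b·HF[Task/Rest] + c·HF[After/Rest]
  + d·LF[Rest] + e·LF[Task/Rest] + f·LF[After/Rest]
  + g·LF/HF[Rest] + h·LF/HF[Task/Rest] + i·LF/HF[After/Rest]
  − discriminant point
```

with `w = S_pooled⁻¹(μ₊ − μ₋)` and the cut at the equal-prior midpoint,
so `D > 0` supports the first-named diagnosis. Confusion counts,
sensitivity/specificity, and the Mahalanobis distance between group means
(with its Hotelling-T² test) summarise each pairwise contrast.

**Task randomness.** The 100-digit task output is scored by counting bias
(CB, fraction of ±1 steps), interval bias (IB, fraction of repeated
inter-digit steps), and Evans' RNG index (digram concentration).

**Summary statistics.** Pearson chi-square, pooled two-sample t, and
one-way ANOVA F recomputed directly from published `(n, mean, sd)` /
contingency summaries.

Because no raw recordings are publicly available, the `synth` module
generates RR traces with sinusoidal LF/HF modulation of known band power
(`a²/2` for amplitude `a`), feature cohorts moment-matched to published
group summaries, and digit sequences with tunable biases.

## Worked example

```python
from hrvdx.synth import SyntheticTraceSpec, generate_rr_trace
from hrvdx.pipeline import run_subject

# a reactive ("control-like") subject: HF suppressed in Task, rebound After
spec = SyntheticTraceSpec(
    mean_rr_ms=(820, 730, 820),
    lf_amp_ms=(25, 12, 30),
    hf_amp_ms=(28, 10, 35),
    white_noise_sd_ms=2.0,
    seed=101,
)
res = run_subject(generate_rr_trace(spec))
print(res.features[["hf_rest", "hf_task_rest", "hf_after_rest"]].round(2))
```

prints

```
hf_rest          382.37
hf_task_rest       0.14
hf_after_rest      1.68
dtype: float64
```

an HF power of ~382 ms² at Rest (modulation amplitude 28 ms contributes
28²/2 = 392 ms², minus estimation loss), suppression to 14% of baseline
under task load, and a rebound to 168% afterwards — the normal reactivity
pattern. A blunted profile keeps both ratios near 1.

The numbered scripts under `analysis/` run the full study on synthetic
material: `01_simulate_data.py` (traces, digits, cohort),
`02_subject_pipeline.py` (spectral trends and features),
`03_randomness_indices.py`, `04_summary_statistics.py` (chi-square
3.860, pooled t 2.998, group-effect F 16.61/6.23 at Rest from the
published summaries), and `05_discriminant_study.py` (pairwise
discriminants on the resampled cohort). Tables land in `results/`.

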