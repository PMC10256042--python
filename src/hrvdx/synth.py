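"""Synthetic RR traces, feature cohorts, and digit sequences.

No raw recordings ship with this package, so every downstream stage is
exercised on synthetic data with known structure:

* **RR traces** — heartbeat interval series with sinusoidal LF/HF
  modulation of known amplitude per behavioural condition, white
  beat-to-beat noise, and an optional fraction of out-of-range artifact
  beats.  A sinusoid of amplitude ``a`` contributes exactly ``a**2 / 2``
  of variance, giving closed-form targets for band-power recovery.
* **Cohorts** — subjects × 9-feature tables drawn from moment-matched
  positive distributions (lognormal for right-skewed power features,
  zero-truncated normal otherwise), parameterised by group ``(mean, sd)``
  summaries.
* **Digit sequences** — the 100-digit random-generation task output, with
  tunable counting and interval-repetition tendencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RRSeries

__all__ = [
    "SyntheticTraceSpec",
    "CohortSpec",
    "DigitSequenceSpec",
    "CONDITIONS",
    "generate_rr_trace",
    "generate_cohort",
    "generate_digit_sequence",
    "lognormal_params",
    "write_digit_sequence",
]

CONDITIONS = ("Rest", "Task", "After")


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Parameters of one synthetic Rest/Task/After RR recording.

    Amplitudes are in ms of RR modulation; the LF and HF modulation
    frequencies must lie inside their respective analysis bands.
    ``artifact_rate`` is the fraction of beats replaced by out-of-range
    values (mimicking missed/paroxysmal beats).
    """

    mean_rr_ms: tuple[float, float, float] = (800.0, 700.0, 800.0)
    lf_amp_ms: tuple[float, float, float] = (25.0, 15.0, 30.0)
    hf_amp_ms: tuple[float, float, float] = (25.0, 12.0, 27.0)
    lf_freq_hz: float = 0.10
    hf_freq_hz: float = 0.25
    white_noise_sd_ms: float = 3.0
    artifact_rate: float = 0.0
    durations_s: tuple[float, float, float] = (60.0, 100.0, 60.0)
    modulation: str = "sinusoid"
    seed: int = 0

    def __post_init__(self) -> None:
        _check(
            self.modulation in ("sinusoid", "band_noise"),
            "modulation must be 'sinusoid' or 'band_noise'",
        )
        for name in ("mean_rr_ms", "lf_amp_ms", "hf_amp_ms", "durations_s"):
            v = getattr(self, name)
            _check(len(v) == 3, f"{name} needs one value per condition (Rest, Task, After)")
        for m in self.mean_rr_ms:
            _check(273.0 < m < 1500.0, f"mean_rr_ms={m} outside the plausible (273, 1500) ms")
        for name in ("lf_amp_ms", "hf_amp_ms"):
            for a in getattr(self, name):
                _check(a >= 0, f"{name} must be >= 0")
        _check(0.04 <= self.lf_freq_hz <= 0.15, f"lf_freq_hz={self.lf_freq_hz} outside 0.04-0.15 Hz")
        _check(0.15 <= self.hf_freq_hz <= 0.40, f"hf_freq_hz={self.hf_freq_hz} outside 0.15-0.4 Hz")
        _check(self.white_noise_sd_ms >= 0, "white_noise_sd_ms must be >= 0")
        _check(0 <= self.artifact_rate < 0.2, f"artifact_rate={self.artifact_rate} outside [0, 0.2)")
        for d in self.durations_s:
            _check(d > 0, "durations_s must be positive")

    @property
    def schedule(self) -> list[tuple[str, float, float]]:
        """(label, onset_s, duration_s) for the three conditions."""
        out, onset = [], 0.0
        for label, dur in zip(CONDITIONS, self.durations_s):
            out.append((label, onset, dur))
            onset += dur
        return out


@dataclass(frozen=True)
class CohortSpec:
    """Group-wise ``(mean, sd)`` summaries of the 9 discriminant features.

    ``groups`` maps a group label to ``{"n": int, "features": {name: (mean, sd)}}``.
    With ``lognormal=True`` features are drawn from a lognormal matched to
    the given moments (power features are positive and right-skewed, sd of
    the order of the mean); otherwise from a normal truncated at zero.

    ``correlation`` optionally sets a common within-subject correlation
    matrix across features (Gaussian copula on the underlying normals);
    the default is independence — published tables report only marginal
    moments, so there is no data-derived default for the joint structure.
    """

    groups: dict = field(default_factory=dict)
    lognormal: bool = True
    correlation: "np.ndarray | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        _check(len(self.groups) >= 1, "at least one group required")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            object.__setattr__(self, "correlation", R)
            _check(R.ndim == 2 and R.shape[0] == R.shape[1], "correlation must be square")
            _check(np.allclose(R, R.T) and np.allclose(np.diag(R), 1.0),
                   "correlation must be symmetric with unit diagonal")
            k = {len(g["features"]) for g in self.groups.values()}
            _check(k == {R.shape[0]}, "correlation size must match the feature count")
        for label, g in self.groups.items():
            _check(g.get("n", 0) >= 2, f"group {label!r} needs n >= 2")
            for name, (mean, sd) in g["features"].items():
                _check(sd >= 0, f"{label}/{name}: sd must be >= 0")
                if self.lognormal:
                    _check(mean > 0, f"{label}/{name}: lognormal matching needs mean > 0")


@dataclass(frozen=True)
class DigitSequenceSpec:
    """Generator settings for a synthetic random-number-generation response.

    With probability ``p_count`` the next digit is the previous one ±1
    (uniform over the feasible directions at the 0/9 edges); with
    probability ``p_repeat_interval`` the previous inter-digit step is
    repeated (when feasible); otherwise the digit is drawn uniformly.
    """

    length: int = 100
    p_count: float = 0.0
    p_repeat_interval: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.length >= 2, "length must be >= 2")
        _check(0 <= self.p_count <= 1, "p_count must be in [0, 1]")
        _check(0 <= self.p_repeat_interval <= 1, "p_repeat_interval must be in [0, 1]")
        _check(self.p_count + self.p_repeat_interval <= 1, "p_count + p_repeat_interval must be <= 1")


def _condition_at(spec: SyntheticTraceSpec, t_s: float) -> int:
    edges = np.cumsum(spec.durations_s)
    return int(np.searchsorted(edges, t_s, side="right"))


def generate_rr_trace(spec: SyntheticTraceSpec) -> RRSeries:
    """Generate one synthetic Rest/Task/After RR interval series.

    Beat ``i`` at onset time ``t_i`` (cumulative, starting at 0) gets

    ``RR_i = mean_rr(c) + lf_amp(c) sin(2 pi f_LF t_i)
           + hf_amp(c) sin(2 pi f_HF t_i) + N(0, noise_sd)``

    with condition ``c`` selected by ``t_i``; the next onset is
    ``t_{i+1} = t_i + RR_i``.  Artifact beats replace the clean value with
    a uniform draw from the out-of-range set (below 273 or above 1500 ms)
    *after* the timeline is built, so condition boundary times are
    unaffected by artifacts.
    """
    rng = np.random.default_rng(spec.seed)
    total_s = float(sum(spec.durations_s))

    if spec.modulation == "sinusoid":
        def lf_mod(t: float) -> float:
            return float(np.sin(2 * np.pi * spec.lf_freq_hz * t))

        def hf_mod(t: float) -> float:
            return float(np.sin(2 * np.pi * spec.hf_freq_hz * t))
    else:
        # band-limited noise: K random-phase tones spread over each band,
        # unit variance overall so a condition amplitude a still contributes
        # a^2/2 of band power (matching the single-sinusoid calibration)
        K = 20
        lf_f = rng.uniform(0.04, 0.15, K)
        hf_f = rng.uniform(0.15, 0.40, K)
        lf_ph, hf_ph = rng.uniform(0, 2 * np.pi, K), rng.uniform(0, 2 * np.pi, K)
        norm = np.sqrt(K)

        def lf_mod(t: float) -> float:
            return float(np.sum(np.sin(2 * np.pi * lf_f * t + lf_ph))) / norm

        def hf_mod(t: float) -> float:
            return float(np.sum(np.sin(2 * np.pi * hf_f * t + hf_ph))) / norm

    t, rr, t_list = 0.0, [], []
    while t < total_s:
        c = min(_condition_at(spec, t), 2)
        val = (
            spec.mean_rr_ms[c]
            + spec.lf_amp_ms[c] * lf_mod(t)
            + spec.hf_amp_ms[c] * hf_mod(t)
            + (rng.normal(0.0, spec.white_noise_sd_ms) if spec.white_noise_sd_ms > 0 else 0.0)
        )
        val = max(val, 1.0)
        t_list.append(t * 1000.0)
        rr.append(val)
        t += val / 1000.0
    rr = np.array(rr)
    if spec.artifact_rate > 0:
        n_art = int(round(spec.artifact_rate * rr.size))
        idx = rng.choice(rr.size, size=n_art, replace=False)
        low = rng.uniform(60.0, 272.0, size=n_art)
        high = rng.uniform(1501.0, 2500.0, size=n_art)
        rr[idx] = np.where(rng.random(n_art) < 0.5, low, high)
    return RRSeries(rr_ms=rr, t_ms=np.array(t_list), schedule=spec.schedule)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched lognormal ``(mu, sigma)`` for a target mean and sd."""
    if mean <= 0:
        raise ValueError("lognormal moment matching needs mean > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort feature table from group-wise summary moments.

    Returns a DataFrame with ``subject_id``, ``group``, and one column per
    feature; features are drawn independently per subject.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label in spec.groups:
        g = spec.groups[label]
        n = int(g["n"])
        feats = g["features"]
        if spec.correlation is not None:
            L = np.linalg.cholesky(spec.correlation)
            Z = rng.normal(size=(n, len(feats))) @ L.T
        else:
            Z = rng.normal(size=(n, len(feats)))
        cols = {}
        for j, (name, (mean, sd)) in enumerate(feats.items()):
            z = Z[:, j]
            if sd == 0:
                cols[name] = np.full(n, float(mean))
            elif spec.lognormal:
                mu, sigma = lognormal_params(mean, sd)
                cols[name] = np.exp(mu + sigma * z)
            else:
                v = mean + sd * z
                # zero-truncation by redraw; negligible when mean >> sd
                bad = v <= 0
                while bad.any():
                    v[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                    bad = v <= 0
                cols[name] = v
        df = pd.DataFrame(cols)
        df.insert(0, "group", label)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(out))])
    return out


def generate_digit_sequence(spec: DigitSequenceSpec) -> np.ndarray:
    """Generate a digit sequence over {0..9} per the spec's tendencies."""
    rng = np.random.default_rng(spec.seed)
    s = np.empty(spec.length, dtype=int)
    s[0] = rng.integers(0, 10)
    prev_diff: int | None = None
    for i in range(1, spec.length):
        u = rng.random()
        prev = s[i - 1]
        if u < spec.p_count:
            dirs = [d for d in (-1, 1) if 0 <= prev + d <= 9]
            s[i] = prev + dirs[rng.integers(0, len(dirs))]
        elif u < spec.p_count + spec.p_repeat_interval and prev_diff is not None and 0 <= prev + prev_diff <= 9:
            s[i] = prev + prev_diff
        else:
            s[i] = rng.integers(0, 10)
        prev_diff = int(s[i] - prev)
    return s


def write_digit_sequence(digits: np.ndarray, path: str | Path) -> None:
    """Write a sequence as plain text, one digit character after another."""
    Path(path).write_text("".join(str(int(d)) for d in digits) + "\n")


def write_trace(rr: RRSeries, csv_path: str | Path, schedule_path: str | Path | None = None) -> None:
    """Write the trace CSV plus a JSON schedule sidecar."""
    from .preprocess import write_rr_csv

    write_rr_csv(rr, csv_path)
    if schedule_path is not None and rr.schedule is not None:
        payload = [
            {"condition": label, "onset_s": onset, "duration_s": dur}
            for label, onset, dur in rr.schedule
        ]
        Path(schedule_path).write_text(json.dumps(payload, indent=2))
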