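"""Randomness indices of the digit-generation task.

Subjects produce 100 digits (0–9) at 1 Hz while "being random"; human
sequences deviate from randomness in stereotyped ways.  Three classical
indices quantify this, each a unitless score in [0, 1]:

* ``counting_bias`` (CB) — fraction of adjacent pairs that count up or
  down by one.
* ``interval_bias`` (IB) — fraction of adjacent signed inter-digit steps
  that repeat the previous step.
* ``rng_index`` (RNG) — Evans' digram-concentration index: 0 when every
  occupied first-order digit pair occurs once, 1 when each digit is always
  followed by the same successor.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["counting_bias", "interval_bias", "rng_index", "randomness_indices", "read_digit_sequence"]


def _as_digits(s) -> np.ndarray:
    d = np.asarray(s, dtype=int)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("digit sequence must be 1-D with length >= 2")
    if d.min() < 0 or d.max() > 9:
        raise ValueError("digits must lie in 0..9")
    return d


def counting_bias(s) -> float:
    """Fraction of adjacent ordered pairs differing by exactly 1.

    Non-modular: 9→0 and 0→9 are not counting steps.
    """
    d = _as_digits(s)
    return float(np.mean(np.abs(np.diff(d)) == 1))


def interval_bias(s) -> float:
    """Fraction of adjacent signed inter-digit steps that repeat.

    With ``d_i = s_{i+1} - s_i``, the proportion of ``i`` with
    ``d_{i+1} = d_i`` over the ``length - 2`` comparisons.
    """
    d = _as_digits(s)
    if d.size < 3:
        raise ValueError("interval bias needs length >= 3")
    steps = np.diff(d)
    return float(np.mean(steps[1:] == steps[:-1]))


def rng_index(s) -> float:
    """Evans' RNG index: digram concentration relative to the marginals.

    From the 10x10 table of first-order pair counts ``n_ij`` with row
    marginals ``n_i``:

    ``RNG = sum_{n_ij>0} n_ij ln n_ij / sum_{n_i>0} n_i ln n_i``

    The denominator vanishes only when every row marginal is <= 1 (all
    occupied digrams are singletons); RNG is then defined as 0.
    """
    d = _as_digits(s)
    table = np.zeros((10, 10))
    np.add.at(table, (d[:-1], d[1:]), 1.0)
    cells = table[table > 0]
    rows = table.sum(axis=1)
    rows = rows[rows > 0]
    denom = float(np.sum(rows * np.log(rows)))
    if denom == 0.0:
        return 0.0
    return float(np.sum(cells * np.log(cells)) / denom)


def randomness_indices(s) -> dict:
    """All three indices as ``{"CB": ..., "IB": ..., "RNG": ...}``."""
    return {"CB": counting_bias(s), "IB": interval_bias(s), "RNG": rng_index(s)}


def read_digit_sequence(path: str | Path) -> np.ndarray:
    """Read a plain-text digit sequence (whitespace ignored)."""
    text = "".join(Path(path).read_text().split())
    return _as_digits([int(c) for c in text])
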