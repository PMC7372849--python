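"""Paired t-test and 2x2 chi-square, the study's two significance procedures.

Both statistics are computed from their closed forms; scipy supplies only
the t and chi-square distribution tails.  Tests are two-sided; significance
is conventionally read at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class DegenerateSampleError(ValueError):
    """Paired differences have zero variance; the t statistic is undefined."""


class DegenerateTableError(ValueError):
    """A 2x2 table has a zero marginal; chi-square is undefined."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length measurement lists paired by case."""

    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("paired samples must be equal-length 1D arrays")
        if len(a) < 2:
            raise ValueError("paired t-test needs n >= 2")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)


@dataclass(frozen=True)
class ProportionPair:
    """Worse-case counts for two methods: successes out of n each."""

    successes_a: int
    n_a: int
    successes_b: int
    n_b: int

    def __post_init__(self) -> None:
        for s, n in ((self.successes_a, self.n_a), (self.successes_b, self.n_b)):
            if not (0 <= s <= n):
                raise ValueError(f"invalid proportion: {s}/{n}")


def paired_t_test(sample: PairedSample) -> TestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    d = sample.values_a - sample.values_b
    n = len(d)
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError("paired differences have zero variance")
    t = float(d.mean()) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=float(df), p_value=p)


def two_sample_t_test(a, b) -> TestResult:
    """Welch two-sample t-test, for comparisons across unpaired cohorts
    (e.g. an auto-segmentation cohort vs the interobserver cases)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two-sample t-test needs n >= 2 in each group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateSampleError("both samples have zero variance")
    se2 = va / len(a) + vb / len(b)
    t = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = se2 ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=float(df), p_value=p)


def chi_square_2x2(pair: ProportionPair, correction: bool = False) -> TestResult:
    """Pearson chi-square on the 2x2 (worse / not-worse) x (method) table,
    with optional Yates continuity correction."""
    if pair.n_a == 0 or pair.n_b == 0:
        raise DegenerateTableError("both methods need n > 0")
    obs = np.array(
        [
            [pair.successes_a, pair.n_a - pair.successes_a],
            [pair.successes_b, pair.n_b - pair.successes_b],
        ],
        dtype=float,
    )
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise DegenerateTableError("a zero marginal makes chi-square undefined")
    expected = row @ col / total
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(statistic=chi2, df=1.0, p_value=p)
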