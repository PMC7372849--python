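"""Consolidated interobserver-normalized scoring and the worse-case rule.

The score maps any metric value T onto a 0–100 scale anchored by two points:
the perfect value P (DSC = 1; HD95/MSD = 0) scores 100, and the
interobserver reference value R scores 50:

    score = max(50 + 50 * (T - R) / (P - R), 0)

Values worse than R by more than the R-to-P gap clamp to 0.  An upper clamp
at 100 guards against T beyond P, which cannot occur for valid metric values
(DSC <= 1, distances >= 0).

The worse-case rule counts, per organ, the cases whose DSC against the
manual reference falls strictly below the organ's interobserver mean DSC,
and reports the count as a percentage rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .interobserver import ReferenceBaseline
from .metrics import MetricRecord

#: perfect metric values: overlap metrics peak at 1, distances at 0
PERFECT_VALUES: dict[str, float] = {
    "dsc": 1.0,
    "recall": 1.0,
    "precision": 1.0,
    "hd": 0.0,
    "hd95": 0.0,
    "msd": 0.0,
}

#: metrics entering the generalized (overall) score
GENERAL_SCORE_METRICS: tuple[str, ...] = ("dsc", "hd95", "msd")


class DegenerateConfigError(ValueError):
    """P equals R for a scored metric, making the score undefined."""


@dataclass
class ScoreConfig:
    """Perfect values P and reference values R per metric."""

    reference: dict[str, float]
    perfect: dict[str, float] = field(default_factory=lambda: dict(PERFECT_VALUES))
    metrics_for_general_score: tuple[str, ...] = GENERAL_SCORE_METRICS

    def __post_init__(self) -> None:
        for m in self.metrics_for_general_score:
            if m not in self.reference:
                raise ValueError(f"no reference value for metric {m!r}")
            if self.perfect[m] == self.reference[m]:
                raise DegenerateConfigError(
                    f"perfect and reference values coincide for {m!r}"
                )

    @classmethod
    def from_baseline(cls, baseline: ReferenceBaseline) -> "ScoreConfig":
        return cls(reference={m: baseline.mean[m] for m in MetricRecord.FIELDS})


@dataclass
class ScoreRecord:
    """Per-metric and generalized scores for one organ/method."""

    organ: str
    method: str
    per_metric: dict[str, float]
    general: float
    n_cases: int


def score(T: float, P: float, R: float) -> float:
    """Consolidated score of a metric value T given perfect P and reference R."""
    if P == R:
        raise DegenerateConfigError(f"degenerate score configuration: P == R == {P}")
    if not np.isfinite(T):
        raise ValueError(f"metric value must be finite, got {T}")
    raw = 50.0 + 50.0 * (T - R) / (P - R)
    return float(min(max(raw, 0.0), 100.0))


def score_record(rec: MetricRecord, cfg: ScoreConfig) -> dict[str, float]:
    """Score every configured metric of one record."""
    out: dict[str, float] = {}
    for m in cfg.metrics_for_general_score:
        val = getattr(rec, m, None)
        if val is None:
            raise ValueError(
                f"record case={rec.case_id!r} organ={rec.organ!r} lacks metric {m!r}"
            )
        out[m] = score(val, cfg.perfect[m], cfg.reference[m])
    return out


def generalized_score(records: list[MetricRecord], cfg: ScoreConfig) -> list[ScoreRecord]:
    """Per-(organ, method) scores: per-metric means over cases, then the
    generalized score as the mean of the three per-record metric scores over
    all cases (per-record averaging, then pooling over patients)."""
    if not records:
        raise ValueError("no metric records to score")
    groups: dict[tuple[str, str], list[MetricRecord]] = {}
    for r in records:
        groups.setdefault((r.organ, r.method), []).append(r)
    out: list[ScoreRecord] = []
    for (organ, method), recs in sorted(groups.items()):
        per_rec = [score_record(r, cfg) for r in recs]
        per_metric = {
            m: float(np.mean([s[m] for s in per_rec]))
            for m in cfg.metrics_for_general_score
        }
        general = float(np.mean([s[m] for s in per_rec for m in cfg.metrics_for_general_score]))
        out.append(
            ScoreRecord(
                organ=organ, method=method, per_metric=per_metric,
                general=general, n_cases=len(recs),
            )
        )
    return out


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3), as used for printed percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def count_worse_cases(
    per_case_dsc: list[float], organ_reference_dsc: float
) -> tuple[int, int, float]:
    """Count cases with DSC strictly below the organ's interobserver mean DSC.

    Returns (count, total, percent) with percent = 100*count/total rounded
    half-up to one decimal.  Ties with the reference count as not-worse.
    """
    if len(per_case_dsc) == 0:
        raise ValueError("empty per-case DSC list")
    if not (0.0 < organ_reference_dsc <= 1.0):
        raise ValueError(f"reference DSC must be in (0, 1], got {organ_reference_dsc}")
    vals = np.asarray(per_case_dsc, dtype=float)
    count = int((vals < organ_reference_dsc).sum())
    total = int(len(vals))
    percent = round_half_up(100.0 * count / total, 1)
    return count, total, percent
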