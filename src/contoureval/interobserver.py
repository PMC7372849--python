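"""Interobserver-variability baseline.

A small cohort of cases, each contoured by several observers, yields pairwise
metric records; their pooled per-metric means are the reference values R that
anchor the consolidated score at 50, and the per-organ mean DSC is the
reference for the worse-than-manual counting rule.

Pairing scheme: by default every *ordered* observer pair contributes a
record (both directions), so the asymmetric recall/precision are each
represented in both roles and their pooled means coincide.  A
designated-reference mode is also provided, in which one named observer is
always the reference Vx; that scheme makes pooled recall and precision
differ, as happens when a study fixes a gold-standard observer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import MetricRecord, evaluate_pair
from .volume_io import StructureSet

logger = logging.getLogger(__name__)


@dataclass
class ObserverCohort:
    """Cases each carrying the same organs contoured by >= 2 observers."""

    cases: list[StructureSet]

    def __post_init__(self) -> None:
        if not self.cases:
            raise ValueError("observer cohort has no cases")


@dataclass
class ReferenceBaseline:
    """Pooled interobserver statistics used as scoring references.

    ``mean``/``sd`` are per-metric pooled over all organs, cases and pairs;
    ``per_organ_dsc`` is the per-organ mean DSC used by the worse-case rule.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    per_organ_dsc: dict[str, float] = field(default_factory=dict)
    n_pairs: int = 0

    def reference(self, metric: str) -> float:
        return self.mean[metric]


def pairwise_metrics(
    cohort: ObserverCohort,
    scheme: str = "ordered",
    reference_observer: str | None = None,
    percentile_mode: str = "interpolation",
) -> list[MetricRecord]:
    """Metric records for observer pairs, per organ per case.

    scheme="ordered": one record per ordered pair (k observers -> k(k-1)
    records per organ).  scheme="designated": pairs (reference_observer,
    other) only.  Missing organ/observer combinations are skipped with a
    warning, not an error.
    """
    if scheme not in ("ordered", "designated"):
        raise ValueError(f"unknown pairing scheme {scheme!r}")
    if scheme == "designated" and not reference_observer:
        raise ValueError("designated scheme requires reference_observer")
    records: list[MetricRecord] = []
    for sset in cohort.cases:
        observers = sset.provenances()
        if len(observers) < 2:
            raise ValueError(f"case {sset.case_id}: need >= 2 observers")
        for organ in sset.organs():
            available = [
                o for o in observers
                if any(m.organ == organ and m.provenance == o for m in sset.masks)
            ]
            missing = set(observers) - set(available)
            if missing:
                logger.warning(
                    "case %s organ %s: observers %s missing, pairs skipped",
                    sset.case_id, organ, sorted(missing),
                )
            if scheme == "ordered":
                pairs = itertools.permutations(available, 2)
            else:
                if reference_observer not in available:
                    logger.warning(
                        "case %s organ %s: reference observer %s missing",
                        sset.case_id, organ, reference_observer,
                    )
                    continue
                pairs = ((reference_observer, o) for o in available if o != reference_observer)
            for ref, test in pairs:
                rec = evaluate_pair(
                    sset.get(organ, ref),
                    sset.get(organ, test),
                    case_id=sset.case_id,
                    percentile_mode=percentile_mode,
                )
                rec.method = f"{ref}|{test}"
                records.append(rec)
    return records


def build_baseline(records: list[MetricRecord]) -> ReferenceBaseline:
    """Pool pairwise records into the per-metric reference values R.

    The pooled mean/SD is taken over all records (all organs, cases and
    pairs); SD is the sample standard deviation (n-1), or 0 for a single
    record.
    """
    if not records:
        raise ValueError("cannot build a baseline from an empty record list")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for m in MetricRecord.FIELDS:
        vals = np.array([getattr(r, m) for r in records], dtype=float)
        mean[m] = float(vals.mean())
        sd[m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    per_organ: dict[str, float] = {}
    for organ in sorted({r.organ for r in records}):
        vals = [r.dsc for r in records if r.organ == organ]
        per_organ[organ] = float(np.mean(vals))
    return ReferenceBaseline(mean=mean, sd=sd, per_organ_dsc=per_organ, n_pairs=len(records))
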