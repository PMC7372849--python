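"""End-to-end study replica.

Given a cohort (truth + observer + method contours + dose per case), the
pipeline computes:

1. the interobserver baseline (pairwise metrics on the observer sub-cohort,
   pooled into reference values R);
2. per-case geometric metrics of every auto-segmentation method against the
   manual reference;
3. a metric summary table (mean +/- SD per metric and method, paired t-test
   between methods, Welch t-test against the interobserver records);
4. worse-case percentages per organ (DSC below the organ's interobserver
   mean) with chi-square comparison between methods;
5. consolidated scores per organ and method, with paired t-tests on the
   per-case generalized scores;
6. DVH endpoints and relative dose differences vs the manual contours.

All summary cells are recomputable from the retained per-case records.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dosimetry import DEFAULT_ENDPOINTS, delta_dose, dose_metrics
from .interobserver import ObserverCohort, ReferenceBaseline, build_baseline, pairwise_metrics
from .metrics import MetricRecord, UndefinedMetricError, evaluate_pair
from .scoring import GENERAL_SCORE_METRICS, ScoreConfig, generalized_score, score_record
from .scoring import count_worse_cases
from .stats import (
    DegenerateSampleError,
    PairedSample,
    ProportionPair,
    chi_square_2x2,
    paired_t_test,
    two_sample_t_test,
)
from .synth import MANUAL, CohortBundle
from .volume_io import StructureSet

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Study configuration.

    ``n_baseline_cases`` observer-contoured cases feed the interobserver
    baseline (the study design used a handful of multi-observer cases);
    alternatively explicit ``reference_values`` R may be supplied.
    """

    methods: list[str] | None = None
    n_baseline_cases: int = 5
    reference_values: dict[str, float] | None = None
    score_metrics: tuple[str, ...] = GENERAL_SCORE_METRICS
    dvh_endpoints: tuple[float, ...] = DEFAULT_ENDPOINTS
    percentile_mode: str = "interpolation"
    chi_square_correction: bool = False
    reference_provenance: str = MANUAL


@dataclass
class StudyReport:
    baseline: ReferenceBaseline
    baseline_records: pd.DataFrame
    per_case_metrics: pd.DataFrame
    metric_summary: pd.DataFrame
    worse_cases: pd.DataFrame
    scores: pd.DataFrame
    per_case_scores: pd.DataFrame
    delta_dose: pd.DataFrame
    delta_dose_summary: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "baseline_records": self.baseline_records,
            "per_case_metrics": self.per_case_metrics,
            "metric_summary": self.metric_summary,
            "worse_cases": self.worse_cases,
            "scores": self.scores,
            "per_case_scores": self.per_case_scores,
            "delta_dose": self.delta_dose,
            "delta_dose_summary": self.delta_dose_summary,
        }


def _records_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def compute_method_metrics(
    bundle: CohortBundle, cfg: RunConfig
) -> tuple[list[MetricRecord], list[str]]:
    """Metrics of every method contour against the manual reference."""
    methods = cfg.methods or bundle.methods
    records: list[MetricRecord] = []
    skipped: list[str] = []
    for case in bundle.cases:
        sset = case.structures
        for organ in sset.organs():
            try:
                ref = sset.get(organ, cfg.reference_provenance)
            except KeyError:
                skipped.append(f"{case.case_id}/{organ}: no manual reference")
                continue
            for method in methods:
                try:
                    test = sset.get(organ, method)
                except KeyError:
                    skipped.append(f"{case.case_id}/{organ}/{method}: missing contour")
                    continue
                try:
                    records.append(
                        evaluate_pair(
                            ref, test, case_id=case.case_id,
                            percentile_mode=cfg.percentile_mode,
                        )
                    )
                except UndefinedMetricError as exc:
                    skipped.append(str(exc))
    for msg in skipped:
        logger.warning("skipped: %s", msg)
    return records, skipped


def compute_baseline(bundle: CohortBundle, cfg: RunConfig):
    """Interobserver baseline from the first ``n_baseline_cases`` cases."""
    n = min(cfg.n_baseline_cases, len(bundle.cases))
    obs_cases = []
    for case in bundle.cases[:n]:
        masks = [m for m in case.structures.masks if m.provenance in bundle.observers]
        obs_cases.append(StructureSet(case_id=case.case_id, masks=masks))
    cohort = ObserverCohort(cases=obs_cases)
    obs_records = pairwise_metrics(cohort, percentile_mode=cfg.percentile_mode)
    baseline = build_baseline(obs_records)
    if cfg.reference_values:
        baseline.mean.update(cfg.reference_values)
    return baseline, obs_records


def _metric_summary(
    method_records: list[MetricRecord],
    obs_records: list[MetricRecord],
    methods: list[str],
) -> pd.DataFrame:
    df = _records_frame(method_records)
    obs_df = _records_frame(obs_records)
    rows = []
    for metric in MetricRecord.FIELDS:
        row: dict = {"metric": metric}
        per_method: dict[str, pd.Series] = {}
        for m in methods:
            sub = df[df["method"] == m]
            # one value per case: mean over organs keeps cases as the paired unit
            per_case = sub.groupby("case_id")[metric].mean()
            per_method[m] = per_case
            row[f"{m}_mean"] = sub[metric].mean()
            row[f"{m}_sd"] = sub[metric].std(ddof=1)
        row["baseline_mean"] = obs_df[metric].mean()
        row["baseline_sd"] = obs_df[metric].std(ddof=1)
        for a, b in itertools.combinations(methods, 2):
            joined = pd.concat([per_method[a], per_method[b]], axis=1, join="inner")
            try:
                res = paired_t_test(
                    PairedSample(joined.iloc[:, 0].values, joined.iloc[:, 1].values)
                )
                row[f"p_{a}_vs_{b}"] = res.p_value
            except (DegenerateSampleError, ValueError):
                row[f"p_{a}_vs_{b}"] = np.nan
        for m in methods:
            sub = df[df["method"] == m]
            try:
                row[f"p_{m}_vs_baseline"] = two_sample_t_test(
                    sub[metric].values, obs_df[metric].values
                ).p_value
            except (DegenerateSampleError, ValueError):
                row[f"p_{m}_vs_baseline"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _worse_case_table(
    method_records: list[MetricRecord],
    baseline: ReferenceBaseline,
    methods: list[str],
    correction: bool,
) -> pd.DataFrame:
    df = _records_frame(method_records)
    rows = []
    for organ in sorted(df["organ"].unique()):
        ref_dsc = baseline.per_organ_dsc.get(organ, baseline.mean["dsc"])
        counts: dict[str, tuple[int, int, float]] = {}
        for m in methods:
            vals = df[(df["organ"] == organ) & (df["method"] == m)]["dsc"].tolist()
            if not vals:
                continue
            counts[m] = count_worse_cases(vals, ref_dsc)
        for m, (cnt, tot, pct) in counts.items():
            rows.append(
                {
                    "organ": organ,
                    "method": m,
                    "reference_dsc": ref_dsc,
                    "worse": cnt,
                    "total": tot,
                    "percent": pct,
                }
            )
        if len(methods) >= 2 and all(m in counts for m in methods[:2]):
            a, b = methods[:2]
            try:
                res = chi_square_2x2(
                    ProportionPair(
                        counts[a][0], counts[a][1], counts[b][0], counts[b][1]
                    ),
                    correction=correction,
                )
                for r in rows[-len(counts):]:
                    r[f"p_{a}_vs_{b}"] = res.p_value
            except Exception:
                pass
    return pd.DataFrame(rows)


def _score_tables(
    method_records: list[MetricRecord],
    score_cfg: ScoreConfig,
    methods: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    per_case_rows = []
    for r in method_records:
        s = score_record(r, score_cfg)
        per_case_rows.append(
            {
                "case_id": r.case_id,
                "organ": r.organ,
                "method": r.method,
                **{f"score_{m}": v for m, v in s.items()},
                "general": float(np.mean(list(s.values()))),
            }
        )
    per_case = pd.DataFrame(per_case_rows)
    summary = generalized_score(method_records, score_cfg)
    rows = []
    for sr in summary:
        row = {
            "organ": sr.organ,
            "method": sr.method,
            **{f"score_{m}": v for m, v in sr.per_metric.items()},
            "general": sr.general,
            "n_cases": sr.n_cases,
        }
        rows.append(row)
    score_df = pd.DataFrame(rows)
    # paired t-test on per-case generalized scores between the first two methods
    if len(methods) >= 2:
        a, b = methods[:2]
        pvals = {}
        for organ in score_df["organ"].unique():
            sa = per_case[(per_case["organ"] == organ) & (per_case["method"] == a)]
            sb = per_case[(per_case["organ"] == organ) & (per_case["method"] == b)]
            joined = pd.merge(sa, sb, on="case_id", suffixes=("_a", "_b"))
            try:
                pvals[organ] = paired_t_test(
                    PairedSample(joined["general_a"].values, joined["general_b"].values)
                ).p_value
            except (DegenerateSampleError, ValueError):
                pvals[organ] = np.nan
        score_df[f"p_{a}_vs_{b}"] = score_df["organ"].map(pvals)
    return score_df, per_case


def compute_delta_dose(
    bundle: CohortBundle, cfg: RunConfig
) -> pd.DataFrame:
    """Per case/organ/method relative DVH-endpoint differences (%) against
    the manual contour, using the case's planned dose distribution."""
    methods = cfg.methods or bundle.methods
    rows = []
    for case in bundle.cases:
        sset = case.structures
        for organ in sset.organs():
            try:
                ref_mask = sset.get(organ, cfg.reference_provenance)
                ms = dose_metrics(case.dose, ref_mask, endpoints=cfg.dvh_endpoints)
            except (KeyError, Exception) as exc:  # noqa: BLE001 - recorded, run continues
                if isinstance(exc, KeyError):
                    continue
                logger.warning("dose metrics failed for %s/%s: %s", case.case_id, organ, exc)
                continue
            for method in methods:
                try:
                    auto_mask = sset.get(organ, method)
                    auto = dose_metrics(case.dose, auto_mask, endpoints=cfg.dvh_endpoints)
                    comp = delta_dose(ms, auto)
                except Exception as exc:  # noqa: BLE001
                    logger.warning(
                        "delta dose failed for %s/%s/%s: %s", case.case_id, organ, method, exc
                    )
                    continue
                row = {"case_id": case.case_id, "organ": organ, "method": method}
                for name, val in comp.delta.items():
                    row[f"delta_{name}"] = val
                for name in ("d98", "d95", "d50", "d2"):
                    row[f"manual_{name}"] = ms.endpoint(name)
                    row[f"auto_{name}"] = auto.endpoint(name)
                rows.append(row)
    return pd.DataFrame(rows)


def _delta_summary(delta_df: pd.DataFrame, methods: list[str]) -> pd.DataFrame:
    if delta_df.empty:
        return pd.DataFrame()
    endpoints = [c for c in delta_df.columns if c.startswith("delta_")]
    rows = []
    for organ in sorted(delta_df["organ"].unique()):
        for ep in endpoints:
            row: dict = {"organ": organ, "endpoint": ep.removeprefix("delta_")}
            per_method = {}
            for m in methods:
                sub = delta_df[(delta_df["organ"] == organ) & (delta_df["method"] == m)]
                per_method[m] = sub.set_index("case_id")[ep]
                row[f"{m}_mean"] = sub[ep].mean()
                row[f"{m}_sd"] = sub[ep].std(ddof=1)
            if len(methods) >= 2:
                a, b = methods[:2]
                joined = pd.concat([per_method[a], per_method[b]], axis=1, join="inner").dropna()
                try:
                    row[f"p_{a}_vs_{b}"] = paired_t_test(
                        PairedSample(joined.iloc[:, 0].values, joined.iloc[:, 1].values)
                    ).p_value
                except (DegenerateSampleError, ValueError):
                    row[f"p_{a}_vs_{b}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def run_study(bundle: CohortBundle, cfg: RunConfig | None = None) -> StudyReport:
    """Run the full geometric + dosimetric evaluation on a cohort."""
    cfg = cfg or RunConfig()
    if not bundle.cases:
        raise ValueError("empty cohort")
    methods = cfg.methods or bundle.methods

    baseline, obs_records = compute_baseline(bundle, cfg)
    method_records, skipped = compute_method_metrics(bundle, cfg)
    if not method_records:
        raise ValueError("no evaluable method contours in the cohort")

    score_cfg = ScoreConfig(
        reference={m: baseline.mean[m] for m in MetricRecord.FIELDS},
        metrics_for_general_score=cfg.score_metrics,
    )
    score_df, per_case_scores = _score_tables(method_records, score_cfg, methods)
    delta_df = compute_delta_dose(bundle, cfg)

    return StudyReport(
        baseline=baseline,
        baseline_records=_records_frame(obs_records),
        per_case_metrics=_records_frame(method_records),
        metric_summary=_metric_summary(method_records, obs_records, methods),
        worse_cases=_worse_case_table(
            method_records, baseline, methods, cfg.chi_square_correction
        ),
        scores=score_df,
        per_case_scores=per_case_scores,
        delta_dose=delta_df,
        delta_dose_summary=_delta_summary(delta_df, methods),
        skipped=skipped,
    )


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Persist every table as CSV plus the baseline as JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables().items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "baseline.json").write_text(
        json.dumps(
            {
                "mean": report.baseline.mean,
                "sd": report.baseline.sd,
                "per_organ_dsc": report.baseline.per_organ_dsc,
                "n_pairs": report.baseline.n_pairs,
            },
            indent=2,
        )
    )
    if report.skipped:
        (outdir / "skipped.log").write_text("\n".join(report.skipped))
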