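"""Time-to-onset extraction and survival comparison across drugs.

Time to onset (TTO) is the interval in days from drug initiation (earliest
day-precision therapy start for that drug on the report) to adverse-event
occurrence (the report's event date).  Reports with incomplete, partial-
precision, negative or internally inconsistent dates are excluded — never
imputed — and the exclusion reasons are tallied.

Onset distributions are compared across drugs with the Kaplan-Meier
product-limit estimator (every case is an event; there is no censoring in
case-only data, so 1 - S(t) is exactly the empirical CDF), the k-sample
log-rank test for formal inference, and the Kruskal-Wallis rank test as a
purely descriptive supplement.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

#: default onset-time bins in days; both printed endpoints are included
DEFAULT_TTO_BINS = ((0, 30), (31, 60), (61, 90), (91, 180), (181, 360), (361, None))

EXCLUSION_REASONS = (
    "missing_start", "missing_event", "partial_precision", "negative",
    "inconsistent", "none",
)


@dataclass
class OnsetRecord:
    primaryid: str
    drug: str
    tto_days: Optional[int]
    included: bool
    exclusion_reason: str = "none"


def extract_tto(bundle_or_records, case_ids: set, drug_exposure: dict, norm) -> list:
    """Per (case report, suspect drug) onset records with exclusion status.

    ``bundle_or_records`` supplies demo/drug/ther lists (a ReportBundle or
    any object with those attributes).  For each case report and each of
    its exposed canonical drugs, the start date is the earliest
    day-precision therapy start among that drug's therapy rows; the event
    date is the report's event_dt.
    """
    demo = bundle_or_records.demo
    drugs = bundle_or_records.drug
    ther = bundle_or_records.ther

    event_dt = {d.primaryid: d.event_dt for d in demo}
    # (primaryid, drug_seq) -> canonical name, for rows on case reports
    seq_name: dict = {}
    for rec in drugs:
        if rec.primaryid in case_ids:
            name = norm.canonical(rec.verbatim_name or rec.active_ingredient)
            if name is not None:
                seq_name[(rec.primaryid, rec.drug_seq)] = name
    # (primaryid, canonical) -> therapy rows
    ther_rows: dict = {}
    for row in ther:
        name = seq_name.get((row.primaryid, row.drug_seq))
        if name is not None:
            ther_rows.setdefault((row.primaryid, name), []).append(row)

    records: list = []
    for pid in sorted(case_ids):
        for drug in sorted(drug_exposure.get(pid, ())):
            records.append(
                _onset_for(pid, drug, ther_rows.get((pid, drug), ()),
                           event_dt.get(pid))
            )
    return records


def _onset_for(pid: str, drug: str, ther_rows: Sequence, event) -> OnsetRecord:
    def excluded(reason: str) -> OnsetRecord:
        return OnsetRecord(primaryid=pid, drug=drug, tto_days=None,
                           included=False, exclusion_reason=reason)

    if not ther_rows or all(r.start_dt.precision == "missing" for r in ther_rows):
        return excluded("missing_start")
    day_rows = [r for r in ther_rows if r.start_dt.is_day]
    if not day_rows:
        return excluded("partial_precision")
    start_row = min(day_rows, key=lambda r: r.start_dt.ordinal)
    if event is None or event.precision == "missing":
        return excluded("missing_event")
    if not event.is_day:
        return excluded("partial_precision")
    if start_row.end_dt.is_day and start_row.end_dt.ordinal < start_row.start_dt.ordinal:
        return excluded("inconsistent")
    tto = event.ordinal - start_row.start_dt.ordinal
    if tto < 0:
        return excluded("negative")
    return OnsetRecord(primaryid=pid, drug=drug, tto_days=int(tto), included=True)


def summarize_tto(records: Iterable[OnsetRecord], bins=DEFAULT_TTO_BINS) -> dict:
    """n, missing n, central summary and binned counts/percentages."""
    records = list(records)
    times = np.array([r.tto_days for r in records if r.included], dtype=float)
    n_missing = sum(1 for r in records if not r.included)
    reasons = Counter(r.exclusion_reason for r in records if not r.included)
    if times.size == 0:
        raise ValueError("no included onset records to summarize")
    q1, med, q3 = np.percentile(times, [25, 50, 75])
    bin_counts = {}
    for lo, hi in bins:
        label = f"{lo}-{hi}" if hi is not None else f">{lo - 1}"
        if hi is None:
            count = int(np.sum(times >= lo))
        else:
            count = int(np.sum((times >= lo) & (times <= hi)))
        bin_counts[label] = {
            "count": count,
            "percent": round(100.0 * count / times.size, 2),
        }
    return {
        "n": int(times.size),
        "n_missing": int(n_missing),
        "exclusion_reasons": dict(reasons),
        "mean": float(np.mean(times)),
        "sd": float(np.std(times, ddof=1)) if times.size > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(np.min(times)),
        "max": float(np.max(times)),
        "bins": bin_counts,
    }


@dataclass
class KMCurve:
    """Product-limit curve for one group with its median and 95% CI."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    median_ci: tuple = (math.nan, math.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.group,
            "time": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
        })


def km_fit(groups: Dict[str, Sequence], censor_flags: Optional[dict] = None) -> dict:
    """Kaplan-Meier curve per group.

    ``censor_flags`` maps group name to an event-observed indicator array;
    omitted flags mean every observation is an event (the case-only
    setting, where 1 - S(t) equals the empirical CDF exactly).  Median CI
    by inversion of the curve's log-log confidence band.
    """
    curves: dict = {}
    for name, times in groups.items():
        times = np.asarray(list(times), dtype=float)
        observed = None if censor_flags is None else censor_flags.get(name)
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=observed, label=str(name))
        sf = kmf.survival_function_
        event_table = kmf.event_table
        grid = sf.index.values
        at_risk = (event_table["at_risk"].reindex(grid)
                   .ffill().bfill().values)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        curves[name] = KMCurve(
            group=str(name),
            times=grid,
            survival=sf.iloc[:, 0].values,
            at_risk=at_risk,
            median=float(kmf.median_survival_time_),
            median_ci=(lo, hi),
        )
    return curves


def logrank(groups: Dict[str, Sequence], censor_flags: Optional[dict] = None) -> tuple:
    """k-sample log-rank test; returns (chi2, df, p)."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    durations: List[float] = []
    labels: List[str] = []
    observed: List[int] = []
    for name, times in groups.items():
        times = list(times)
        durations.extend(float(t) for t in times)
        labels.extend([str(name)] * len(times))
        flags = censor_flags.get(name) if censor_flags else None
        observed.extend(list(flags) if flags is not None else [1] * len(times))
    res = multivariate_logrank_test(durations, labels, observed)
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


def kruskal_wallis(groups: Dict[str, Sequence]) -> tuple:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Descriptive only in this pipeline; all samples identical (zero
    variance overall) yields H = 0, p = 1.
    """
    samples = [np.asarray(list(v), dtype=float) for v in groups.values()]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
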