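"""Descriptive tables, reporter-bias sensitivity analysis and the pipeline.

The descriptive summary mirrors the standard characteristics table of a
spontaneous-reporting study: sex, age bands, reporter occupation, top
reporting countries, serious-outcome codes and the onset-time block.
Outcome percentages are computed per code against the case total (a
report can carry several outcome codes, so they deliberately do not sum
to 100).  All percentages are rounded half-up to two decimals.

The sensitivity analysis removes reports from one reporter-occupation
stratum (lawyers, for litigation-bias assessment) after deduplication and
recomputes every disproportionality signal.  Lawyer-submitted reports
concentrated on one drug inflate the event background for every other
drug, so excluding them typically enlarges the positive-signal set —
masked signals surface.

``run_pipeline`` chains the whole analysis from a YAML config and writes
CSV tables plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from types import SimpleNamespace
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .case_mapping import (
    DrugNormalizer, PTQuery, build_all_contingencies, flag_cases,
    load_pt_query, normalize_drugs,
)
from .dedup import dedup_bundles
from .faers_io import read_quarter
from .interaction import count_triplets, screen_interactions
from .signal_stats import signal_table
from .synth import SynthConfig, DrugSpec, TTOModel, default_config, simulate
from .tto_survival import extract_tto, km_fit, kruskal_wallis, logrank, summarize_tto

logger = logging.getLogger("dystosignal")

OCCUPATION_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "LW": "Lawyer",
    "CN": "Consumer",
    "HP": "Other health-professional",
    "OT": "Not specified",
    "missing": "Not specified",
}

OUTCOME_LABELS = {
    "HO": "Hospitalization: initial or prolonged",
    "DS": "Disability",
    "LT": "Life-threatening",
    "DE": "Death",
    "RI": "Required intervention to prevent permanent impairment/damage",
    "CA": "Congenital anomaly",
    "OT": "Other",
}

AGE_BANDS = ("<18", "18-44", "45-64", "65-74", "75-84", ">=85", "unknown")

#: divisor converting a FAERS age unit to years
AGE_UNIT_YEARS = {"YR": 1.0, "DEC": 0.1, "MON": 12.0, "WK": 52.18,
                  "DY": 365.25, "HR": 8766.0}


def percent(count: int, total: int) -> float:
    """Half-up percentage to 2 decimals, computed in decimal arithmetic."""
    if total == 0:
        return 0.0
    value = (Decimal(100 * count) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(value)


def _age_band(age_value: Optional[float], age_unit: str) -> str:
    if age_value is None:
        return "unknown"
    divisor = AGE_UNIT_YEARS.get(age_unit.upper())
    if divisor is None:
        logger.warning("unknown age unit %r; routed to unknown band", age_unit)
        return "unknown"
    years = age_value / divisor
    if years < 18:
        return "<18"
    if years < 45:
        return "18-44"
    if years < 65:
        return "45-64"
    if years < 75:
        return "65-74"
    if years < 85:
        return "75-84"
    return ">=85"


@dataclass
class DescriptiveSummary:
    total: int
    sex: Dict[str, dict]
    age: Dict[str, dict]
    occupation: Dict[str, dict]
    countries: Dict[str, dict]
    outcomes: Dict[str, dict]
    tto: Optional[dict] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block_name in ("sex", "age", "occupation", "countries", "outcomes"):
            for label, cell in getattr(self, block_name).items():
                rows.append((block_name, label, cell["count"], cell["percent"]))
        return pd.DataFrame(rows, columns=["block", "category", "count", "percent"])


def descriptive_table(case_demo: list, tto_summary: Optional[dict] = None,
                      top_countries: int = 5) -> DescriptiveSummary:
    """Characteristics table over the case reports (one row per case)."""
    if not case_demo:
        raise ValueError("case set is empty")
    total = len(case_demo)

    def block(counts: dict) -> dict:
        return {k: {"count": v, "percent": percent(v, total)}
                for k, v in counts.items()}

    sex_counts = {"Female": 0, "Male": 0, "Not specified": 0}
    age_counts = {band: 0 for band in AGE_BANDS}
    occ_counts: Dict[str, int] = {}
    country_counts: Dict[str, int] = {}
    outcome_counts = {label: 0 for label in OUTCOME_LABELS.values()}
    for d in case_demo:
        sex_counts[{"F": "Female", "M": "Male"}.get(d.sex, "Not specified")] += 1
        age_counts[_age_band(d.age_value, d.age_unit)] += 1
        occ = OCCUPATION_LABELS.get(d.occp_cod, "Not specified")
        occ_counts[occ] = occ_counts.get(occ, 0) + 1
        if d.reporter_country:
            country_counts[d.reporter_country] = (
                country_counts.get(d.reporter_country, 0) + 1)
        for code in d.outcome_codes:
            outcome_counts[OUTCOME_LABELS[code]] += 1

    top = dict(sorted(country_counts.items(),
                      key=lambda kv: (-kv[1], kv[0]))[:top_countries])
    return DescriptiveSummary(
        total=total,
        sex=block(sex_counts),
        age=block(age_counts),
        occupation=block(dict(sorted(occ_counts.items(),
                                     key=lambda kv: (-kv[1], kv[0])))),
        countries=block(top),
        outcomes=block(outcome_counts),
        tto=tto_summary,
    )


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityDiff:
    occupation: str
    baseline_positive: set
    filtered_positive: set
    gained: set = field(default_factory=set)
    lost: set = field(default_factory=set)
    deltas: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.gained = self.filtered_positive - self.baseline_positive
        self.lost = self.baseline_positive - self.filtered_positive


def compute_signals(retained: set, reac: list, drug: list,
                    norm: DrugNormalizer, query: PTQuery,
                    roles: set = frozenset({"PS"})) -> tuple:
    """Case flags, exposure map, contingency tables and ranked signals."""
    case_ids = flag_cases(reac, retained, query)
    exposure = normalize_drugs(drug, norm, roles=roles, retained=retained)
    tables = build_all_contingencies(case_ids, exposure, retained)
    results = signal_table(tables)
    return case_ids, exposure, tables, results


def sensitivity_exclude(occupation: str, demo_all: list, retained: set,
                        reac: list, drug: list, norm: DrugNormalizer,
                        query: PTQuery,
                        roles: set = frozenset({"PS"})) -> SensitivityDiff:
    """Recompute every signal after dropping one reporter-occupation stratum."""
    occ_of = {d.primaryid: d.occp_cod for d in demo_all}
    _, _, _, baseline = compute_signals(retained, reac, drug, norm, query, roles)
    kept = {pid for pid in retained if occ_of.get(pid) != occupation}
    _, _, _, filtered = compute_signals(kept, reac, drug, norm, query, roles)

    base_by = {r.drug: r for r in baseline}
    filt_by = {r.drug: r for r in filtered}
    rows = []
    for name in sorted(set(base_by) | set(filt_by)):
        b, f = base_by.get(name), filt_by.get(name)
        rows.append({
            "drug": name,
            "a_baseline": b.a if b else 0,
            "a_filtered": f.a if f else 0,
            "ror_baseline": b.ror if b else float("nan"),
            "ror_filtered": f.ror if f else float("nan"),
            "positive_baseline": bool(b.positive) if b else False,
            "positive_filtered": bool(f.positive) if f else False,
        })
    return SensitivityDiff(
        occupation=occupation,
        baseline_positive={r.drug for r in baseline if r.positive},
        filtered_positive={r.drug for r in filtered if r.positive},
        deltas=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _synth_config_from_dict(spec: dict) -> SynthConfig:
    cfg = default_config(
        n_cases=int(spec.get("n_cases", 5000)),
        seed=int(spec.get("seed", 0)),
    )
    if "drug_catalog" in spec:
        cfg.drug_catalog = [DrugSpec(**d) for d in spec["drug_catalog"]]
        # the demo defaults key effects by drug name; a user-supplied
        # catalog invalidates them, so start those maps empty
        cfg.signal_pairs = {}
        cfg.interaction_triplets = []
        cfg.tto_models = {}
        cfg.lawyer_bias = {}
    if "pt_catalog" in spec:
        cfg.pt_catalog = [(p["pt"], float(p["prob"])) for p in spec["pt_catalog"]]
    if "target_event_pts" in spec:
        cfg.target_event_pts = list(spec["target_event_pts"])
    if "signal_pairs" in spec:
        cfg.signal_pairs = {k: float(v) for k, v in spec["signal_pairs"].items()}
    if "interaction_triplets" in spec:
        cfg.interaction_triplets = [
            (t["drugA"], t["drugB"], float(t["excess"]))
            for t in spec["interaction_triplets"]
        ]
    if "tto_models" in spec:
        cfg.tto_models = {k: TTOModel(**v) for k, v in spec["tto_models"].items()}
    if "lawyer_bias" in spec:
        cfg.lawyer_bias = {k: float(v) for k, v in spec["lawyer_bias"].items()}
    for key in ("duplicate_rate", "deletion_rate", "missing_date_rate"):
        if key in spec:
            setattr(cfg, key, float(spec[key]))
    if "occupation_mix" in spec:
        cfg.occupation_mix = {k: float(v) for k, v in spec["occupation_mix"].items()}
    if "date_window" in spec:
        cfg.date_window = tuple(str(d) for d in spec["date_window"])
    return cfg


def run_pipeline(config_path, out_dir=None) -> Path:
    """Execute ingest -> dedup -> cases -> signals -> TTO -> interactions ->
    descriptive -> sensitivity from a YAML config; returns the output dir.

    The config names either a ``synth`` block (simulation parameters) or an
    ``input.quarters`` list of directories with FAERS-style ASCII tables;
    optional keys: ``query`` (PT file), ``normalizer`` (drug-mapping CSV),
    ``roles``, ``interaction_roles``, ``min_n111``, ``tto_top_k``,
    ``sensitivity_occupation``, ``out``.
    """
    config_path = Path(config_path)
    with open(config_path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}

    if "synth" not in config and "input" not in config:
        raise ValueError("config needs a 'synth' or 'input' section")
    out = Path(out_dir or config.get("out", "results"))
    out.mkdir(parents=True, exist_ok=True)
    warnings: list = []
    manifest: dict = {"version": __version__, "config": str(config_path)}

    # --- ingest ------------------------------------------------------------
    if "synth" in config:
        synth_cfg = _synth_config_from_dict(config["synth"] or {})
        bundles, ledger = simulate(synth_cfg)
        ledger.to_json(out / "truth_ledger.json")
        manifest["seed"] = synth_cfg.seed
        drug_names = [d.name for d in synth_cfg.drug_catalog]
        default_query = PTQuery(name="synthetic-target", scope="narrow",
                                pts=set(synth_cfg.target_event_pts))
        default_norm = DrugNormalizer.identity(drug_names)
    elif "input" in config:
        bundles = [
            read_quarter(path, quarter=Path(path).name)
            for path in config["input"]["quarters"]
        ]
        default_query = default_norm = None
    else:
        raise ValueError("config needs a 'synth' or 'input' section")
    logger.info("ingest: %d bundles, %d demo rows",
                len(bundles), sum(len(b.demo) for b in bundles))

    query = (load_pt_query(config["query"]) if config.get("query")
             else default_query)
    norm = (DrugNormalizer.from_csv(config["normalizer"])
            if config.get("normalizer") else default_norm)
    if query is None or norm is None:
        raise ValueError("real-data runs need 'query' and 'normalizer' files")
    roles = frozenset(config.get("roles", ["PS"]))
    interaction_roles = frozenset(config.get("interaction_roles", ["PS", "SS"]))

    # --- dedup -------------------------------------------------------------
    dedup_result, demo_all = dedup_bundles(bundles)
    retained = dedup_result.retained_primaryids
    manifest["counts"] = {
        "parsed": len(demo_all),
        "retained": len(retained),
        "removed_as_duplicate": dedup_result.removed_as_duplicate,
        "removed_by_deletion": dedup_result.removed_by_deletion,
    }
    logger.info("dedup: %d parsed -> %d retained", len(demo_all), len(retained))
    (out / "retained_primaryids.txt").write_text(
        "\n".join(sorted(retained)) + "\n", encoding="utf-8")

    reac = [r for b in bundles for r in b.reac]
    drugs = [r for b in bundles for r in b.drug]
    ther = [r for b in bundles for r in b.ther]

    # --- cases and signals ---------------------------------------------------
    case_ids, exposure, tables, results = compute_signals(
        retained, reac, drugs, norm, query, roles)
    manifest["counts"]["cases"] = len(case_ids)
    logger.info("cases: %d of %d retained reports", len(case_ids), len(retained))
    pd.DataFrame(
        [(t.drug, t.a, t.b, t.c, t.d) for t in tables.values()],
        columns=["drug", "a", "b", "c", "d"],
    ).sort_values("drug").to_csv(out / "contingency.csv", index=False)
    pd.DataFrame([{
        "drug": r.drug, "a": r.a,
        "ror": r.ror, "ror_lo": r.ror_lo, "ror_hi": r.ror_hi,
        "prr": r.prr, "chi2": r.chi2, "ic": r.ic, "ic025": r.ic025,
        "ebgm": r.ebgm, "ebgm05": r.ebgm05,
        "flag_ror": r.flag_ror, "flag_prr": r.flag_prr,
        "flag_bcpnn": r.flag_bcpnn, "flag_mgps": r.flag_mgps,
        "positive": r.positive,
    } for r in results]).to_csv(out / "signals.csv", index=False)

    # --- time to onset -------------------------------------------------------
    pool = SimpleNamespace(demo=demo_all, drug=drugs, ther=ther)
    onset = extract_tto(pool, case_ids, exposure, norm)
    included = [r for r in onset if r.included]
    manifest["counts"]["tto_records"] = len(onset)
    manifest["counts"]["tto_included"] = len(included)
    tto_summary = summarize_tto(onset) if included else None
    if tto_summary is None:
        warnings.append("no complete-date onset records; TTO stage skipped")

    top_k = int(config.get("tto_top_k", 5))
    by_drug: Dict[str, list] = {}
    for r in included:
        by_drug.setdefault(r.drug, []).append(r.tto_days)
    groups = dict(sorted(by_drug.items(),
                         key=lambda kv: (-len(kv[1]), kv[0]))[:top_k])
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    rows = []
    if tto_summary:
        rows.append({"drug": "(all)", **{k: tto_summary[k] for k in
                     ("n", "median", "q1", "q3", "mean", "min", "max")}})
    for name, times in sorted(groups.items()):
        s = summarize_tto([r for r in included if r.drug == name])
        rows.append({"drug": name, **{k: s[k] for k in
                     ("n", "median", "q1", "q3", "mean", "min", "max")}})
    pd.DataFrame(rows).to_csv(out / "tto_summary.csv", index=False)

    if len(groups) >= 2:
        curves = km_fit(groups)
        pd.concat([c.to_frame() for c in curves.values()]).to_csv(
            out / "km_curves.csv", index=False)
        chi2, df_, p = logrank(groups)
        h, kw_p = kruskal_wallis(groups)
        manifest["tto_tests"] = {
            "logrank_chi2": chi2, "logrank_df": df_, "logrank_p": p,
            "kruskal_h": h, "kruskal_p": kw_p,
            "km_medians": {k: c.median for k, c in curves.items()},
        }
    else:
        (out / "km_curves.csv").write_text(
            "group,time,survival,at_risk\n", encoding="utf-8")
        warnings.append("fewer than two drugs with onset data; "
                        "survival comparison skipped")

    # --- interactions --------------------------------------------------------
    ddi_exposure = normalize_drugs(drugs, norm, roles=interaction_roles,
                                   retained=retained)
    min_n111 = int(config.get("min_n111", 3))
    triplets = count_triplets(retained, ddi_exposure, case_ids, min_n111=min_n111)
    screened = screen_interactions(triplets,
                                   model=config.get("e111_model", "odds_additive"))
    pd.DataFrame([{
        "drugA": t.drugA, "drugB": t.drugB, "n111": t.n111,
        "n11plus": t.n11plus, "e111": t.e111, "model_used": t.model_used,
        "omega": t.omega, "omega025": t.omega025, "omega975": t.omega975,
        "flag": t.flag,
    } for t in screened]).to_csv(out / "triplets.csv", index=False)
    manifest["counts"]["triplets"] = len(screened)

    # --- descriptive ---------------------------------------------------------
    case_demo = [d for d in demo_all
                 if d.primaryid in case_ids]
    summary = descriptive_table(case_demo, tto_summary) if case_demo else None
    if summary:
        summary.to_frame().to_csv(out / "descriptive.csv", index=False)
    else:
        warnings.append("no cases; descriptive table skipped")

    # --- sensitivity ---------------------------------------------------------
    occ = config.get("sensitivity_occupation", "LW")
    diff = sensitivity_exclude(occ, demo_all, retained, reac, drugs, norm,
                               query, roles)
    diff.deltas.to_csv(out / "sensitivity.csv", index=False)
    manifest["sensitivity"] = {
        "occupation": occ,
        "baseline_positive": sorted(diff.baseline_positive),
        "filtered_positive": sorted(diff.filtered_positive),
        "gained": sorted(diff.gained),
        "lost": sorted(diff.lost),
    }

    manifest["warnings"] = warnings
    manifest["positive_drugs"] = sorted(
        r.drug for r in results if r.positive)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return out
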