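"""Synthetic spontaneous-report generator with a known ground truth.

Emulates the structure of FAERS quarterly data at desk scale so every
downstream stage — deduplication, case definition, disproportionality,
time-to-onset and interaction screening — can be tested against a ledger
of injected truth:

* multi-drug reports with per-drug marginal frequencies;
* a target event whose probability follows an odds model: baseline odds
  times the product of per-drug odds multipliers of the drugs on the
  report, times an extra multiplier for configured drug pairs
  (interaction triplets), capped below 1.  Injected effects live on the
  odds scale so they are directly comparable to the reporting odds ratio
  the pipeline estimates;
* drug-specific time-to-onset distributions (exponential, Weibull or
  log-normal) parameterized by their median in days;
* duplicate report versions sharing a CASEID with strictly increasing
  receipt dates, and quarterly deletion lists;
* a reporter-occupation mix including a lawyer stratum whose reporting
  volume can be inflated per drug (litigation-driven reporting bias);
* missing dates at a configurable per-field rate.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np

from .faers_io import (
    DemoRecord, DrugRecord, MISSING_DATE, ReactionRecord,
    ReportBundle, TherapyRecord, date_from_ordinal, parse_date,
)

logger = logging.getLogger("dystosignal")

DEFAULT_OCCUPATION_MIX = {
    "MD": 0.22, "PH": 0.13, "LW": 0.05, "CN": 0.21, "HP": 0.15, "OT": 0.24,
}


@dataclass
class DrugSpec:
    """One catalog drug: marginal presence probability, role mix, ATC."""

    name: str
    marginal: float
    ss_prob: float = 1.0   # P(role=SS) for non-primary-suspect rows; else C
    atc: str = ""


@dataclass
class TTOModel:
    """Onset-time distribution for one drug, parameterized by its median.

    ``family`` is exponential, weibull or lognormal; ``shape`` is the
    Weibull shape or the log-normal sigma (ignored for exponential).
    """

    family: str = "exponential"
    median: float = 30.0
    shape: float = 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "exponential":
            scale = self.median / math.log(2.0)
            draws = rng.exponential(scale, size)
        elif self.family == "weibull":
            scale = self.median / math.log(2.0) ** (1.0 / self.shape)
            draws = scale * rng.weibull(self.shape, size)
        elif self.family == "lognormal":
            draws = rng.lognormal(math.log(self.median), self.shape, size)
        else:
            raise ValueError(f"unknown TTO family {self.family!r}")
        return np.floor(draws).astype(int)


@dataclass
class SynthConfig:
    n_cases: int = 1000
    drug_catalog: List[DrugSpec] = field(default_factory=list)
    pt_catalog: List[Tuple[str, float]] = field(default_factory=list)
    target_event_pts: List[str] = field(default_factory=list)
    signal_pairs: Dict[str, float] = field(default_factory=dict)
    interaction_triplets: List[Tuple[str, str, float]] = field(default_factory=list)
    tto_models: Dict[str, TTOModel] = field(default_factory=dict)
    duplicate_rate: float = 0.1
    deletion_rate: float = 0.02
    occupation_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPATION_MIX))
    lawyer_bias: Dict[str, float] = field(default_factory=dict)
    missing_date_rate: float = 0.55
    date_window: Tuple[str, str] = ("20190101", "20231231")
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not self.drug_catalog:
            raise ValueError("drug_catalog is empty")
        for d in self.drug_catalog:
            if not 0.0 <= d.marginal <= 1.0:
                raise ValueError(f"marginal out of [0,1] for {d.name}")
        for m in self.signal_pairs.values():
            if m <= 0:
                raise ValueError("odds multipliers must be > 0")
        for _, _, m in self.interaction_triplets:
            if m <= 0:
                raise ValueError("interaction multipliers must be > 0")
        for model in self.tto_models.values():
            if model.median <= 0:
                raise ValueError("TTO medians must be > 0")
        targets = set(self.target_event_pts)
        known = {name for name, _ in self.pt_catalog}
        if not targets or not targets <= known:
            raise ValueError("target_event_pts must be a non-empty subset "
                             "of pt_catalog")
        if not (known - targets):
            raise ValueError("pt_catalog needs at least one non-target PT")


@dataclass
class CaseTruth:
    """Ground truth for one synthetic case."""

    caseid: str
    versions: List[Tuple[str, int]]          # (primaryid, fda ordinal)
    deleted: bool
    event: bool
    drugs: List[str]                         # all drugs present
    suspects: List[str]                      # drugs with role PS or SS
    primary: str                             # the single PS drug
    occupation: str
    tto_days: Dict[str, int]                 # drawn onset per suspect drug
    event_date_missing: bool
    start_missing: Dict[str, bool]


@dataclass
class TruthLedger:
    drug_effects: Dict[str, float]
    drug_tto_median: Dict[str, float]
    triplet_effects: Dict[str, float]        # "drugA|drugB" -> excess mult
    target_event_pts: List[str]
    capped_fraction: float
    cases: Dict[str, CaseTruth]

    def primaryids(self) -> list:
        return [pid for c in self.cases.values() for pid, _ in c.versions]

    def last_version(self, caseid: str) -> str:
        return self.cases[caseid].versions[-1][0]

    def to_json(self, path) -> None:
        payload = {
            "drug_effects": self.drug_effects,
            "drug_tto_median": self.drug_tto_median,
            "triplet_effects": self.triplet_effects,
            "target_event_pts": self.target_event_pts,
            "capped_fraction": self.capped_fraction,
            "cases": {cid: asdict(c) for cid, c in self.cases.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def default_config(n_cases: int = 5000, seed: int = 0) -> SynthConfig:
    """Demo configuration shaped like the dystonia study's headline drugs.

    Marginals, odds multipliers and onset medians echo the relative
    pattern of the real analysis (a dominant antiemetic with heavy
    lawyer-driven reporting volume, several antipsychotics with strong
    signals and short onset, plus null background drugs), scaled to desk
    size.
    """
    catalog = [
        DrugSpec("metoclopramide", 0.06, atc="A03FA01"),
        DrugSpec("aripiprazole", 0.04, atc="N05AX12"),
        DrugSpec("risperidone", 0.04, atc="N05AX08"),
        DrugSpec("quetiapine", 0.03, atc="N05AH04"),
        DrugSpec("olanzapine", 0.03, atc="N05AH03"),
        DrugSpec("haloperidol", 0.02, atc="N05AD01"),
        DrugSpec("ibuprofen", 0.08, atc="M01AE01"),
        DrugSpec("metformin", 0.08, atc="A10BA02"),
        DrugSpec("omeprazole", 0.06, atc="A02BC01"),
        DrugSpec("lisinopril", 0.06, atc="C09AA03"),
    ]
    pts = [
        ("dystonia", 0.030), ("torticollis", 0.010),
        ("oromandibular dystonia", 0.005),
        ("nausea", 0.30), ("headache", 0.25), ("dizziness", 0.20),
        ("fatigue", 0.20),
    ]
    return SynthConfig(
        n_cases=n_cases,
        drug_catalog=catalog,
        pt_catalog=pts,
        target_event_pts=["dystonia", "torticollis", "oromandibular dystonia"],
        signal_pairs={
            "metoclopramide": 20.0, "aripiprazole": 8.0, "risperidone": 8.0,
            "quetiapine": 4.0, "olanzapine": 5.0, "haloperidol": 12.0,
        },
        interaction_triplets=[("aripiprazole", "risperidone", 3.0)],
        tto_models={
            "metoclopramide": TTOModel("lognormal", 2.0, 1.2),
            "aripiprazole": TTOModel("lognormal", 5.0, 1.2),
            "risperidone": TTOModel("lognormal", 2.0, 1.2),
            "quetiapine": TTOModel("lognormal", 19.0, 1.0),
            "olanzapine": TTOModel("lognormal", 16.0, 1.0),
            "haloperidol": TTOModel("exponential", 3.0),
        },
        lawyer_bias={"metoclopramide": 3.0},
        seed=seed,
    )


def _quarter_label(ordinal: int) -> str:
    d = date_from_ordinal(ordinal)
    year, month = int(d.raw[:4]), int(d.raw[4:6])
    return f"{year}Q{(month - 1) // 3 + 1}"


def simulate(config: SynthConfig) -> tuple:
    """Generate quarterly ReportBundles plus the matching TruthLedger."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = config.drug_catalog
    nd = len(drugs)
    names = [d.name for d in drugs]
    idx = {name: i for i, name in enumerate(names)}

    # --- drug presence -----------------------------------------------------
    marginals = np.array([d.marginal for d in drugs])
    presence = rng.random((n, nd)) < marginals
    none_rows = np.flatnonzero(~presence.any(axis=1))
    if none_rows.size:
        weights = marginals / marginals.sum()
        forced = rng.choice(nd, size=none_rows.size, p=weights)
        presence[none_rows, forced] = True
    heavy = np.flatnonzero(presence.sum(axis=1) > 5)
    for row in heavy:
        on = np.flatnonzero(presence[row])
        keep = rng.choice(on, size=5, replace=False)
        presence[row] = False
        presence[row, keep] = True

    # --- event indicator (odds model) --------------------------------------
    target_pts = [p for p in config.pt_catalog if p[0] in set(config.target_event_pts)]
    other_pts = [p for p in config.pt_catalog if p[0] not in set(config.target_event_pts)]
    p0 = min(sum(w for _, w in target_pts), 0.95)
    log_odds = np.full(n, math.log(p0 / (1.0 - p0)))
    log_mult = np.zeros(nd)
    for name, m in config.signal_pairs.items():
        log_mult[idx[name]] = math.log(m)
    log_odds += presence @ log_mult
    for da, db, excess in config.interaction_triplets:
        both = presence[:, idx[da]] & presence[:, idx[db]]
        log_odds[both] += math.log(excess)
    p_event = 1.0 / (1.0 + np.exp(-log_odds))
    capped = p_event > 0.99
    p_event = np.minimum(p_event, 0.99)
    capped_fraction = float(capped.mean())
    if capped_fraction > 0.05:
        logger.warning(
            "event-probability cap hit on %.1f%% of cases; "
            "config multipliers may be too extreme", 100 * capped_fraction)
    event = rng.random(n) < p_event

    # --- occupations --------------------------------------------------------
    occ_codes = list(config.occupation_mix)
    occ_probs = np.array([config.occupation_mix[c] for c in occ_codes], dtype=float)
    occ_probs = occ_probs / occ_probs.sum()
    occupations = rng.choice(occ_codes, size=n, p=occ_probs)

    # --- lawyer-bias volume inflation ---------------------------------------
    # extra event reports attributed to lawyers for each biased drug
    extra_specs: list = []     # (drug index,) one entry per extra report
    for name, bias in config.lawyer_bias.items():
        if bias <= 1.0:
            continue
        base_volume = int(np.sum(event & presence[:, idx[name]]))
        n_extra = rng.poisson((bias - 1.0) * base_volume)
        extra_specs.extend([idx[name]] * int(n_extra))

    # --- assemble reports ----------------------------------------------------
    start_ord = parse_date(config.date_window[0]).ordinal
    end_ord = parse_date(config.date_window[1]).ordinal
    if start_ord is None or end_ord is None or end_ord < start_ord:
        raise ValueError("date_window must be two valid YYYYMMDD dates")

    target_names = [name for name, _ in target_pts]
    target_w = np.array([w for _, w in target_pts], dtype=float)
    target_w /= target_w.sum()
    other_names = [name for name, _ in other_pts]
    other_w = np.array([w for _, w in other_pts], dtype=float)
    other_w /= other_w.sum()

    bundles: Dict[str, ReportBundle] = {}
    cases: Dict[str, CaseTruth] = {}

    def bundle_for(ordinal: int) -> ReportBundle:
        label = _quarter_label(ordinal)
        if label not in bundles:
            bundles[label] = ReportBundle(quarter=label)
        return bundles[label]

    def emit_case(i_case: int, drug_idx: list, is_event: bool, occ: str) -> None:
        caseid = str(100000 + i_case)
        present = [names[j] for j in drug_idx]
        primary_pos = int(rng.integers(len(drug_idx)))
        primary = present[primary_pos]
        roles = {}
        suspects = []
        for pos, name in enumerate(present):
            if pos == primary_pos:
                roles[name] = "PS"
                suspects.append(name)
            else:
                spec = drugs[idx[name]]
                if rng.random() < spec.ss_prob:
                    roles[name] = "SS"
                    suspects.append(name)
                else:
                    roles[name] = "C"

        # onset times per drug and calendar anchoring on the primary suspect
        tto: Dict[str, int] = {}
        for name in present:
            model = config.tto_models.get(name, TTOModel())
            tto[name] = int(model.sample(rng, 1)[0])
        anchor_start = int(rng.integers(start_ord, end_ord + 1))
        if is_event:
            event_ord = anchor_start + tto[primary]
        else:
            event_ord = anchor_start + int(rng.exponential(30.0))
        starts = {primary: anchor_start}
        for name in present:
            if name != primary:
                starts[name] = event_ord - tto[name]
        fda_ord = event_ord + int(rng.geometric(1.0 / 30.0))

        event_missing = bool(rng.random() < config.missing_date_rate)
        start_missing = {
            name: bool(rng.random() < config.missing_date_rate)
            for name in present
        }

        # duplicate versions
        n_versions = 1
        if rng.random() < config.duplicate_rate:
            n_versions += int(rng.geometric(0.5))
        fda_ords = [fda_ord]
        for _ in range(n_versions - 1):
            fda_ords.append(fda_ords[-1] + int(rng.geometric(1.0 / 20.0)))

        if is_event:
            pt = target_names[int(rng.choice(len(target_names), p=target_w))]
        else:
            pt = other_names[int(rng.choice(len(other_names), p=other_w))]

        sex = "F" if rng.random() < 0.55 else "M"
        age = float(int(rng.integers(5, 90)))
        country = "US" if rng.random() < 0.6 else "GB"
        outcome = frozenset({"HO"}) if (is_event and rng.random() < 0.33) else frozenset()

        versions = []
        for v, f_ord in enumerate(fda_ords, start=1):
            pid = f"{caseid}{v:02d}"
            versions.append((pid, f_ord))
            b = bundle_for(f_ord)
            b.demo.append(DemoRecord(
                primaryid=pid, caseid=caseid,
                fda_dt=date_from_ordinal(f_ord),
                event_dt=(MISSING_DATE if event_missing
                          else date_from_ordinal(event_ord)),
                sex=sex, age_value=age, age_unit="YR",
                occp_cod=occ, reporter_country=country,
                outcome_codes=outcome,
            ))
            for seq, name in enumerate(present, start=1):
                b.drug.append(DrugRecord(
                    primaryid=pid, drug_seq=seq, role=roles[name],
                    verbatim_name=name.upper(), active_ingredient=name,
                ))
                b.ther.append(TherapyRecord(
                    primaryid=pid, drug_seq=seq,
                    start_dt=(MISSING_DATE if start_missing[name]
                              else date_from_ordinal(starts[name])),
                    end_dt=MISSING_DATE,
                ))
            b.reac.append(ReactionRecord(primaryid=pid, pt=pt.capitalize()))

        deleted = bool(rng.random() < config.deletion_rate)
        if deleted:
            bundle_for(fda_ords[-1]).deletion_caseids.add(caseid)

        cases[caseid] = CaseTruth(
            caseid=caseid, versions=versions, deleted=deleted,
            event=is_event, drugs=sorted(present), suspects=sorted(suspects),
            primary=primary, occupation=occ,
            tto_days={d: tto[d] for d in suspects},
            event_date_missing=event_missing,
            start_missing=start_missing,
        )

    for i in range(n):
        drug_idx = list(np.flatnonzero(presence[i]))
        emit_case(i, drug_idx, bool(event[i]), str(occupations[i]))
    for k, j in enumerate(extra_specs):
        emit_case(n + k, [j], True, "LW")

    ledger = TruthLedger(
        drug_effects={name: config.signal_pairs.get(name, 1.0) for name in names},
        drug_tto_median={
            name: config.tto_models.get(name, TTOModel()).median for name in names
        },
        triplet_effects={f"{a}|{b}": m for a, b, m in config.interaction_triplets},
        target_event_pts=list(config.target_event_pts),
        capped_fraction=capped_fraction,
        cases=cases,
    )
    ordered = [bundles[q] for q in sorted(bundles)]
    return ordered, ledger


def truth_check(bundles: list, ledger: TruthLedger) -> dict:
    """Consistency checks between emitted bundles and the truth ledger."""
    checks: Dict[str, bool] = {}

    emitted = [d.primaryid for b in bundles for d in b.demo]
    ledger_pids = ledger.primaryids()
    checks["primaryids_match"] = sorted(emitted) == sorted(ledger_pids)
    checks["primaryids_unique"] = len(set(emitted)) == len(emitted)

    checks["versions_increasing"] = all(
        all(b[1] > a[1] for a, b in zip(c.versions, c.versions[1:]))
        for c in ledger.cases.values()
    )

    deletion_union: set = set()
    for b in bundles:
        deletion_union |= set(b.deletion_caseids)
    ledger_deleted = {cid for cid, c in ledger.cases.items() if c.deleted}
    checks["deletions_match"] = deletion_union == ledger_deleted

    target = {p.lower() for p in ledger.target_event_pts}
    pts_by_pid: dict = {}
    for b in bundles:
        for r in b.reac:
            pts_by_pid.setdefault(r.primaryid, set()).add(r.pt.lower())
    checks["event_flags_match"] = all(
        c.event == any(
            pt in target for pid, _ in c.versions for pt in pts_by_pid.get(pid, ())
        )
        for c in ledger.cases.values()
    )

    checks["pass"] = all(checks.values())
    return checks
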