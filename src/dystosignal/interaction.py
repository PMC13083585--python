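"""Drug-drug interaction screening with the omega shrinkage measure.

For an unordered drug pair (A, B) and a target event, reports are split
into four exposure strata: both drugs, A only, B only, neither.  The
observed event count among both-drug reports (n111) is compared with its
expectation E111 under a no-interaction baseline built from the event
proportions f10, f01, f00 in the single-drug and no-drug strata:

    omega     = log2[(n111 + 0.5) / (E111 + 0.5)]
    omega025  = omega - z / (ln 2 * sqrt(n111)),   z = 1.96

The +0.5 shrinkage stabilizes small counts; an interaction signal is
flagged when omega025 > 0.  The baseline model for E111 is pluggable
because more than one convention exists in the surveillance literature:

* ``odds_additive`` (default): expected odds among both-drug reports is
  odds(f10) + odds(f01) - odds(f00), floored at the larger single-drug
  odds — excess risk adds on the odds scale;
* ``multiplicative``: 1 - g111 = (1-f10)(1-f01)/(1-f00), relative risks
  multiply;
* ``max_single``: g111 = max(f10, f01), no synergy at all;
* ``odds_multiplicative``: odds(g111) = odds(f10)*odds(f01)/odds(f00),
  single-drug effects compose multiplicatively on the odds scale (the
  same composition the bundled synthetic generator uses, which makes it
  the matched null baseline in generator-driven calibration tests).

Degenerate strata (an empty denominator, or a proportion of 1 that makes
an odds infinite) fall back to the next simpler model, and the model
actually used is recorded per triplet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional

E111_MODELS = ("odds_multiplicative", "odds_additive", "multiplicative",
               "max_single")


@dataclass
class TripletSignal:
    drugA: str
    drugB: str
    n111: int
    n11plus: int
    f10: Optional[float]
    f01: Optional[float]
    f00: Optional[float]
    e111: float = math.nan
    model_used: str = ""
    omega: float = math.nan
    omega025: float = math.nan
    omega975: float = math.nan
    flag: bool = False


def count_triplets(
    all_retained: set, drug_exposure: dict, case_ids: set, min_n111: int = 1
) -> list:
    """Stratum counts for every drug pair with >= min_n111 event reports.

    Counting is at report level; each report lands in exactly one stratum
    per pair (both / A only / B only / neither).
    """
    if min_n111 < 1:
        raise ValueError("min_n111 must be >= 1")
    exposed: Dict[str, set] = {}
    for pid, drugs in drug_exposure.items():
        if pid in all_retained:
            for d in drugs:
                exposed.setdefault(d, set()).add(pid)
    cases = case_ids & all_retained
    n_total = len(all_retained)

    # pairs observed together on event reports, with their n111
    pair_events: Dict[tuple, int] = {}
    for pid in cases:
        drugs = sorted(drug_exposure.get(pid, ()))
        for pair in combinations(drugs, 2):
            pair_events[pair] = pair_events.get(pair, 0) + 1

    out = []
    for (da, db), n111 in sorted(pair_events.items()):
        if n111 < min_n111:
            continue
        ea, eb = exposed[da], exposed[db]
        both = ea & eb
        n11plus = len(both)
        n_a_only = len(ea) - n11plus
        n_b_only = len(eb) - n11plus
        n_neither = n_total - len(ea) - len(eb) + n11plus
        ev_a = len(ea & cases)
        ev_b = len(eb & cases)
        ev_a_only = ev_a - n111
        ev_b_only = ev_b - n111
        ev_neither = len(cases) - ev_a - ev_b + n111
        out.append(
            TripletSignal(
                drugA=da, drugB=db, n111=n111, n11plus=n11plus,
                f10=ev_a_only / n_a_only if n_a_only else None,
                f01=ev_b_only / n_b_only if n_b_only else None,
                f00=ev_neither / n_neither if n_neither else None,
            )
        )
    return out


def _odds(p: float) -> float:
    return p / (1.0 - p)


def expected_e111(t: TripletSignal, model: str = "odds_additive") -> float:
    """Expected event count among both-drug reports under no interaction.

    Falls back odds_additive -> multiplicative -> max_single when a
    stratum needed by the model is degenerate; records ``model_used`` on
    the triplet.  Raises on n11plus = 0 (the triplet is undefined).
    """
    if model not in E111_MODELS:
        raise ValueError(f"unknown E111 model {model!r}")
    if t.n11plus == 0:
        raise ValueError("E111 undefined for n11plus = 0")
    order = E111_MODELS[E111_MODELS.index(model):]
    for m in order:
        g = _g111(t, m)
        if g is not None:
            t.model_used = m
            t.e111 = g * t.n11plus
            return t.e111
    # max_single with no single-drug stratum at all: fall back to f00
    g = t.f00 if t.f00 is not None else 0.0
    t.model_used = "background"
    t.e111 = g * t.n11plus
    return t.e111


def _g111(t: TripletSignal, model: str) -> Optional[float]:
    f10, f01, f00 = t.f10, t.f01, t.f00
    if model == "odds_multiplicative":
        if None in (f10, f01, f00) or 1.0 in (f10, f01, f00) or f00 == 0.0:
            return None
        odds = _odds(f10) * _odds(f01) / _odds(f00)
        odds = max(odds, _odds(f10), _odds(f01))
        return odds / (1.0 + odds)
    if model == "odds_additive":
        if None in (f10, f01, f00) or 1.0 in (f10, f01, f00):
            return None
        odds = _odds(f10) + _odds(f01) - _odds(f00)
        odds = max(odds, _odds(f10), _odds(f01))
        return odds / (1.0 + odds)
    if model == "multiplicative":
        if None in (f10, f01, f00) or f00 == 1.0:
            return None
        g = 1.0 - (1.0 - f10) * (1.0 - f01) / (1.0 - f00)
        return min(max(g, f10, f01), 1.0)
    if model == "max_single":
        candidates = [f for f in (f10, f01) if f is not None]
        return max(candidates) if candidates else None
    return None


def omega_stat(n111: int, e111: float, z: float = 1.96) -> tuple:
    """Omega point estimate with symmetric 95% bounds.

    Half-width is z / (ln 2 * sqrt(n111)); for n111 = 0 the bounds are
    undefined (NaN) and only the point estimate is reported.
    """
    if n111 < 0 or e111 < 0:
        raise ValueError("counts must be non-negative")
    omega = math.log2((n111 + 0.5) / (e111 + 0.5))
    if n111 == 0:
        return omega, math.nan, math.nan
    hw = z / (math.log(2.0) * math.sqrt(n111))
    return omega, omega - hw, omega + hw


def screen_interactions(
    triplets: list, model: str = "odds_additive", min_n111: int = 1
) -> list:
    """Compute E111 and omega for each triplet, flag and rank.

    Ranking follows the presentation convention for interaction tables:
    n111 descending, ties by omega descending.  The signal flag is
    omega025 > 0.  Triplets with n11plus = 0 are dropped.
    """
    scored = []
    for t in triplets:
        if t.n11plus == 0 or t.n111 < min_n111:
            continue
        expected_e111(t, model=model)
        t.omega, t.omega025, t.omega975 = omega_stat(t.n111, t.e111)
        t.flag = (not math.isnan(t.omega025)) and t.omega025 > 0.0
        scored.append(t)
    return sorted(scored, key=lambda t: (-t.n111, -t.omega, t.drugA, t.drugB))
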