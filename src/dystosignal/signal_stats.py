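"""Disproportionality statistics: ROR, PRR, BCPNN and MGPS.

All four algorithms compare the observed co-reporting count ``a`` of a
drug-event pair with its expectation under independence in the same 2x2
table:

* ROR  = (a*d)/(b*c) with a Woolf log-normal 95% CI;
* PRR  = [a/(a+b)] / [c/(c+d)] with the uncorrected Pearson chi-square;
* BCPNN information component IC = log2[(a+0.5)/(aexp+0.5)],
  aexp = (a+b)(a+c)/N, with the closed-form lower credibility bound
  IC025 = IC - 3.3*(a+0.5)^-1/2 - 2*(a+0.5)^-3/2;
* MGPS empirical-Bayes geometric mean taken here as the relative
  reporting ratio EBGM = a*N/[(a+c)(a+b)] with a normal-approximation
  lower bound EBGM05 = exp(ln EBGM - 1.64*sqrt(1/a+1/b+1/c+1/d)).

A drug is flagged positive only when all four algorithms meet their
thresholds simultaneously (a >= 3 plus ROR lower CI > 1; PRR >= 2 and
chi2 >= 4; IC025 > 0; EBGM05 > 2) — a deliberately conservative
conjunction that suppresses method-specific false positives.

Zero cells: the Haldane-Anscombe correction (+0.5 to every cell) is
applied, only when a zero cell occurs, before computing ROR/PRR/MGPS;
the a >= 3 gate makes this rare in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .case_mapping import ContingencyTable

__all__ = [
    "SignalResult", "ror_stat", "prr_stat", "bcpnn_stat", "mgps_stat",
    "evaluate_signal", "rank_drugs", "signal_table",
]


@dataclass
class SignalResult:
    drug: str
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    aexp: float
    ebgm: float
    ebgm05: float
    flag_ror: bool
    flag_prr: bool
    flag_bcpnn: bool
    flag_mgps: bool
    positive: bool
    corrected: bool = False


def _log_ci_halfwidth(a: float, b: float, c: float, d: float, z: float) -> float:
    return z * math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def ror_stat(t: ContingencyTable, z: float = 1.96) -> tuple:
    """Reporting odds ratio with its log-normal (Woolf) CI.

    Requires strictly positive cells; ``evaluate_signal`` applies the
    zero-cell correction before calling.
    """
    a, b, c, d = (float(x) for x in t.cells)
    ror = (a * d) / (b * c)
    hw = _log_ci_halfwidth(a, b, c, d, z)
    return ror, ror * math.exp(-hw), ror * math.exp(hw)


def prr_stat(t: ContingencyTable) -> tuple:
    """Proportional reporting ratio and uncorrected Pearson chi-square."""
    a, b, c, d = (float(x) for x in t.cells)
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def bcpnn_stat(t: ContingencyTable) -> tuple:
    """Information component and its closed-form lower 95% bound.

    Returns ``(ic, ic025, aexp)``.  Well defined for zero cells thanks to
    the +0.5 shrinkage.
    """
    a, b, c, d = (float(x) for x in t.cells)
    n = a + b + c + d
    aexp = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (aexp + 0.5))
    s = a + 0.5
    ic025 = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
    return ic, ic025, aexp


def mgps_stat(t: ContingencyTable, z: float = 1.64) -> tuple:
    """Relative-reporting-ratio EBGM with normal-approximation lower bound."""
    a, b, c, d = (float(x) for x in t.cells)
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    hw = _log_ci_halfwidth(a, b, c, d, z)
    return ebgm, ebgm * math.exp(-hw)


def evaluate_signal(t: ContingencyTable) -> SignalResult:
    """All four statistics, per-algorithm flags and the combined verdict."""
    corrected = min(t.cells) == 0
    # Haldane-Anscombe: shift every cell by 0.5 for the ratio statistics
    work = _Shifted(t) if corrected else t

    ror, ror_lo, ror_hi = ror_stat(work)
    prr, chi2 = prr_stat(work)
    ic, ic025, aexp = bcpnn_stat(t)  # IC handles zeros natively
    ebgm, ebgm05 = mgps_stat(work)

    a = t.a
    flag_ror = a >= 3 and ror_lo > 1.0
    flag_prr = a >= 3 and prr >= 2.0 and chi2 >= 4.0
    flag_bcpnn = a >= 3 and ic025 > 0.0
    flag_mgps = a >= 3 and ebgm05 > 2.0
    return SignalResult(
        drug=t.drug, a=a,
        ror=ror, ror_lo=ror_lo, ror_hi=ror_hi,
        prr=prr, chi2=chi2,
        ic=ic, ic025=ic025, aexp=aexp,
        ebgm=ebgm, ebgm05=ebgm05,
        flag_ror=flag_ror, flag_prr=flag_prr,
        flag_bcpnn=flag_bcpnn, flag_mgps=flag_mgps,
        positive=flag_ror and flag_prr and flag_bcpnn and flag_mgps,
        corrected=corrected,
    )


class _Shifted:
    """View of a table with +0.5 on every cell (zero-cell correction)."""

    def __init__(self, t: ContingencyTable):
        self.cells = tuple(x + 0.5 for x in t.cells)
        self.drug = t.drug


def rank_drugs(results: list, by: str = "case_count") -> list:
    """Stable descending sort by case count or ROR; ties alphabetical."""
    if by == "case_count":
        key = lambda r: (-r.a, r.drug)
    elif by == "ror":
        key = lambda r: (-r.ror, r.drug)
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    return sorted(results, key=key)


def signal_table(contingencies: dict, by: str = "case_count") -> list:
    """Evaluate and rank every drug's table."""
    return rank_drugs([evaluate_signal(t) for t in contingencies.values()], by=by)
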