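"""Case definition, drug normalization and 2x2 contingency construction.

Cases are defined by a preferred-term (PT) query — typically the narrow
scope of a standardized MedDRA query, which favors specificity — matched
case-insensitively after whitespace normalization.  Drug names are
canonicalized through a user-supplied synonym table (MedDRA and the WHO
Drug Dictionary are licensed, so the mappings travel as plain CSV), with
an optional ATC class per canonical name.

The counting unit throughout is the retained (post-deduplication) report:
a report with three matching PTs is one case; a report naming a drug twice
contributes one exposure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Set


def normalize_pt(text: str) -> str:
    """Whitespace-collapse and lowercase a preferred term for matching."""
    return " ".join(text.split()).lower()


@dataclass
class PTQuery:
    """A named PT set with a scope label (narrow or broad)."""

    name: str
    scope: str
    pts: Set[str]

    def __post_init__(self):
        self.pts = {normalize_pt(p) for p in self.pts if p.strip()}
        if not self.pts:
            raise ValueError(f"PT query {self.name!r} is empty")

    def matches(self, pt: str) -> bool:
        return normalize_pt(pt) in self.pts


def load_pt_query(path, name: str = "", scope: str = "narrow") -> PTQuery:
    """Load a PT query from a text or CSV file.

    Accepts one PT per line, or CSV rows with columns ``pt[,code,scope]``
    (header optional).  PTs are deduplicated case-insensitively.  When a
    ``scope`` column is present, only rows matching ``scope`` are kept
    unless that would empty the set (then all rows are kept).
    """
    path = Path(path)
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if row and any(cell.strip() for cell in row):
                rows.append([cell.strip() for cell in row])
    if not rows:
        raise ValueError(f"empty PT query file: {path}")
    header = [c.lower() for c in rows[0]]
    pt_col, scope_col = 0, None
    if "pt" in header:
        pt_col = header.index("pt")
        scope_col = header.index("scope") if "scope" in header else None
        rows = rows[1:]
    pts = []
    for row in rows:
        if scope_col is not None and len(row) > scope_col:
            if row[scope_col].lower() not in ("", scope.lower()):
                continue
        if len(row) > pt_col:
            pts.append(row[pt_col])
    if not pts:  # scope filter emptied the set; fall back to all rows
        pts = [row[pt_col] for row in rows if len(row) > pt_col]
    return PTQuery(name=name or path.stem, scope=scope, pts=set(pts))


@dataclass
class DrugNormalizer:
    """Verbatim-to-canonical drug name mapping with optional ATC classes."""

    mapping: Dict[str, str] = field(default_factory=dict)
    atc: Dict[str, str] = field(default_factory=dict)
    unmapped: list = field(default_factory=list)

    def __post_init__(self):
        self.mapping = {
            " ".join(k.split()).lower(): " ".join(v.split()).lower()
            for k, v in self.mapping.items()
        }

    @classmethod
    def from_csv(cls, path) -> "DrugNormalizer":
        """Read a ``verbatim,canonical[,atc]`` CSV (header optional)."""
        mapping: Dict[str, str] = {}
        atc: Dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if len(row) < 2 or not row[0].strip():
                    continue
                if row[0].strip().lower() == "verbatim":
                    continue
                canonical = " ".join(row[1].split()).lower()
                mapping[" ".join(row[0].split()).lower()] = canonical
                if len(row) > 2 and row[2].strip():
                    atc[canonical] = row[2].strip().upper()
        return cls(mapping=mapping, atc=atc)

    @classmethod
    def identity(cls, names: Iterable[str]) -> "DrugNormalizer":
        """Normalizer that maps each name (any casing) to itself."""
        return cls(mapping={n: n for n in names})

    def canonical(self, verbatim: str) -> Optional[str]:
        key = " ".join(verbatim.split()).lower()
        if key in self.mapping:
            return self.mapping[key]
        self.unmapped.append(verbatim)
        return None


def flag_cases(reac: list, retained: set, query: PTQuery) -> set:
    """Return the retained primaryids with at least one PT in the query."""
    pts = query.pts
    return {
        r.primaryid
        for r in reac
        if r.primaryid in retained and normalize_pt(r.pt) in pts
    }


def normalize_drugs(
    drug: list,
    norm: DrugNormalizer,
    roles: set = frozenset({"PS"}),
    retained: Optional[set] = None,
) -> dict:
    """Map each report to its set of canonical drug names.

    Only drug rows whose role is in ``roles`` contribute (default: primary
    suspect only, the strictest reading of "highest suspicion").  Unmapped
    verbatim names are routed to ``norm.unmapped`` and excluded.
    """
    exposure: dict = {}
    for rec in drug:
        if rec.role not in roles:
            continue
        if retained is not None and rec.primaryid not in retained:
            continue
        name = norm.canonical(rec.verbatim_name or rec.active_ingredient)
        if name is None:
            continue
        exposure.setdefault(rec.primaryid, set()).add(name)
    return exposure


@dataclass
class ContingencyTable:
    """Report-level a/b/c/d counts for one drug-event pair.

    a: drug and event; b: drug, no event; c: event, no drug; d: neither.
    """

    a: int
    b: int
    c: int
    d: int
    drug: str = ""

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


def build_contingency(
    case_ids: set, drug_exposure: dict, all_retained: set, drug: str
) -> ContingencyTable:
    """2x2 table for one canonical drug over the retained report set."""
    exposed = {pid for pid, drugs in drug_exposure.items() if drug in drugs}
    exposed &= all_retained
    cases = case_ids & all_retained
    a = len(exposed & cases)
    b = len(exposed - cases)
    c = len(cases - exposed)
    d = len(all_retained) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d, drug=drug)


def build_all_contingencies(
    case_ids: set, drug_exposure: dict, all_retained: set
) -> dict:
    """Tables for every canonical drug appearing in the exposure map."""
    drugs: set = set()
    for pids_drugs in drug_exposure.values():
        drugs |= pids_drugs
    return {
        d: build_contingency(case_ids, drug_exposure, all_retained, d)
        for d in sorted(drugs)
    }
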