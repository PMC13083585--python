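"""Reading and writing FAERS-style quarterly ASCII bundles.

FAERS distributes each quarter as a set of dollar-delimited text tables
(DEMO, DRUG, REAC, THER, OUTC) plus, from 2019 Q1 onward, a deletion list of
CASEIDs whose reports must be dropped.  This module parses those tables into
typed records with tolerant date handling: dates in spontaneous reports are
frequently partial (``YYYY`` or ``YYYYMM``) or calendar-invalid, and the
parser never raises — invalidity is encoded in the :class:`DateValue`
precision so that downstream exclusion rules, not imputation, decide what to
do with them.

Column names follow the post-2012 FAERS ASCII dialect (``primaryid``,
``caseid``, ``fda_dt``, ``occp_cod``, ``role_cod``, ``drugname``,
``prod_ai``, ``start_dt``, ``end_dt``, ``outc_cod``).
"""

from __future__ import annotations

import datetime
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger("dystosignal")

DELIMITER = "$"

SEX_CODES = {"F", "M"}
OCCUPATION_CODES = {"MD", "PH", "LW", "CN", "HP", "OT"}
OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI", "OT"}
DRUG_ROLES = {"PS", "SS", "C", "I"}

#: module-level tally of calendar-invalid 8-digit date strings seen by
#: :func:`parse_date`; callers may also pass their own Counter.
invalid_date_counter: Counter = Counter()


# ---------------------------------------------------------------------------
# dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DateValue:
    """A FAERS date field with explicit precision.

    ``precision`` is one of ``day``, ``month``, ``year`` or ``missing``;
    ``ordinal`` (proleptic-Gregorian day count) is defined only at day
    precision, which makes comparison between two day-precision values total.
    """

    raw: str
    precision: str
    ordinal: Optional[int] = None

    @property
    def is_day(self) -> bool:
        return self.precision == "day"

    def sort_key(self) -> tuple:
        """Ordering key: any day-precision date sorts above all partial or
        missing dates (which compare equal among themselves)."""
        if self.is_day:
            return (1, self.ordinal)
        return (0, 0)


MISSING_DATE = DateValue(raw="", precision="missing")


def parse_date(raw: str, counter: Optional[Counter] = None) -> DateValue:
    """Parse a FAERS date string into a :class:`DateValue`.  Total function.

    Accepts empty strings, partial dates (``YYYY``, ``YYYYMM``) and full
    ``YYYYMMDD``.  Calendar-invalid 8-digit strings (month 13, day 32, ...)
    map to ``missing`` and bump a warning counter rather than raising.
    """
    if counter is None:
        counter = invalid_date_counter
    text = (raw or "").strip()
    if not text:
        return MISSING_DATE
    if not text.isdigit():
        counter["non_numeric"] += 1
        return DateValue(raw=text, precision="missing")
    if len(text) == 4:
        return DateValue(raw=text, precision="year")
    if len(text) == 6:
        month = int(text[4:6])
        if 1 <= month <= 12:
            return DateValue(raw=text, precision="month")
        counter["invalid_month"] += 1
        return DateValue(raw=text, precision="missing")
    if len(text) == 8:
        try:
            d = datetime.date(int(text[:4]), int(text[4:6]), int(text[6:8]))
        except ValueError:
            counter["invalid_calendar"] += 1
            return DateValue(raw=text, precision="missing")
        return DateValue(raw=text, precision="day", ordinal=d.toordinal())
    counter["bad_length"] += 1
    return DateValue(raw=text, precision="missing")


def date_from_ordinal(ordinal: int) -> DateValue:
    """Build a day-precision DateValue from a proleptic ordinal."""
    d = datetime.date.fromordinal(int(ordinal))
    return DateValue(raw=d.strftime("%Y%m%d"), precision="day", ordinal=int(ordinal))


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: DateValue = MISSING_DATE
    event_dt: DateValue = MISSING_DATE
    sex: str = "unknown"
    age_value: Optional[float] = None
    age_unit: str = ""
    occp_cod: str = "missing"
    reporter_country: str = ""
    outcome_codes: frozenset = frozenset()


@dataclass
class DrugRecord:
    primaryid: str
    drug_seq: int
    role: str
    verbatim_name: str
    active_ingredient: str = ""


@dataclass
class ReactionRecord:
    primaryid: str
    pt: str


@dataclass
class TherapyRecord:
    primaryid: str
    drug_seq: int
    start_dt: DateValue = MISSING_DATE
    end_dt: DateValue = MISSING_DATE


@dataclass
class ReportBundle:
    """One quarter's parsed tables plus its deletion list."""

    quarter: str
    demo: list = field(default_factory=list)
    drug: list = field(default_factory=list)
    reac: list = field(default_factory=list)
    ther: list = field(default_factory=list)
    deletion_caseids: set = field(default_factory=set)

    def referential_orphans(self) -> dict:
        """primaryids in child tables that are absent from DEMO (logged,
        never dropped — spontaneous-report bundles contain them)."""
        known = {d.primaryid for d in self.demo}
        return {
            "drug": sorted({r.primaryid for r in self.drug} - known),
            "reac": sorted({r.primaryid for r in self.reac} - known),
            "ther": sorted({r.primaryid for r in self.ther} - known),
        }


def numeric_id_key(identifier: str) -> tuple:
    """Sort key for numeric-as-text FAERS identifiers.

    Strips leading zeros so '007' == '7'; falls back to lexicographic for
    non-numeric ids (never produced by FAERS but tolerated).
    """
    text = identifier.strip()
    if text.isdigit():
        return (0, int(text), "")
    return (1, 0, text)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_TABLE_PREFIXES = ("DEMO", "DRUG", "REAC", "THER", "OUTC", "DELETED")


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\\$",
        engine="python",
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
        encoding_errors="replace",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _require(df: pd.DataFrame, columns: Iterable[str], path: Path) -> None:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")


def _classify_paths(paths) -> dict:
    """Map table name -> path from a directory or iterable of files."""
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        candidates = sorted(Path(paths).iterdir())
    else:
        candidates = [Path(p) for p in paths]
    found: dict = {}
    for p in candidates:
        upper = p.name.upper()
        for prefix in _TABLE_PREFIXES:
            if upper.startswith(prefix):
                found.setdefault(prefix, p)
                break
    return found


def read_quarter(paths, quarter: str = "") -> ReportBundle:
    """Parse one quarter's dollar-delimited tables into a ReportBundle.

    ``paths`` is a directory containing files named DEMO*/DRUG*/REAC*/THER*/
    OUTC* (and optionally DELETED*), or an iterable of such files.  Unknown
    columns are ignored; all rows are preserved; referential orphans are
    logged but kept.  A missing mandatory key column is a hard error.
    """
    table_paths = _classify_paths(paths)
    bundle = ReportBundle(quarter=quarter)

    outcomes: dict = {}
    if "OUTC" in table_paths:
        df = _read_table(table_paths["OUTC"])
        _require(df, ["primaryid", "outc_cod"], table_paths["OUTC"])
        for pid, code in zip(df["primaryid"], df["outc_cod"]):
            code = code.strip().upper()
            if code in OUTCOME_CODES:
                outcomes.setdefault(pid.strip(), set()).add(code)

    if "DEMO" in table_paths:
        path = table_paths["DEMO"]
        df = _read_table(path)
        _require(df, ["primaryid", "caseid"], path)
        for row in df.itertuples(index=False):
            row = row._asdict()
            pid = row["primaryid"].strip()
            sex = row.get("sex", "").strip().upper()
            age_raw = row.get("age", "").strip()
            try:
                age_value = float(age_raw) if age_raw else None
            except ValueError:
                age_value = None
            occ = row.get("occp_cod", "").strip().upper()
            bundle.demo.append(
                DemoRecord(
                    primaryid=pid,
                    caseid=row["caseid"].strip(),
                    fda_dt=parse_date(row.get("fda_dt", "")),
                    event_dt=parse_date(row.get("event_dt", "")),
                    sex=sex if sex in SEX_CODES else "unknown",
                    age_value=age_value,
                    age_unit=row.get("age_cod", "").strip().upper(),
                    occp_cod=occ if occ in OCCUPATION_CODES else "missing",
                    reporter_country=row.get("reporter_country", "").strip(),
                    outcome_codes=frozenset(outcomes.get(pid, ())),
                )
            )

    if "DRUG" in table_paths:
        path = table_paths["DRUG"]
        df = _read_table(path)
        _require(df, ["primaryid", "drug_seq"], path)
        for row in df.itertuples(index=False):
            row = row._asdict()
            role = row.get("role_cod", "").strip().upper()
            bundle.drug.append(
                DrugRecord(
                    primaryid=row["primaryid"].strip(),
                    drug_seq=int(row["drug_seq"]),
                    role=role if role in DRUG_ROLES else "C",
                    verbatim_name=row.get("drugname", "").strip(),
                    active_ingredient=row.get("prod_ai", "").strip(),
                )
            )

    if "REAC" in table_paths:
        path = table_paths["REAC"]
        df = _read_table(path)
        _require(df, ["primaryid", "pt"], path)
        for row in df.itertuples(index=False):
            row = row._asdict()
            pt = " ".join(row["pt"].split())
            if pt:
                bundle.reac.append(
                    ReactionRecord(primaryid=row["primaryid"].strip(), pt=pt)
                )

    if "THER" in table_paths:
        path = table_paths["THER"]
        df = _read_table(path)
        seq_col = "dsg_drug_seq" if "dsg_drug_seq" in df.columns else "drug_seq"
        _require(df, ["primaryid", seq_col], path)
        for row in df.itertuples(index=False):
            row = row._asdict()
            bundle.ther.append(
                TherapyRecord(
                    primaryid=row["primaryid"].strip(),
                    drug_seq=int(row[seq_col]),
                    start_dt=parse_date(row.get("start_dt", "")),
                    end_dt=parse_date(row.get("end_dt", "")),
                )
            )

    if "DELETED" in table_paths:
        text = table_paths["DELETED"].read_text(encoding="utf-8", errors="replace")
        lines = [ln.strip() for ln in text.splitlines()]
        # tolerate a header line reading 'caseid'
        bundle.deletion_caseids = {
            ln for ln in lines if ln and ln.lower() != "caseid"
        }

    orphans = bundle.referential_orphans()
    n_orphans = sum(len(v) for v in orphans.values())
    if n_orphans:
        logger.warning(
            "quarter %s: %d child rows reference primaryids absent from DEMO",
            quarter, n_orphans,
        )
    return bundle


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_quarter(bundle: ReportBundle, directory) -> list:
    """Emit a ReportBundle as dollar-delimited tables read_quarter accepts.

    Returns the list of paths written.  Header-only files are produced for
    empty tables; the deletion list is written only when non-empty.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = bundle.quarter.replace(" ", "") or "Q"
    written = []

    def emit(name: str, header: list, rows: list) -> None:
        path = directory / f"{name}{suffix}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(DELIMITER.join(header) + "\n")
            for row in rows:
                fh.write(DELIMITER.join(str(v) for v in row) + "\n")
        written.append(path)

    emit(
        "DEMO",
        ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
         "age_cod", "occp_cod", "reporter_country"],
        [
            (
                d.primaryid, d.caseid, d.fda_dt.raw, d.event_dt.raw,
                d.sex if d.sex in SEX_CODES else "",
                "" if d.age_value is None else (
                    int(d.age_value) if float(d.age_value).is_integer()
                    else d.age_value
                ),
                d.age_unit,
                d.occp_cod if d.occp_cod in OCCUPATION_CODES else "",
                d.reporter_country,
            )
            for d in bundle.demo
        ],
    )
    emit(
        "DRUG",
        ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
        [
            (r.primaryid, r.drug_seq, r.role, r.verbatim_name, r.active_ingredient)
            for r in bundle.drug
        ],
    )
    emit("REAC", ["primaryid", "pt"], [(r.primaryid, r.pt) for r in bundle.reac])
    emit(
        "THER",
        ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
        [
            (r.primaryid, r.drug_seq, r.start_dt.raw, r.end_dt.raw)
            for r in bundle.ther
        ],
    )
    outc_rows = [
        (d.primaryid, code)
        for d in bundle.demo
        for code in sorted(d.outcome_codes)
    ]
    emit("OUTC", ["primaryid", "outc_cod"], outc_rows)

    if bundle.deletion_caseids:
        path = directory / f"DELETED{suffix}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            for caseid in sorted(bundle.deletion_caseids, key=numeric_id_key):
                fh.write(caseid + "\n")
        written.append(path)
    return written
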