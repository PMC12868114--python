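"""Case-level preprocessing of raw FAERS-style records.

Implements the FDA deduplication rule (per CASEID keep the submission
with the highest FDA_DT, ties broken by the highest PRIMARYID), merges
the five tables into :class:`CaseReport` objects, matches a target
drug's name variants, and computes time-to-onset with explicit
rejection categories for inconsistent or partial dates.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .io import RawRecordSet

logger = logging.getLogger(__name__)

# age-unit code -> factor converting the stored value to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

# FAERS occupation code -> reporter class
OCCP_TO_CLASS = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "LW": "lawyer",
    "OT": "other health-professional",
    "HP": "other health-professional",
}

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


def parse_date(s: str | None) -> tuple[dt.date | None, str | None]:
    """Parse a FAERS digit-string date, honouring partial precision.

    8 digits → day precision, 6 → month, 4 → year.  Partial dates are
    completed to the first day/month only so a calendar object exists;
    the returned precision tag records what was actually known.
    Returns ``(None, None)`` for anything unparseable.
    """
    if not s:
        return None, None
    s = s.strip()
    if not s.isdigit():
        return None, None
    try:
        if len(s) == 8:
            return dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), "day"
        if len(s) == 6:
            return dt.date(int(s[:4]), int(s[4:6]), 1), "month"
        if len(s) == 4:
            return dt.date(int(s), 1, 1), "year"
    except ValueError:
        return None, None
    return None, None


@dataclass(frozen=True)
class DrugRow:
    name: str
    role: str  # PS, SS, C, I
    start_dt: dt.date | None = None
    start_precision: str | None = None


@dataclass
class CaseReport:
    """One deduplicated safety report."""

    caseid: str
    primaryid: str
    fda_dt: dt.date | None
    sex: str  # F / M / UNK
    age_years: float | None
    weight_kg: float | None
    reporter_class: str  # consumer / physician / ... / unknown
    reporter_code: str  # raw occupation code, for as-printed tabulation
    country: str | None
    outcomes: frozenset[str]
    drugs: list[DrugRow]
    reactions: list[str]
    event_dt: dt.date | None = None
    event_precision: str | None = None

    @property
    def year(self) -> int | None:
        return self.fda_dt.year if self.fda_dt else None

    @property
    def is_death(self) -> bool:
        return "DE" in self.outcomes


class MatchLevel(Enum):
    NONE = "none"
    ANY_ROLE = "any_role"
    PRIMARY_SUSPECT = "primary_suspect"


_WS = re.compile(r"\s+")


def _norm_name(name: str) -> str:
    return _WS.sub(" ", name.strip()).casefold()


def match_target_drug(case: CaseReport,
                      name_list: Sequence[str]) -> MatchLevel:
    """Match the target drug's name variants against a case's drug rows.

    Case-insensitive exact match after trimming and whitespace
    collapsing — no substring matching, so e.g. a congener sharing a
    name stem does not match.  ``PRIMARY_SUSPECT`` requires a matching
    row with role code PS.
    """
    if not name_list:
        raise ValueError("name_list must be non-empty")
    targets = {_norm_name(n) for n in name_list}
    level = MatchLevel.NONE
    for row in case.drugs:
        if _norm_name(row.name) in targets:
            if row.role == "PS":
                return MatchLevel.PRIMARY_SUSPECT
            level = MatchLevel.ANY_ROLE
    return level


def deduplicate(records: RawRecordSet) -> RawRecordSet:
    """Collapse multiple submissions of the same case.

    Per CASEID the demo row with the highest FDA_DT survives; on FDA_DT
    ties, the highest PRIMARYID.  Child-table rows are retained only for
    surviving primaryids.  Idempotent and order-independent.  Demo rows
    with a missing caseid are routed to ``rejects``.
    """
    demo = records.demo
    rejects = list(records.rejects)
    if len(demo):
        missing = demo["caseid"].astype(str).str.strip() == ""
        for row in demo[missing].itertuples(index=False):
            rejects.append(("demo", "$".join(str(v) for v in row)))
        demo = demo[~missing].copy()
    if len(demo):
        fda = pd.to_numeric(demo["fda_dt"], errors="coerce").fillna(-1)
        pid = pd.to_numeric(demo["primaryid"], errors="coerce").fillna(-1)
        order = pd.DataFrame({
            "caseid": demo["caseid"].values,
            "_fda": fda.values,
            "_pid": pid.values,
        }, index=demo.index)
        # stable: sort by keys then take the last row of each caseid group
        order = order.sort_values(["caseid", "_fda", "_pid"], kind="mergesort")
        keep_idx = order.groupby("caseid", sort=False).tail(1).index
        demo = demo.loc[demo.index.intersection(keep_idx)]
        demo = demo.sort_values(["caseid"], kind="mergesort").reset_index(drop=True)
    surviving = set(demo["primaryid"]) if len(demo) else set()

    def _filter(tab: pd.DataFrame) -> pd.DataFrame:
        if not len(tab):
            return tab.copy()
        return tab[tab["primaryid"].isin(surviving)].reset_index(drop=True)

    out = RawRecordSet(
        demo=demo.reset_index(drop=True),
        drug=_filter(records.drug),
        reac=_filter(records.reac),
        outc=_filter(records.outc),
        ther=_filter(records.ther),
        rejects=rejects,
    )
    out.flag_orphans()
    return out


@dataclass
class AssemblyStats:
    """Exclusion accounting from table merge to CaseReports."""

    n_demo_rows: int = 0
    n_no_reactions: int = 0
    n_cases: int = 0
    notes: list[str] = field(default_factory=list)


def _to_float(s: str) -> float | None:
    try:
        v = float(s)
    except (TypeError, ValueError):
        return None
    return v


def assemble_cases(records: RawRecordSet) -> tuple[list[CaseReport], AssemblyStats]:
    """Join the deduplicated tables into CaseReports on primaryid.

    Ages are normalised to years from the age-unit code; cases with zero
    reaction rows are dropped with a logged count (a safety report
    without a coded reaction carries no analysable event).
    """
    stats = AssemblyStats(n_demo_rows=len(records.demo))
    by_pid_drug: dict[str, list] = {}
    for row in records.drug.itertuples(index=False):
        by_pid_drug.setdefault(row.primaryid, []).append(row)
    by_pid_reac: dict[str, list[str]] = {}
    for row in records.reac.itertuples(index=False):
        by_pid_reac.setdefault(row.primaryid, []).append(row.pt)
    by_pid_outc: dict[str, set[str]] = {}
    for row in records.outc.itertuples(index=False):
        code = row.outc_cod.strip().upper()
        if code:
            by_pid_outc.setdefault(row.primaryid, set()).add(code)
    by_pid_ther: dict[tuple[str, str], str] = {}
    for row in records.ther.itertuples(index=False):
        key = (row.primaryid, row.dsg_drug_seq)
        # conflicting duplicates: keep the earliest non-empty start string
        prev = by_pid_ther.get(key)
        if prev is None or (row.start_dt and (not prev or row.start_dt < prev)):
            by_pid_ther[key] = row.start_dt

    cases: list[CaseReport] = []
    for row in records.demo.itertuples(index=False):
        pid = row.primaryid
        reactions = by_pid_reac.get(pid, [])
        # report-level counting: a repeated PT row still means one event
        seen: set[str] = set()
        reactions = [pt for pt in reactions
                     if pt and not (pt in seen or seen.add(pt))]
        if not reactions:
            stats.n_no_reactions += 1
            continue
        age_years = None
        age_val = _to_float(row.age)
        unit = row.age_cod.strip().upper() or "YR"
        if age_val is not None and unit in AGE_UNIT_TO_YEARS:
            age_years = age_val * AGE_UNIT_TO_YEARS[unit]
        sex = row.sex.strip().upper()
        if sex not in ("F", "M"):
            sex = "UNK"
        occp = row.occp_cod.strip().upper()
        drugs = []
        for d in by_pid_drug.get(pid, []):
            start_raw = by_pid_ther.get((pid, d.drug_seq))
            start, prec = parse_date(start_raw)
            drugs.append(DrugRow(name=d.drugname, role=d.role_cod.strip().upper(),
                                 start_dt=start, start_precision=prec))
        fda_date, _ = parse_date(row.fda_dt)
        event, eprec = parse_date(row.event_dt)
        cases.append(CaseReport(
            caseid=row.caseid,
            primaryid=pid,
            fda_dt=fda_date,
            sex=sex,
            age_years=age_years,
            weight_kg=_to_float(row.wt),
            reporter_class=OCCP_TO_CLASS.get(occp, "unknown"),
            reporter_code=occp,
            country=row.reporter_country.strip() or None,
            outcomes=frozenset(by_pid_outc.get(pid, set())),
            drugs=drugs,
            reactions=reactions,
            event_dt=event,
            event_precision=eprec,
        ))
    stats.n_cases = len(cases)
    logger.info("assembled %d cases (%d dropped: no reactions)",
                stats.n_cases, stats.n_no_reactions)
    return cases, stats


# time-to-onset bins; inclusive edges in days, None = unbounded
ONSET_BINS: list[tuple[str, int, int | None]] = [
    ("0-30", 1, 30),
    ("31-60", 31, 60),
    ("61-90", 61, 90),
    ("91-120", 91, 120),
    ("121-150", 121, 150),
    ("151-180", 151, 180),
    ("181-360", 181, 360),
    (">360", 361, None),
]

ONSET_BIN_LABELS = [b[0] for b in ONSET_BINS]


def onset_bin(days: int) -> str:
    if days < 1:
        raise ValueError("onset_days must be >= 1")
    for label, lo, hi in ONSET_BINS:
        if days >= lo and (hi is None or days <= hi):
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class OnsetRecord:
    caseid: str
    onset_days: int
    bin: str


class OnsetRejection(Enum):
    MISSING_EVENT_DATE = "missing event date"
    MISSING_START_DATE = "missing therapy start date"
    PARTIAL_EVENT_DATE = "event date below day precision"
    PARTIAL_START_DATE = "start date below day precision"
    EVENT_BEFORE_START = "event precedes therapy start"


def compute_onset(case: CaseReport,
                  target_names: Sequence[str]) -> OnsetRecord | OnsetRejection:
    """Days from first target-drug therapy start to the adverse event.

    Same-day events count as day 1 (day difference + 1), so onset is
    always a positive integer.  Cases with missing or partial dates, or
    an event preceding the start, are rejected with a categorised
    reason — rejection is an analysis outcome, not an error.  When the
    target appears on several rows the earliest day-precision start is
    used: first exposure defines latency.
    """
    targets = {_norm_name(n) for n in target_names}
    starts = [d.start_dt for d in case.drugs
              if _norm_name(d.name) in targets and d.start_dt is not None]
    day_starts = [d.start_dt for d in case.drugs
                  if _norm_name(d.name) in targets
                  and d.start_dt is not None and d.start_precision == "day"]
    if case.event_dt is None:
        return OnsetRejection.MISSING_EVENT_DATE
    if not starts:
        return OnsetRejection.MISSING_START_DATE
    if case.event_precision != "day":
        return OnsetRejection.PARTIAL_EVENT_DATE
    if not day_starts:
        return OnsetRejection.PARTIAL_START_DATE
    start = min(day_starts)
    delta = (case.event_dt - start).days
    if delta < 0:
        return OnsetRejection.EVENT_BEFORE_START
    days = delta + 1
    return OnsetRecord(caseid=case.caseid, onset_days=days, bin=onset_bin(days))


def compute_onsets(cases: Iterable[CaseReport], target_names: Sequence[str],
                   ) -> tuple[list[OnsetRecord], dict[OnsetRejection, int]]:
    """Vectorised convenience wrapper; returns records and rejection tallies."""
    records: list[OnsetRecord] = []
    rejections: dict[OnsetRejection, int] = {r: 0 for r in OnsetRejection}
    for case in cases:
        out = compute_onset(case, target_names)
        if isinstance(out, OnsetRecord):
            records.append(out)
        else:
            rejections[out] += 1
    return records, rejections
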