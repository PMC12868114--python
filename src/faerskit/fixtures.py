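"""Minimal synthetic universes built from marginal counts.

Published FAERS tabulations print block counts (sex, age bins, outcome
categories, top-k countries, onset bins, death-by-demographic cross
tables).  The helpers here expand such printed counts into minimal
:class:`~faerskit.preprocess.CaseReport` universes so the summary
operations can be validated against published arithmetic: feed the
counts in, and the summaries must print the published percentages back.

All universes built here are synthetic stand-ins: every attribute not
named by the counts is left at its missing/unknown default.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

from .preprocess import ONSET_BINS, CaseReport, OnsetRecord, onset_bin

_counter = itertools.count()


def make_case(sex: str = "UNK", age_years: float | None = None,
              outcomes: Sequence[str] = (), country: str | None = None,
              reporter_class: str = "unknown",
              year: int | None = None,
              weight_kg: float | None = None) -> CaseReport:
    """A minimal CaseReport with one placeholder reaction."""
    import datetime as dt

    i = next(_counter)
    fda = dt.date(year, 7, 1) if year else None
    return CaseReport(
        caseid=f"FX{i}", primaryid=f"FX{i}1", fda_dt=fda, sex=sex,
        age_years=age_years, weight_kg=weight_kg,
        reporter_class=reporter_class, reporter_code="",
        country=country, outcomes=frozenset(outcomes),
        drugs=[], reactions=["PT_FIXTURE"],
    )


def cases_from_sex_counts(counts: Mapping[str, int]) -> list[CaseReport]:
    return [make_case(sex=lvl) for lvl, n in counts.items() for _ in range(n)]


#: representative age per published bin label
AGE_BIN_REPRESENTATIVE = {"<18": 10.0, "18-44": 30.0, "45-64": 55.0,
                          ">64": 70.0, "Unknown": None}


def cases_from_age_bin_counts(counts: Mapping[str, int]) -> list[CaseReport]:
    return [make_case(age_years=AGE_BIN_REPRESENTATIVE[lvl])
            for lvl, n in counts.items() for _ in range(n)]


def cases_from_outcome_counts(counts: Mapping[str, int]) -> list[CaseReport]:
    """One single-outcome case per mention, as block counts imply."""
    return [make_case(outcomes=[code]) for code, n in counts.items()
            for _ in range(n)]


def cases_from_country_counts(counts: Mapping[str, int]) -> list[CaseReport]:
    return [make_case(country=c) for c, n in counts.items() for _ in range(n)]


#: representative onset day inside each bin
ONSET_BIN_REPRESENTATIVE = {label: lo for label, lo, _ in ONSET_BINS}


def onsets_from_bin_counts(counts: Mapping[str, int]) -> list[OnsetRecord]:
    recs = []
    for label, n in counts.items():
        day = ONSET_BIN_REPRESENTATIVE[label]
        assert onset_bin(day) == label
        for i in range(n):
            recs.append(OnsetRecord(caseid=f"OX{label}{i}", onset_days=day,
                                    bin=label))
    return recs


def cases_from_death_cross(death: Mapping[str, int],
                           nondeath: Mapping[str, int],
                           variable: str = "sex") -> list[CaseReport]:
    """Universe realising a printed death/non-death cross-tabulation.

    ``variable`` selects which attribute the level labels describe
    ("sex" or "age"); death cases carry outcome code DE.
    """
    cases: list[CaseReport] = []
    for is_death, counts in ((True, death), (False, nondeath)):
        for lvl, n in counts.items():
            kw = {}
            if variable == "sex":
                kw["sex"] = lvl
            else:
                kw["age_years"] = AGE_BIN_REPRESENTATIVE[lvl]
            for _ in range(n):
                cases.append(make_case(outcomes=["DE"] if is_death else [],
                                       **kw))
    return cases
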