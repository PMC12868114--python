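import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerskit.io import RawRecordSet, TABLE_COLUMNS
from faerskit.preprocess import (
    MatchLevel,
    OnsetRecord,
    OnsetRejection,
    assemble_cases,
    compute_onset,
    deduplicate,
    match_target_drug,
    onset_bin,
    parse_date,
)
from faerskit.synthetic import SyntheticConfig, generate

from conftest import TARGET, case_with


def _demo_row(primaryid, caseid, fda_dt, **kw):
    row = {c: "" for c in TABLE_COLUMNS["demo"]}
    row.update(primaryid=primaryid, caseid=caseid, fda_dt=fda_dt, **kw)
    return row


def _records(demo_rows, drug_rows=(), reac_rows=()):
    rs = RawRecordSet.empty()
    if demo_rows:
        rs.demo = pd.DataFrame(demo_rows, dtype=str)
    if drug_rows:
        rs.drug = pd.DataFrame(drug_rows, dtype=str)
    if reac_rows:
        rs.reac = pd.DataFrame(reac_rows, dtype=str)
    return rs


class TestDeduplicate:
    def test_highest_fda_dt_survives(self):
        rs = _records([_demo_row("11", "1", "20200101"),
                       _demo_row("12", "1", "20210101")])
        out = deduplicate(rs)
        assert list(out.demo["primaryid"]) == ["12"]

    def test_fda_dt_tie_broken_by_highest_primaryid(self):
        rs = _records([_demo_row("11112222", "1", "20200101"),
                       _demo_row("11113333", "1", "20200101")])
        out = deduplicate(rs)
        assert list(out.demo["primaryid"]) == ["11113333"]

    def test_idempotent_on_unique_set(self):
        rs = _records([_demo_row("11", "1", "20200101"),
                       _demo_row("21", "2", "20200102")])
        once = deduplicate(rs)
        twice = deduplicate(once)
        assert once.equals(twice)
        assert len(once.demo) == 2

    def test_order_independent(self):
        rows = [_demo_row("11", "1", "20200101"),
                _demo_row("12", "1", "20210101"),
                _demo_row("13", "1", "20210101"),
                _demo_row("21", "2", "20190101")]
        base = deduplicate(_records(rows))
        for perm in ([3, 2, 1, 0], [1, 3, 0, 2], [2, 0, 3, 1]):
            out = deduplicate(_records([rows[i] for i in perm]))
            assert out.equals(base)

    def test_child_rows_follow_surviving_primaryid(self):
        rs = _records(
            [_demo_row("11", "1", "20200101"), _demo_row("12", "1", "20210101")],
            drug_rows=[{"primaryid": p, "caseid": "1", "drug_seq": "1",
                        "role_cod": "PS", "drugname": "Venlafaxine"}
                       for p in ("11", "12")],
            reac_rows=[{"primaryid": p, "caseid": "1", "pt": "Nausea"}
                       for p in ("11", "12")])
        out = deduplicate(rs)
        assert list(out.drug["primaryid"]) == ["12"]
        assert list(out.reac["primaryid"]) == ["12"]

    def test_missing_caseid_routed_to_rejects(self):
        rs = _records([_demo_row("11", "", "20200101"),
                       _demo_row("21", "2", "20200101")])
        out = deduplicate(rs)
        assert len(out.demo) == 1
        assert len(out.rejects) == 1

    def test_survivors_never_exceed_input(self, small_universe):
        _, records, truth = small_universe
        out = deduplicate(records)
        assert len(out.demo) <= len(records.demo)
        assert out.demo["caseid"].is_unique
        # every duplicate lineage collapses to its last submission
        n_dups = sum(len(v) > 1 for v in truth.duplicate_lineage.values())
        assert len(records.demo) - len(out.demo) == n_dups


class TestAssemble:
    def test_age_unit_conversion_months(self):
        rs = _records(
            [_demo_row("11", "1", "20200101", age="600", age_cod="MON")],
            reac_rows=[{"primaryid": "11", "caseid": "1", "pt": "Nausea"}])
        cases, _ = assemble_cases(rs)
        assert cases[0].age_years == pytest.approx(50.0)

    @pytest.mark.parametrize("age,unit,expected", [
        ("5", "DEC", 50.0), ("47", "YR", 47.0), ("104.36", "WK", 2.0),
        ("730.5", "DY", 2.0), ("8766", "HR", 1.0)])
    def test_age_unit_conversions(self, age, unit, expected):
        rs = _records(
            [_demo_row("11", "1", "20200101", age=age, age_cod=unit)],
            reac_rows=[{"primaryid": "11", "caseid": "1", "pt": "Nausea"}])
        cases, _ = assemble_cases(rs)
        assert cases[0].age_years == pytest.approx(expected, rel=1e-3)

    def test_case_without_reactions_excluded_and_counted(self):
        rs = _records([_demo_row("11", "1", "20200101"),
                       _demo_row("21", "2", "20200101")],
                      reac_rows=[{"primaryid": "21", "caseid": "2",
                                  "pt": "Nausea"}])
        cases, stats = assemble_cases(rs)
        assert len(cases) == 1
        assert stats.n_no_reactions == 1

    def test_case_count_matches_brute_force_recount(self):
        cfg = SyntheticConfig(n_cases=500, seed=7)
        records, _ = generate(cfg)
        deduped = deduplicate(records)
        cases, _ = assemble_cases(deduped)
        with_reac = set(deduped.reac["primaryid"])
        expected = sum(1 for p in deduped.demo["primaryid"] if p in with_reac)
        assert len(cases) == expected
        assert len({c.caseid for c in cases}) == len(cases)


class TestMatchTargetDrug:
    NAMES = ["Venlafaxine", "Venlafaxine Hcl", "Venlafaxine Hydrochloride",
             "Effexor", "Effexor xr", "Venbysi xr"]

    @pytest.mark.parametrize("drugname,role,expected", [
        ("EFFEXOR XR", "PS", MatchLevel.PRIMARY_SUSPECT),
        ("Venlafaxine Hydrochloride", "C", MatchLevel.ANY_ROLE),
        ("Desvenlafaxine", "PS", MatchLevel.NONE),  # no substring matching
        ("  venlafaxine   hcl ", "SS", MatchLevel.ANY_ROLE),
        ("venbysi  XR", "PS", MatchLevel.PRIMARY_SUSPECT),
    ])
    def test_name_matching(self, drugname, role, expected):
        case = case_with(drugs=[(drugname, role)])
        assert match_target_drug(case, self.NAMES) is expected

    def test_empty_name_list_rejected(self):
        with pytest.raises(ValueError):
            match_target_drug(case_with(), [])


class TestOnset:
    def _case(self, start, event, event_precision="day", start_precision="day"):
        return case_with(
            drugs=[("Venlafaxine", "PS", start, start_precision)],
            event_dt=event, event_precision=event_precision)

    def test_two_week_onset(self):
        c = self._case(dt.date(2020, 1, 1), dt.date(2020, 1, 15))
        rec = compute_onset(c, TARGET)
        assert isinstance(rec, OnsetRecord)
        assert rec.onset_days == 15
        assert rec.bin == "0-30"

    def test_same_day_event_is_day_one(self):
        rec = compute_onset(self._case(dt.date(2020, 1, 1), dt.date(2020, 1, 1)),
                            TARGET)
        assert rec.onset_days == 1

    def test_event_before_start_rejected(self):
        out = compute_onset(self._case(dt.date(2020, 1, 1), dt.date(2019, 12, 25)),
                            TARGET)
        assert out is OnsetRejection.EVENT_BEFORE_START

    def test_calendar_arithmetic_at_year_boundary(self):
        rec = compute_onset(self._case(dt.date(2020, 1, 1), dt.date(2020, 12, 26)),
                            TARGET)
        assert rec.onset_days == 361
        assert rec.bin == ">360"

    @pytest.mark.parametrize("event,eprec,sprec,expected", [
        (None, None, "day", OnsetRejection.MISSING_EVENT_DATE),
        (dt.date(2020, 6, 1), "month", "day", OnsetRejection.PARTIAL_EVENT_DATE),
        (dt.date(2020, 6, 1), "day", "month", OnsetRejection.PARTIAL_START_DATE),
    ])
    def test_partial_or_missing_dates_rejected(self, event, eprec, sprec,
                                               expected):
        c = self._case(dt.date(2020, 1, 1), event, event_precision=eprec,
                       start_precision=sprec)
        assert compute_onset(c, TARGET) is expected

    def test_earliest_target_start_defines_latency(self):
        c = case_with(
            drugs=[("Venlafaxine", "PS", dt.date(2020, 3, 1), "day"),
                   ("Effexor", "SS", dt.date(2020, 1, 1), "day")],
            event_dt=dt.date(2020, 3, 10), event_precision="day")
        rec = compute_onset(c, TARGET)
        assert rec.onset_days == (dt.date(2020, 3, 10) - dt.date(2020, 1, 1)).days + 1

    @settings(max_examples=200, deadline=None)
    @given(days=st.integers(min_value=1, max_value=5000))
    def test_bin_always_consistent_with_days(self, days):
        label = onset_bin(days)
        lo, hi = {"0-30": (1, 30), "31-60": (31, 60), "61-90": (61, 90),
                  "91-120": (91, 120), "121-150": (121, 150),
                  "151-180": (151, 180), "181-360": (181, 360),
                  ">360": (361, 10**9)}[label]
        assert lo <= days <= hi


@pytest.mark.parametrize("raw,expected", [
    ("20200115", (dt.date(2020, 1, 15), "day")),
    ("202001", (dt.date(2020, 1, 1), "month")),
    ("2020", (dt.date(2020, 1, 1), "year")),
    ("", (None, None)),
    ("2020013", (None, None)),
    ("20200230", (None, None)),  # impossible calendar day
])
def test_parse_date_precisions(raw, expected):
    assert parse_date(raw) == expected
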