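import datetime as dt

import pytest

from faerskit.preprocess import CaseReport, DrugRow
from faerskit.synthetic import SignalPair, SyntheticConfig, generate

TARGET = ["Venlafaxine", "Effexor", "Effexor xr"]


def case_with(drugs=(), reactions=("PT_X",), caseid="C1", sex="UNK",
              age_years=None, outcomes=(), country=None, event_dt=None,
              event_precision=None, fda_dt=dt.date(2020, 1, 1),
              weight_kg=None, reporter_class="unknown"):
    return CaseReport(
        caseid=caseid, primaryid=caseid + "1", fda_dt=fda_dt, sex=sex,
        age_years=age_years, weight_kg=weight_kg,
        reporter_class=reporter_class, reporter_code="",
        country=country, outcomes=frozenset(outcomes),
        drugs=[DrugRow(*d) if not isinstance(d, DrugRow) else d for d in drugs],
        reactions=list(reactions), event_dt=event_dt,
        event_precision=event_precision,
    )


@pytest.fixture(scope="session")
def small_universe():
    """6,000-case universe with one strong injected signal (seed-fixed)."""
    cfg = SyntheticConfig(n_cases=6000, seed=11,
                          signal_pairs=[SignalPair(0, 6, 8.0)])
    records, truth = generate(cfg)
    return cfg, records, truth


@pytest.fixture
def hand_universe():
    """Six hand-built reports: 3 target-PS (2 with the PT), 1 other report
    with the PT, 2 with neither -> a=2, b=1, c=1, d=2 for (target, PT_A)."""
    mk = case_with
    return [
        mk(caseid="H1", drugs=[("Venlafaxine", "PS")], reactions=["PT_A"]),
        mk(caseid="H2", drugs=[("Effexor", "PS")], reactions=["PT_A", "PT_B"]),
        mk(caseid="H3", drugs=[("VENLAFAXINE", "PS")], reactions=["PT_B"]),
        mk(caseid="H4", drugs=[("Aspirin", "PS")], reactions=["PT_A"]),
        mk(caseid="H5", drugs=[("Aspirin", "PS")], reactions=["PT_B"]),
        mk(caseid="H6", drugs=[("Ibuprofen", "PS")], reactions=["PT_C"]),
    ]
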