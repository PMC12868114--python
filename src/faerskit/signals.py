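"""Signal criteria, ranked tables and subgroup re-analysis.

A drug-event pair is a *signal* when it clears prespecified thresholds:

* ROR: at least 3 reports and the lower 95% CI bound above 1;
* PRR: at least 3 reports, PRR >= 2 and chi-square >= 4 (the Evans
  rule; the chi-square companion can be switched off);
* BCPNN: IC025 above 0;
* MGPS: EBGM05 above 2.

The conjunction of all four is the conservative default used for the
ranked tables.  Subgroup runs restrict the universe to one stratum and
recompute everything inside it, including a re-fitted MGPS prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

from .disproportionality import (
    ContingencyTable,
    EbgmEstimate,
    GpsFitResult,
    IcEstimate,
    NonEstimable,
    RatioEstimate,
    bcpnn_ic,
    build_all_tables,
    chi_square,
    drug_event_counts,
    ebgm,
    gps_fit,
    prr,
    ror,
)
from .io import MeddraMap
from .preprocess import CaseReport

logger = logging.getLogger(__name__)

METHODS = ("ror", "prr", "ic", "ebgm")


@dataclass
class SignalResult:
    """Full statistics row for one PT, with per-method signal flags."""

    pt: str
    soc: str
    n: int  # cell a: reports with drug and event
    ror_est: RatioEstimate | NonEstimable
    prr_est: RatioEstimate | NonEstimable
    chi2: float
    ic_est: IcEstimate
    ebgm_est: EbgmEstimate
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def meets_all_four(self) -> bool:
        return all(self.flags.get(m, False) for m in METHODS)

    @property
    def ebgm(self) -> float:
        return self.ebgm_est.ebgm


def evaluate_criteria(pt: str, soc: str, n: int,
                      ror_est: RatioEstimate | NonEstimable,
                      prr_est: RatioEstimate | NonEstimable,
                      chi2: float, ic_est: IcEstimate,
                      ebgm_est: EbgmEstimate,
                      use_chi2_with_prr: bool = True) -> SignalResult:
    """Apply the four signal criteria to one PT's statistics.

    A non-estimable ROR or PRR simply fails its flag; the Bayesian flags
    are always evaluable.  ``use_chi2_with_prr=False`` drops the
    chi-square >= 4 companion from the PRR rule.
    """
    ror_flag = (n >= 3 and isinstance(ror_est, RatioEstimate)
                and ror_est.ci_low > 1.0)
    prr_flag = (n >= 3 and isinstance(prr_est, RatioEstimate)
                and prr_est.point >= 2.0
                and (not use_chi2_with_prr or chi2 >= 4.0))
    flags = {
        "ror": bool(ror_flag),
        "prr": bool(prr_flag),
        "ic": bool(ic_est.ic025 > 0.0),
        "ebgm": bool(ebgm_est.ebgm05 > 2.0),
    }
    return SignalResult(pt=pt, soc=soc, n=n, ror_est=ror_est, prr_est=prr_est,
                        chi2=chi2, ic_est=ic_est, ebgm_est=ebgm_est, flags=flags)


def compute_signal_table(cases: Sequence[CaseReport],
                         target_names: Sequence[str],
                         meddra: MeddraMap | None = None,
                         prior=None,
                         ic_variant: str = "shrunk",
                         yates: bool = True,
                         use_chi2_with_prr: bool = True,
                         min_prior_pairs: int = 100,
                         ) -> tuple[list[SignalResult], GpsFitResult | None]:
    """All four statistics plus flags for every PT the target drug has.

    The MGPS prior is fitted on the (a, E) counts of *all* suspect-drug
    / PT pairs in the universe unless a prior is supplied.  PTs with
    a = 0 carry no information about the target and are omitted.
    """
    tables = build_all_tables(cases, target_names)
    fit: GpsFitResult | None = None
    if prior is None:
        counts = drug_event_counts(cases)
        fit = gps_fit(counts[["a", "E"]], min_pairs=min_prior_pairs)
        prior = fit.prior
    results: list[SignalResult] = []
    soc_of = meddra.soc_of if meddra is not None else (lambda pt: MeddraMap.UNMAPPED)
    for row in tables.itertuples(index=False):
        if row.a == 0:
            continue
        t = ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d))
        results.append(evaluate_criteria(
            pt=row.pt, soc=soc_of(row.pt), n=t.a,
            ror_est=ror(t), prr_est=prr(t),
            chi2=chi_square(t, yates=yates),
            ic_est=bcpnn_ic(t, variant=ic_variant),
            ebgm_est=ebgm(t, prior),
            use_chi2_with_prr=use_chi2_with_prr,
        ))
    return results, fit


def _flag_filter(criteria: str) -> Callable[[SignalResult], bool]:
    if criteria == "all4":
        return lambda r: r.meets_all_four
    if criteria == "any":
        return lambda r: any(r.flags.values())
    if criteria in METHODS:
        return lambda r: r.flags.get(criteria, False)
    raise ValueError(f"unknown criteria selector {criteria!r}")


def rank_by_frequency(results: Sequence[SignalResult], k: int,
                      criteria: str = "all4") -> list[SignalResult]:
    """Flagged PTs ordered by case count (ties: EBGM desc, then PT)."""
    keep = [r for r in results if _flag_filter(criteria)(r)]
    keep.sort(key=lambda r: (-r.n, -r.ebgm, r.pt))
    return keep[:k]


def rank_by_intensity(results: Sequence[SignalResult], k: int,
                      criteria: str = "all4") -> list[SignalResult]:
    """Flagged PTs ordered by EBGM (ties: n desc, then PT)."""
    keep = [r for r in results if _flag_filter(criteria)(r)]
    keep.sort(key=lambda r: (-r.ebgm, -r.n, r.pt))
    return keep[:k]


# ---------------------------------------------------------------------------
# subgroups

AGE_SCHEMES: dict[str, list[tuple[str, float, float | None]]] = {
    # inclusive lower edge, exclusive upper edge (None = unbounded)
    "results": [("<18", 0.0, 18.0), ("18-44", 18.0, 45.0),
                ("45-64", 45.0, 65.0), (">64", 65.0, None)],
    "methods": [("<18", 0.0, 18.0), ("18-60", 18.0, 61.0), (">60", 61.0, None)],
}

UNKNOWN = "Unknown"


@dataclass
class SubgroupSpec:
    """A stratification request: variable plus ordered levels.

    Missing values form their own ``Unknown`` stratum, which is carried
    through counting but is not part of hypothesis generation.
    """

    variable: str  # sex | age | region
    levels: list[str] = field(default_factory=list)
    age_scheme: str = "results"

    def __post_init__(self):
        if self.variable not in ("sex", "age", "region"):
            raise ValueError(f"unknown subgroup variable {self.variable!r}")
        if not self.levels:
            if self.variable == "sex":
                self.levels = ["F", "M"]
            elif self.variable == "age":
                self.levels = [b[0] for b in AGE_SCHEMES[self.age_scheme]]
            # region levels must be supplied (no canonical country set)

    def level_of(self, case: CaseReport) -> str:
        if self.variable == "sex":
            return case.sex if case.sex in self.levels else UNKNOWN
        if self.variable == "age":
            if case.age_years is None:
                return UNKNOWN
            for label, lo, hi in AGE_SCHEMES[self.age_scheme]:
                if case.age_years >= lo and (hi is None or case.age_years < hi):
                    return label
            return UNKNOWN
        # region
        return case.country if case.country in self.levels else UNKNOWN


def subgroup_analysis(cases: Sequence[CaseReport],
                      target_names: Sequence[str],
                      spec: SubgroupSpec,
                      meddra: MeddraMap | None = None,
                      **kwargs) -> dict[str, list[SignalResult]]:
    """Re-run the whole signal computation inside each stratum.

    Every stratum rebuilds its 2x2 tables against its own universe and
    re-fits the MGPS prior on its own pair counts (strata with too few
    qualifying pairs fall back to the diffuse prior, logged inside
    :func:`~faerskit.disproportionality.gps_fit`).  The ``Unknown``
    stratum is returned for count conservation but is not meant for
    hypothesis generation.
    """
    strata: dict[str, list[CaseReport]] = {lvl: [] for lvl in spec.levels}
    strata[UNKNOWN] = []
    for case in cases:
        strata.setdefault(spec.level_of(case), []).append(case)
    out: dict[str, list[SignalResult]] = {}
    for level, members in strata.items():
        if not members:
            out[level] = []
            continue
        results, _ = compute_signal_table(members, target_names,
                                          meddra=meddra, **kwargs)
        out[level] = results
    return out


def signal_table_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Export as the standard delimited-table layout."""

    def _ratio(est):
        if isinstance(est, RatioEstimate):
            return est.point, est.ci_low, est.ci_high
        return float("nan"), float("nan"), float("nan")

    rows = []
    for r in results:
        ror_p, ror_l, ror_h = _ratio(r.ror_est)
        prr_p, prr_l, prr_h = _ratio(r.prr_est)
        rows.append({
            "PT": r.pt, "SOC": r.soc, "n": r.n,
            "ROR": ror_p, "ROR_low": ror_l, "ROR_high": ror_h,
            "PRR": prr_p, "PRR_low": prr_l, "PRR_high": prr_h,
            "chi2": r.chi2,
            "IC": r.ic_est.ic, "IC025": r.ic_est.ic025,
            "EBGM": r.ebgm_est.ebgm, "EBGM05": r.ebgm_est.ebgm05,
            "flag_ROR": r.flags.get("ror", False),
            "flag_PRR": r.flags.get("prr", False),
            "flag_IC": r.flags.get("ic", False),
            "flag_EBGM": r.flags.get("ebgm", False),
            "meets_all_four": r.meets_all_four,
        })
    return pd.DataFrame(rows)
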