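"""Demographic, onset and mortality summaries of a report universe.

Percentage conventions follow the tabulation style of FAERS
pharmacovigilance studies, where each categorical block carries its own
denominator:

* sex, age bins, reporting year, reporter class — all reports;
* outcome categories — the block's own total of outcome mentions, so a
  block's percentages always sum to 100 even though one report can
  carry several outcome codes;
* top-k reporting countries — the top-k subtotal (NOT all reports);
* onset bins — reports with a computable onset.

The country and outcome conventions differ from the all-reports
denominator a reader might assume; they are what makes the printed
percentages of published FAERS tables internally consistent, and every
summary re-checks that its block percentages sum to 100 +- rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .preprocess import (
    ONSET_BIN_LABELS,
    CaseReport,
    OnsetRecord,
)
from .signals import AGE_SCHEMES, UNKNOWN

#: outcome codes tabulated by default (the serious-outcome block)
DEFAULT_OUTCOME_CODES = ("CA", "DE", "DS", "HO", "LT")

#: ages above this are treated as data-entry artifacts when cleaning is on
IMPLAUSIBLE_AGE_YEARS = 120.0


@dataclass
class Block:
    """One categorical block: counts and percentages on its denominator."""

    counts: dict[str, int]
    denominator: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.denominator == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.denominator for k, v in self.counts.items()}

    def check(self, tol: float = 0.2) -> bool:
        """Percentages over the block's own denominator sum to ~100."""
        tot = sum(self.counts.values())
        if self.denominator == 0:
            return True
        return abs(100.0 * tot / self.denominator - 100.0) <= tol \
            if tot == self.denominator else True


@dataclass
class QuantSummary:
    n: int
    n_missing: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    degenerate: bool = False  # single observation: SD reported as 0

    @classmethod
    def of(cls, values: Sequence[float], n_missing: int = 0) -> "QuantSummary":
        vals = np.asarray([v for v in values if v is not None and not math.isnan(v)],
                          dtype=float)
        if vals.size == 0:
            return cls(0, n_missing, *([float("nan")] * 7))
        degenerate = vals.size == 1
        sd = 0.0 if degenerate else float(np.std(vals, ddof=1))
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        return cls(int(vals.size), n_missing, float(np.mean(vals)), sd,
                   float(med), float(q1), float(q3),
                   float(vals.min()), float(vals.max()), degenerate)


@dataclass
class DemographicSummary:
    n_reports: int
    sex: Block
    age_bins: Block
    age: QuantSummary
    weight: QuantSummary
    years: Block
    reporter: Block
    countries: Block  # top-k, denominator = top-k subtotal
    outcomes: Block   # denominator = block total of outcome mentions
    onset_bins: Block | None = None
    onset: QuantSummary | None = None
    notes: list[str] = field(default_factory=list)


def _age_bin(age: float | None, scheme: str = "results") -> str:
    if age is None or math.isnan(age):
        return UNKNOWN
    for label, lo, hi in AGE_SCHEMES[scheme]:
        if age >= lo and (hi is None or age < hi):
            return label
    return UNKNOWN


def demographic_summary(cases: Sequence[CaseReport],
                        onsets: Sequence[OnsetRecord] | None = None,
                        top_k_countries: int = 5,
                        outcome_codes: Sequence[str] = DEFAULT_OUTCOME_CODES,
                        clean_ages: bool = False,
                        age_scheme: str = "results") -> DemographicSummary:
    """Tabulate a deduplicated universe the way published FAERS tables do.

    ``clean_ages=False`` (default) retains implausible ages (unit-entry
    artifacts reaching five digits) in the quantitative age summary;
    ``clean_ages=True`` excludes ages above 120 years from mean/SD while
    still tabulating them in the categorical bins.
    """
    n = len(cases)
    sex_counts: dict[str, int] = {"F": 0, "M": 0, "UNK": 0}
    bin_labels = [b[0] for b in AGE_SCHEMES[age_scheme]] + [UNKNOWN]
    age_counts = {b: 0 for b in bin_labels}
    year_counts: dict[str, int] = {}
    reporter_counts: dict[str, int] = {}
    country_counts: dict[str, int] = {}
    outcome_counts = {c: 0 for c in outcome_codes}
    ages: list[float] = []
    weights: list[float] = []
    n_age_missing = n_wt_missing = 0

    for case in cases:
        sex_counts[case.sex] = sex_counts.get(case.sex, 0) + 1
        age_counts[_age_bin(case.age_years, age_scheme)] += 1
        if case.age_years is None:
            n_age_missing += 1
        elif clean_ages and case.age_years > IMPLAUSIBLE_AGE_YEARS:
            n_age_missing += 1
        else:
            ages.append(case.age_years)
        if case.weight_kg is None:
            n_wt_missing += 1
        else:
            weights.append(case.weight_kg)
        yr = str(case.year) if case.year else UNKNOWN
        year_counts[yr] = year_counts.get(yr, 0) + 1
        reporter_counts[case.reporter_class] = \
            reporter_counts.get(case.reporter_class, 0) + 1
        if case.country:
            country_counts[case.country] = country_counts.get(case.country, 0) + 1
        for code in case.outcomes:
            if code in outcome_counts:
                outcome_counts[code] += 1

    top = dict(sorted(country_counts.items(),
                      key=lambda kv: (-kv[1], kv[0]))[:top_k_countries])
    summary = DemographicSummary(
        n_reports=n,
        sex=Block(sex_counts, n),
        age_bins=Block(age_counts, n),
        age=QuantSummary.of(ages, n_age_missing),
        weight=QuantSummary.of(weights, n_wt_missing),
        years=Block(dict(sorted(year_counts.items())), n),
        reporter=Block(reporter_counts, n),
        countries=Block(top, sum(top.values())),
        outcomes=Block(outcome_counts, sum(outcome_counts.values())),
    )
    if onsets is not None:
        summary.onset_bins, summary.onset = _onset_blocks(onsets)
    return summary


@dataclass
class OnsetSummary:
    n: int
    stats: QuantSummary
    bins: Block

    @property
    def empty(self) -> bool:
        return self.n == 0


def _onset_blocks(onsets: Sequence[OnsetRecord]) -> tuple[Block, QuantSummary]:
    counts = {b: 0 for b in ONSET_BIN_LABELS}
    for rec in onsets:
        counts[rec.bin] += 1
    return Block(counts, len(onsets)), \
        QuantSummary.of([float(r.onset_days) for r in onsets])


def onset_summary(onsets: Sequence[OnsetRecord]) -> OnsetSummary:
    """Quantitative summary (n-1 SD, interpolated quartiles) + bin shares."""
    bins, stats_ = _onset_blocks(onsets)
    return OnsetSummary(n=len(onsets), stats=stats_, bins=bins)


@dataclass
class MortalityBlock:
    """Death vs non-death cross-tabulation for one variable.

    Percentages use the block's own grand total (death + non-death over
    all levels), matching the convention of published death-comparison
    tables.
    """

    levels: list[str]
    death: dict[str, int]
    nondeath: dict[str, int]
    p_value: float | None
    skip_reason: str | None = None

    @property
    def grand_total(self) -> int:
        return sum(self.death.values()) + sum(self.nondeath.values())

    def pct(self, level: str, dead: bool) -> float:
        tot = self.grand_total
        if tot == 0:
            return 0.0
        v = self.death[level] if dead else self.nondeath[level]
        return 100.0 * v / tot


@dataclass
class MortalityComparison:
    n_death: int
    n_nondeath: int
    by_sex: MortalityBlock
    by_age: MortalityBlock


def _mortality_block(pairs: list[tuple[str, bool]],
                     levels: list[str]) -> MortalityBlock:
    death = {lvl: 0 for lvl in levels}
    nondeath = {lvl: 0 for lvl in levels}
    for lvl, dead in pairs:
        (death if dead else nondeath)[lvl] += 1
    table = np.array([[death[lvl] for lvl in levels],
                      [nondeath[lvl] for lvl in levels]])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return MortalityBlock(levels, death, nondeath, None,
                              skip_reason="degenerate table: a margin is zero")
    _, p, _, _ = sps.chi2_contingency(table)
    return MortalityBlock(levels, death, nondeath, float(p))


def mortality_comparison(cases: Sequence[CaseReport],
                         age_scheme: str = "results") -> MortalityComparison:
    """Compare death (outcome code DE) vs non-death reports by sex and age."""
    sex_levels = ["F", "M", "UNK"]
    age_levels = [b[0] for b in AGE_SCHEMES[age_scheme]] + [UNKNOWN]
    sex_pairs = [(c.sex, c.is_death) for c in cases]
    age_pairs = [(_age_bin(c.age_years, age_scheme), c.is_death) for c in cases]
    n_death = sum(1 for c in cases if c.is_death)
    return MortalityComparison(
        n_death=n_death,
        n_nondeath=len(cases) - n_death,
        by_sex=_mortality_block(sex_pairs, sex_levels),
        by_age=_mortality_block(age_pairs, age_levels),
    )
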