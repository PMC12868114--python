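"""Synthetic FAERS-like data with known ground truth.

Emulates the structure of spontaneous adverse-event reporting data —
multi-table case reports keyed by CASEID/PRIMARYID/FDA_DT, drug rows
with role codes and name variants, MedDRA-style PT/SOC coding,
demographics with missingness and occasional implausible outliers,
duplicate submissions, therapy/event dates with a bimodal onset mixture
— while injecting drug-event pairs with known elevated relative
reporting rates.  Every downstream stage of the pipeline is testable
against this ground truth without any download.

Signals are injected multiplicatively: for a case whose suspect drug is
g, PT j is drawn with probability proportional to w_j * lambda(g, j),
renormalised, so the per-case PT count stays rate-stable.  Note that
renormalisation and the drug's own contribution to the pooled PT margin
both attenuate the realised observed/expected ratio slightly below the
injected lambda; :func:`realized_rates` measures what the data actually
contain.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MeddraMap, RawRecordSet
from .preprocess import _norm_name

EPOCH = dt.date(2004, 1, 1)

DEFAULT_TARGET_NAMES = [
    "Venlafaxine", "Venlafaxine Hcl", "Venlafaxine Hydrochloride",
    "Effexor", "Effexor xr", "Venbysi xr",
]

DEFAULT_MISSING_RATES = {
    "age": 0.30,
    "sex": 0.10,
    "wt": 0.45,
    "occp_cod": 0.08,
    "reporter_country": 0.03,
    "event_dt": 0.35,
    "start_dt": 0.35,
}

SEX_DISTRIBUTION = {"F": 0.62, "M": 0.27, "UNK": 0.11}
OCCP_DISTRIBUTION = {"CN": 0.55, "MD": 0.27, "OT": 0.12, "PH": 0.045,
                     "LW": 0.005, "HP": 0.01}
COUNTRY_DISTRIBUTION = {"US": 0.58, "GB": 0.15, "DE": 0.12, "FR": 0.11,
                        "CA": 0.04}
OUTCOME_PROBS = {"DE": 0.06, "LT": 0.045, "HO": 0.28, "DS": 0.05,
                 "CA": 0.02, "RI": 0.01, "OT": 0.35}


@dataclass(frozen=True)
class SignalPair:
    """An injected drug-event association.

    ``lam`` is the relative reporting rate (>= 1); ``sex`` restricts the
    injection to one stratum (None = all cases), which lets subgroup
    analyses be validated against ground truth.
    """

    drug: int
    pt: int
    lam: float
    sex: str | None = None


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate a FAERS-scale quarter.

    Drug popularity falls off as 1/(g + 25) over ``n_drugs`` suspects
    (the target drug, index 0, receives about 3.6% of reports) and PT
    background weights as 1/(j + 5) over ``n_pts`` terms, so both
    vocabularies have the long-tailed shape of real reporting data.
    The onset mixture has a short-delay lognormal component (median
    ~7 days) and a long-delay component (median ~350 days), giving the
    bimodal early-peak / late-tail onset pattern seen in spontaneous
    reports.  Implausible ages (unit-entry artifacts in the tens of
    thousands) are injected at a small rate to force an explicit
    cleaning policy downstream.
    """

    n_cases: int = 20_000
    n_drugs: int = 50
    n_pts: int = 150
    n_socs: int = 15
    target_drug_index: int = 0
    target_drug_names: list[str] = field(
        default_factory=lambda: list(DEFAULT_TARGET_NAMES))
    background_pt_weights: np.ndarray | None = None  # default 1/(j+5), normalised
    drug_popularity: np.ndarray | None = None        # default 1/(g+25), normalised
    pts_per_case_mean: float = 1.5   # extra PTs ~ Poisson; each case has 1 + that
    signal_pairs: list[SignalPair] = field(default_factory=list)
    duplicate_rate: float = 0.05
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    sex_distribution: dict[str, float] = field(
        default_factory=lambda: dict(SEX_DISTRIBUTION))
    age_log_mean: float = math.log(45.0)
    age_log_sd: float = 0.45
    implausible_age_rate: float = 0.001
    weight_log_mean: float = math.log(72.0)
    weight_log_sd: float = 0.35
    onset_weight_short: float = 0.45
    onset_short_log_median: float = math.log(7.0)
    onset_short_log_sd: float = 1.0
    onset_long_log_median: float = math.log(350.0)
    onset_long_log_sd: float = 0.9
    partial_event_date_rate: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_drugs <= 0 or self.n_pts <= 0:
            raise ValueError("counts must be positive")
        for name, vec in (("background_pt_weights", self.pt_weights()),
                          ("drug_popularity", self.drug_weights())):
            if len(vec) not in (self.n_pts, self.n_drugs):
                raise ValueError(f"{name}: length inconsistent with config")
            if abs(float(np.sum(vec)) - 1.0) > 1e-9:
                raise ValueError(f"{name}: probabilities must sum to 1")
        for p in self.signal_pairs:
            if p.lam < 1.0:
                raise ValueError("injected relative rates must be >= 1")
            if not (0 <= p.drug < self.n_drugs and 0 <= p.pt < self.n_pts):
                raise ValueError("signal pair indices out of range")
        for k, v in self.missing_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missing rate {k} outside [0, 1]")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate outside [0, 1]")
        dist_sum = sum(self.sex_distribution.values())
        if abs(dist_sum - 1.0) > 1e-9:
            raise ValueError("sex_distribution must sum to 1")

    def pt_weights(self) -> np.ndarray:
        if self.background_pt_weights is not None:
            w = np.asarray(self.background_pt_weights, dtype=float)
        else:
            w = 1.0 / (np.arange(self.n_pts) + 5.0)
        return w / w.sum()

    def drug_weights(self) -> np.ndarray:
        if self.drug_popularity is not None:
            w = np.asarray(self.drug_popularity, dtype=float)
        else:
            w = 1.0 / (np.arange(self.n_drugs) + 25.0)
        return w / w.sum()

    def pt_name(self, j: int) -> str:
        return f"PT_{j:03d}"

    def soc_name(self, j: int) -> str:
        return f"SOC_{j % self.n_socs:02d}"

    def drug_name(self, g: int) -> str:
        if g == self.target_drug_index:
            return self.target_drug_names[0]
        return f"DRUG_{g:03d}"

    def meddra_map(self) -> MeddraMap:
        return MeddraMap({self.pt_name(j): self.soc_name(j)
                          for j in range(self.n_pts)})


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    lambda_map: dict[tuple[int, int], float]
    drug_names: dict[int, list[str]]  # index -> synonym list used in rows
    pt_names: dict[int, str]
    duplicate_lineage: dict[str, list[str]]  # caseid -> primaryids, in order

    def lambda_of(self, drug: int, pt: int) -> float:
        return self.lambda_map.get((drug, pt), 1.0)


def _fmt_date(d: dt.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def generate(config: SyntheticConfig) -> tuple[RawRecordSet, GroundTruth]:
    """Draw a full multi-table record set plus its ground truth.

    Cases are independent.  Each assigns one primary-suspect drug by the
    popularity distribution, draws its distinct PT set from background
    weights multiplied by the pair's lambda and renormalised, then
    appends demographics, outcome codes, therapy start and event dates
    consistent with the onset mixture.  Duplicates re-emit a case under
    a new PRIMARYID with a strictly larger FDA_DT (optionally filling a
    previously missing sex — "most current information").  Bit-identical
    under a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pt_w = config.pt_weights()
    drug_w = config.drug_weights()
    miss = config.missing_rates

    # per (drug, sex-stratum) lambda-adjusted PT weight rows, built lazily
    lam_global: dict[int, np.ndarray] = {}
    lam_by_sex: dict[tuple[int, str], np.ndarray] = {}

    def weights_for(g: int, sex: str) -> np.ndarray:
        sexed = [p for p in config.signal_pairs if p.drug == g and p.sex == sex]
        if sexed:
            key = (g, sex)
            if key not in lam_by_sex:
                lam_by_sex[key] = _adjusted_weights(config, pt_w, g, sex)
            return lam_by_sex[key]
        if g not in lam_global:
            lam_global[g] = _adjusted_weights(config, pt_w, g, None)
        return lam_global[g]

    sex_levels = list(config.sex_distribution)
    sex_probs = np.array([config.sex_distribution[s] for s in sex_levels])
    occp_levels = list(OCCP_DISTRIBUTION)
    occp_probs = np.array(list(OCCP_DISTRIBUTION.values()))
    occp_probs = occp_probs / occp_probs.sum()
    country_levels = list(COUNTRY_DISTRIBUTION)
    country_probs = np.array(list(COUNTRY_DISTRIBUTION.values()))
    country_probs = country_probs / country_probs.sum()

    n = config.n_cases
    drugs_of_case = rng.choice(config.n_drugs, size=n, p=drug_w)
    sexes = np.array(sex_levels)[rng.choice(len(sex_levels), size=n, p=sex_probs)]
    n_extra_pts = rng.poisson(config.pts_per_case_mean, size=n)
    start_offsets = rng.integers(0, 7000, size=n)
    is_short = rng.random(n) < config.onset_weight_short
    onset_raw = np.where(
        is_short,
        rng.lognormal(config.onset_short_log_median, config.onset_short_log_sd, n),
        rng.lognormal(config.onset_long_log_median, config.onset_long_log_sd, n),
    )
    onset_days = np.maximum(1, np.rint(onset_raw).astype(int))
    report_lags = rng.integers(3, 200, size=n)

    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows = [], [], [], [], []
    lineage: dict[str, list[str]] = {}
    truth_drug_names: dict[int, list[str]] = {}
    variants = config.target_drug_names

    for i in range(n):
        caseid = str(3_000_000 + i)
        pid = caseid + "1"
        g = int(drugs_of_case[i])
        sex = str(sexes[i])

        k = 1 + int(n_extra_pts[i])
        w = weights_for(g, sex)
        draws = rng.choice(config.n_pts, size=k, p=w)
        pts = sorted(set(int(j) for j in draws))

        start = EPOCH + dt.timedelta(days=int(start_offsets[i]))
        event = start + dt.timedelta(days=int(onset_days[i]) - 1)
        fda = event + dt.timedelta(days=int(report_lags[i]))

        age_missing = rng.random() < miss["age"]
        if rng.random() < config.implausible_age_rate:
            age_val, age_cod = f"{rng.integers(1000, 25000)}", "YR"
        else:
            years = rng.lognormal(config.age_log_mean, config.age_log_sd)
            # a slice of reports carries a non-year unit code
            u = rng.random()
            if u < 0.05:
                age_val, age_cod = f"{years * 12:.0f}", "MON"
            elif u < 0.08:
                age_val, age_cod = f"{years / 10:.1f}", "DEC"
            else:
                age_val, age_cod = f"{years:.0f}", "YR"
        wt_missing = rng.random() < miss["wt"]
        wt_val = f"{rng.lognormal(config.weight_log_mean, config.weight_log_sd):.1f}"
        sex_missing = rng.random() < miss["sex"]
        occp = str(np.array(occp_levels)[rng.choice(len(occp_levels), p=occp_probs)])
        if rng.random() < miss["occp_cod"]:
            occp = ""
        country = str(np.array(country_levels)[
            rng.choice(len(country_levels), p=country_probs)])
        if rng.random() < miss["reporter_country"]:
            country = ""
        event_str = _fmt_date(event)
        if rng.random() < miss["event_dt"]:
            event_str = ""
        elif rng.random() < config.partial_event_date_rate:
            event_str = event_str[:6]  # month precision
        start_str = _fmt_date(start)
        if rng.random() < miss["start_dt"]:
            start_str = ""

        sex_out = "" if sex_missing else ("" if sex == "UNK" else sex)
        demo_rows.append({
            "primaryid": pid, "caseid": caseid, "fda_dt": _fmt_date(fda),
            "event_dt": event_str,
            "age": "" if age_missing else age_val,
            "age_cod": "" if age_missing else age_cod,
            "sex": sex_out,
            "wt": "" if wt_missing else wt_val,
            "occp_cod": occp, "reporter_country": country,
        })

        if g == config.target_drug_index:
            name = variants[int(rng.integers(0, len(variants)))]
            if rng.random() < 0.3:
                name = name.upper()
        else:
            name = config.drug_name(g)
        truth_drug_names.setdefault(g, [])
        if name not in truth_drug_names[g]:
            truth_drug_names[g].append(name)
        case_drug = [{"primaryid": pid, "caseid": caseid, "drug_seq": "1",
                      "role_cod": "PS", "drugname": name}]
        case_ther = [{"primaryid": pid, "caseid": caseid,
                      "dsg_drug_seq": "1", "start_dt": start_str}]
        # concomitant medication rows
        for extra in range(int(rng.integers(0, 3))):
            og = int(rng.integers(0, config.n_drugs))
            if og == g:
                continue
            case_drug.append({
                "primaryid": pid, "caseid": caseid,
                "drug_seq": str(2 + extra),
                "role_cod": "C" if rng.random() < 0.7 else "SS",
                "drugname": config.drug_name(og),
            })
        case_reac = [{"primaryid": pid, "caseid": caseid,
                      "pt": config.pt_name(j)} for j in pts]
        case_outc = [{"primaryid": pid, "caseid": caseid, "outc_cod": code}
                     for code, p in OUTCOME_PROBS.items() if rng.random() < p]
        drug_rows.extend(case_drug)
        ther_rows.extend(case_ther)
        reac_rows.extend(case_reac)
        outc_rows.extend(case_outc)

        lineage[caseid] = [pid]
        if rng.random() < config.duplicate_rate:
            pid2 = caseid + "2"
            lineage[caseid].append(pid2)
            fda2 = fda + dt.timedelta(days=int(rng.integers(1, 400)))
            row2 = dict(demo_rows[-1])
            row2["primaryid"] = pid2
            row2["fda_dt"] = _fmt_date(fda2)
            if sex_missing and sex != "UNK":
                row2["sex"] = sex  # later submission completes the field
            demo_rows.append(row2)
            for src, dst in ((case_drug, drug_rows), (case_reac, reac_rows),
                             (case_outc, outc_rows), (case_ther, ther_rows)):
                for r in src:
                    r2 = dict(r)
                    r2["primaryid"] = pid2
                    dst.append(r2)

    records = RawRecordSet(
        demo=pd.DataFrame(demo_rows, dtype=str),
        drug=pd.DataFrame(drug_rows, dtype=str),
        reac=pd.DataFrame(reac_rows, dtype=str),
        outc=(pd.DataFrame(outc_rows, dtype=str) if outc_rows
              else RawRecordSet.empty().outc),
        ther=pd.DataFrame(ther_rows, dtype=str),
    )
    records.flag_orphans()
    truth = GroundTruth(
        lambda_map={(p.drug, p.pt): p.lam for p in config.signal_pairs},
        drug_names=truth_drug_names,
        pt_names={j: config.pt_name(j) for j in range(config.n_pts)},
        duplicate_lineage=lineage,
    )
    return records, truth


def _adjusted_weights(config: SyntheticConfig, pt_w: np.ndarray, g: int,
                      sex: str | None) -> np.ndarray:
    w = pt_w.copy()
    for p in config.signal_pairs:
        if p.drug != g:
            continue
        if p.sex is None or p.sex == sex:
            w[p.pt] *= p.lam
    return w / w.sum()


def realized_rates(records: RawRecordSet, truth: GroundTruth,
                   config: SyntheticConfig) -> pd.DataFrame:
    """Empirical observed/expected ratio per injected pair.

    Deduplicates, assembles cases and counts at report level; the
    empirical rate is a / E with E = (a+b)(a+c)/N, and the Monte-Carlo
    standard error treats a as Poisson: SE(rate) ~= sqrt(a) / E.
    """
    from .preprocess import assemble_cases, deduplicate

    cases, _ = assemble_cases(deduplicate(records))
    n = len(cases)
    rows = []
    for (g, j), lam in sorted(truth.lambda_map.items()):
        names = {_norm_name(s) for s in truth.drug_names.get(g, [])}
        names |= {_norm_name(config.drug_name(g))}
        if g == config.target_drug_index:
            names |= {_norm_name(s) for s in config.target_drug_names}
        pt = truth.pt_names[j]
        a = b = c = d = 0
        for case in cases:
            exposed = any(_norm_name(dr.name) in names and dr.role == "PS"
                          for dr in case.drugs)
            has_pt = pt in case.reactions
            if exposed and has_pt:
                a += 1
            elif exposed:
                b += 1
            elif has_pt:
                c += 1
            else:
                d += 1
        e = (a + b) * (a + c) / n if n else 0.0
        rate = a / e if e > 0 else float("nan")
        se = math.sqrt(a) / e if e > 0 else float("nan")
        rows.append((g, j, pt, lam, a, e, rate, se))
    return pd.DataFrame(rows, columns=["drug", "pt_index", "pt", "lam",
                                       "a", "E", "rate", "se"])


def with_signals(config: SyntheticConfig,
                 pairs: Sequence[tuple[int, int, float]]) -> SyntheticConfig:
    """Convenience copy of a config with (drug, pt, lambda) signals added."""
    return replace(config, signal_pairs=list(config.signal_pairs)
                   + [SignalPair(g, j, lam) for g, j, lam in pairs])
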