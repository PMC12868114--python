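"""Disproportionality statistics for 2x2 report tables.

For one drug-event pair over a universe of N deduplicated reports the
2x2 table is

    a = reports with the drug and the event      b = drug, no event
    c = event, no drug                           d = neither

and E = (a+b)(a+c)/N is the count expected in cell ``a`` under
independence.  Four statistics are computed on such tables:

* ROR, the reporting odds ratio ad/bc with a log-normal 95% CI;
* PRR, the proportional reporting ratio with its log CI, accompanied by
  a Yates-corrected Pearson chi-square;
* the BCPNN information component IC = log2 of a shrunk
  observed-to-expected ratio, with its lower credibility bound IC025;
* EBGM, the empirical Bayes geometric mean under DuMouchel's
  gamma-Poisson shrinker (a ~ Poisson(lambda*E) with a two-component
  gamma mixture prior on lambda), with its 5th posterior percentile
  EBGM05.

The frequentist pair is sensitive for common events; the two Bayesian
statistics shrink low-count cells toward independence and so damp the
false positives that raw ratios produce at small a.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .preprocess import CaseReport, MatchLevel, match_target_drug, _norm_name

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Independence-expected count for cell a: (a+b)(a+c)/N."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class NonEstimable:
    """A statistic that cannot be computed for this table, with reason."""

    reason: str


@dataclass(frozen=True)
class RatioEstimate:
    point: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class IcEstimate:
    ic: float
    ic025: float


@dataclass(frozen=True)
class GpsPrior:
    """Hyperparameters of the two-component gamma mixture prior.

    lambda ~ w * Gamma(alpha1, rate beta1) + (1-w) * Gamma(alpha2, rate beta2)
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixture weight must lie in (0, 1)")

    @property
    def mean(self) -> float:
        return (self.w * self.alpha1 / self.beta1
                + (1.0 - self.w) * self.alpha2 / self.beta2)


# canonical optimisation start (DuMouchel); also the diffuse fallback prior
DEFAULT_PRIOR_START = GpsPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0,
                               w=1.0 / 3.0)


@dataclass(frozen=True)
class EbgmEstimate:
    ebgm: float
    ebgm05: float


def ror(t: ContingencyTable) -> RatioEstimate | NonEstimable:
    """Reporting odds ratio ad/bc with log-method 95% CI.

    Any zero cell makes the odds ratio or its variance undefined; such
    tables are returned as non-estimable rather than patched with a
    continuity correction — the signal rule's n >= 3 floor makes a
    correction pointless for screening.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return NonEstimable("zero cell: ROR undefined without correction")
    point = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return RatioEstimate(point,
                         point * math.exp(-Z95 * se),
                         point * math.exp(Z95 * se))


def prr(t: ContingencyTable) -> RatioEstimate | NonEstimable:
    """Proportional reporting ratio with log-method 95% CI.

    PRR = [a/(a+b)] / [c/(c+d)].  Needs c > 0; a = 0 is estimable and
    returns a degenerate zero estimate (such a pair can never signal).
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        return NonEstimable("empty margin")
    if t.c == 0:
        return NonEstimable("no comparator reports with the event")
    if t.a == 0:
        return RatioEstimate(0.0, 0.0, 0.0)
    point = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    return RatioEstimate(point,
                         point * math.exp(-Z95 * se),
                         point * math.exp(Z95 * se))


def chi_square(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the 2x2 table, Yates-corrected by default.

    The continuity correction subtracts 0.5 from each |O - E| deviation,
    clamped at zero so tiny deviations cannot produce a negative term.
    Returns 0 for any zero margin (the statistic is undefined there).
    """
    n = t.n
    if n == 0:
        return 0.0
    rows = (t.a + t.b, t.c + t.d)
    cols = (t.a + t.c, t.b + t.d)
    if 0 in rows or 0 in cols:
        return 0.0
    observed = (t.a, t.b, t.c, t.d)
    expected = (rows[0] * cols[0] / n, rows[0] * cols[1] / n,
                rows[1] * cols[0] / n, rows[1] * cols[1] / n)
    total = 0.0
    for o, e in zip(observed, expected):
        dev = abs(o - e)
        if yates:
            dev = max(dev - 0.5, 0.0)
        total += dev * dev / e
    return total


def bcpnn_ic(t: ContingencyTable, variant: str = "shrunk") -> IcEstimate:
    """BCPNN information component with lower 95% credibility bound.

    ``variant="shrunk"`` (default) is the closed form in wide use:
    IC = log2((a + 0.5) / (E + 0.5)) with delta-method variance
    (1/(a+0.5)) / ln(2)^2.  ``variant="moment"`` is the original
    Dirichlet moment construction (Bate et al.'s expectation/variance of
    the posterior IC).  The two agree to within about 0.1 bit once
    a >= 10.  Shrinkage makes every table estimable.
    """
    if variant == "shrunk":
        e = t.expected
        ic = math.log2((t.a + 0.5) / (e + 0.5))
        sd = math.sqrt(1.0 / (t.a + 0.5)) / LN2
        return IcEstimate(ic, ic - Z95 * sd)
    if variant == "moment":
        n = max(t.n, 1)
        c11, c1_, c_1 = t.a, t.a + t.b, t.a + t.c
        # Dirichlet hyperparameters of the original construction
        a1 = b1 = 1.0
        aa = bb = 2.0
        g11 = 1.0
        gg = g11 * (n + aa) * (n + bb) / ((c1_ + a1) * (c_1 + b1))
        ic = math.log2((c11 + g11) * (n + aa) * (n + bb)
                       / ((n + gg) * (c1_ + a1) * (c_1 + b1)))
        var = ((n - c11 + gg - g11) / ((c11 + g11) * (1 + n + gg))
               + (n - c1_ + aa - a1) / ((c1_ + a1) * (1 + n + aa))
               + (n - c_1 + bb - b1) / ((c_1 + b1) * (1 + n + bb))) / LN2 ** 2
        return IcEstimate(ic, ic - Z95 * math.sqrt(var))
    raise ValueError(f"unknown BCPNN variant {variant!r}")


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float,
               beta: float) -> np.ndarray:
    """Log marginal P(a | E) when lambda ~ Gamma(alpha, rate beta).

    The gamma-Poisson marginal is negative binomial with size alpha and
    success probability beta/(beta+E).
    """
    return (special.gammaln(alpha + a) - special.gammaln(alpha)
            - special.gammaln(a + 1.0)
            + alpha * (np.log(beta) - np.log(beta + e))
            + a * (np.log(e) - np.log(beta + e)))


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    # np.exp (not math.exp) so that extreme line-search probes yield
    # inf/nan -- which the optimiser backtracks from -- instead of raising
    la1, lb1, la2, lb2, lw = theta
    with np.errstate(over="ignore", invalid="ignore"):
        alpha1, beta1 = float(np.exp(la1)), float(np.exp(lb1))
        alpha2, beta2 = float(np.exp(la2)), float(np.exp(lb2))
        w = float(special.expit(lw))
    if not all(np.isfinite(v) and v > 0 for v in (alpha1, beta1, alpha2, beta2)):
        return -np.inf
    if not 0.0 < w < 1.0:
        return -np.inf
    lf1 = _nb_logpmf(a, e, alpha1, beta1) + math.log(w)
    lf2 = _nb_logpmf(a, e, alpha2, beta2) + math.log1p(-w)
    ll = float(np.sum(np.logaddexp(lf1, lf2)))
    return ll if np.isfinite(ll) else -np.inf


@dataclass
class GpsFitResult:
    prior: GpsPrior
    loglik: float
    converged: bool
    n_pairs: int
    fallback: bool = False
    message: str = ""


def gps_fit(counts: Iterable[tuple[float, float]] | pd.DataFrame,
            min_pairs: int = 100,
            start: GpsPrior = DEFAULT_PRIOR_START) -> GpsFitResult:
    """Fit the MGPS prior by direct marginal-likelihood maximisation.

    ``counts`` holds one (a, E) pair per drug-event combination over the
    whole universe.  The five hyperparameters are optimised on the
    unconstrained scale (log for shapes/rates, logit for the weight)
    from the canonical start, which makes the fit deterministic without
    stochastic restarts.  With fewer than ``min_pairs`` pairs having
    a >= 1 the likelihood is too flat to identify a mixture, so the fit
    refuses and falls back to the fixed diffuse starting prior (logged).
    """
    if isinstance(counts, pd.DataFrame):
        arr = counts[["a", "E"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        arr = arr.reshape(0, 2)
    mask = (arr[:, 1] > 0)
    arr = arr[mask]
    a, e = arr[:, 0], arr[:, 1]
    n_pos = int(np.sum(a >= 1))
    if n_pos < min_pairs:
        logger.warning("gps_fit: only %d pairs with a>=1 (<%d); "
                       "using diffuse fallback prior", n_pos, min_pairs)
        ll = _mixture_loglik(_theta_of(start), a, e) if len(a) else float("nan")
        return GpsFitResult(prior=start, loglik=ll, converged=False,
                            n_pairs=len(a), fallback=True,
                            message="insufficient pairs; diffuse prior")

    theta0 = _theta_of(start)
    with np.errstate(invalid="ignore", over="ignore"):
        res = optimize.minimize(
            lambda th: -_mixture_loglik(th, a, e), theta0,
            method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
    la1, lb1, la2, lb2, lw = res.x
    w = float(special.expit(lw))
    # keep w off the boundary; a pinned weight collapses to one component
    if w < 1e-6 or w > 1 - 1e-6:
        logger.warning("gps_fit: mixture weight pinned at boundary (w=%.2g)", w)
        w = min(max(w, 1e-6), 1 - 1e-6)
    prior = GpsPrior(math.exp(la1), math.exp(lb1),
                     math.exp(la2), math.exp(lb2), w)
    return GpsFitResult(prior=prior, loglik=-res.fun, converged=bool(res.success),
                        n_pairs=len(a),
                        message=str(res.message))


def _theta_of(p: GpsPrior) -> np.ndarray:
    return np.array([math.log(p.alpha1), math.log(p.beta1),
                     math.log(p.alpha2), math.log(p.beta2),
                     special.logit(p.w)])


def _posterior_mixture(a: float, e: float, prior: GpsPrior,
                       ) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Posterior of lambda given (a, E): weight q1 and two gamma components.

    Conjugacy updates each component to Gamma(alpha_j + a, beta_j + E);
    the posterior mixing weight of component 1 is proportional to the
    prior weight times its negative-binomial evidence for a.
    """
    av, ev = np.array([a], dtype=float), np.array([e], dtype=float)
    l1 = float(_nb_logpmf(av, ev, prior.alpha1, prior.beta1)[0]) + math.log(prior.w)
    l2 = float(_nb_logpmf(av, ev, prior.alpha2, prior.beta2)[0]) + math.log1p(-prior.w)
    q1 = math.exp(l1 - np.logaddexp(l1, l2))
    return q1, (prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a, prior.beta2 + e)


def ebgm(t: ContingencyTable | tuple[float, float],
         prior: GpsPrior) -> EbgmEstimate:
    """Empirical Bayes geometric mean and its 5th posterior percentile.

    EBGM = 2^{E[log2 lambda | a, E]} computed in closed form from the
    digamma function of the posterior gamma mixture; EBGM05 solves the
    posterior CDF = 0.05 by bracketed root-finding to 1e-10.
    """
    if isinstance(t, ContingencyTable):
        a, e = float(t.a), t.expected
    else:
        a, e = float(t[0]), float(t[1])
    if e <= 0:
        raise ValueError("EBGM requires a positive expected count")
    q1, (s1, r1), (s2, r2) = _posterior_mixture(a, e, prior)
    mean_log = (q1 * (special.digamma(s1) - math.log(r1))
                + (1 - q1) * (special.digamma(s2) - math.log(r2)))
    point = math.exp(mean_log)

    g1 = stats.gamma(s1, scale=1.0 / r1)
    g2 = stats.gamma(s2, scale=1.0 / r2)

    def cdf(x: float) -> float:
        return q1 * g1.cdf(x) + (1 - q1) * g2.cdf(x)

    lo = min(g1.ppf(1e-3), g2.ppf(1e-3))
    hi = max(g1.ppf(0.5), g2.ppf(0.5))
    q05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-10)
    return EbgmEstimate(ebgm=point, ebgm05=float(q05))


# ---------------------------------------------------------------------------
# table construction over a universe of CaseReports

def _case_pts(case: CaseReport) -> set[str]:
    return set(case.reactions)


def build_table(cases: Sequence[CaseReport], target_names: Sequence[str],
                pt: str) -> ContingencyTable:
    """2x2 table for one (target drug, PT) pair, counting reports.

    The exposed margin a+b is the reports where the target drug is the
    primary suspect; a+c is the reports mentioning the PT at least once
    (repeated PT rows in one report count once).  A PT absent from the
    universe yields a = c = 0, which is a valid (if uninformative) table.
    """
    a = b = c = d = 0
    for case in cases:
        exposed = match_target_drug(case, target_names) is MatchLevel.PRIMARY_SUSPECT
        has_pt = pt in _case_pts(case)
        if exposed and has_pt:
            a += 1
        elif exposed:
            b += 1
        elif has_pt:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def build_all_tables(cases: Sequence[CaseReport],
                     target_names: Sequence[str]) -> pd.DataFrame:
    """Tables for every PT in the universe: columns pt, a, b, c, d, E."""
    n = len(cases)
    exposed_flags = [match_target_drug(c, target_names) is MatchLevel.PRIMARY_SUSPECT
                     for c in cases]
    n_exposed = sum(exposed_flags)
    a_counts: dict[str, int] = {}
    pt_totals: dict[str, int] = {}
    for case, exposed in zip(cases, exposed_flags):
        for pt in _case_pts(case):
            pt_totals[pt] = pt_totals.get(pt, 0) + 1
            if exposed:
                a_counts[pt] = a_counts.get(pt, 0) + 1
    rows = []
    for pt in sorted(pt_totals):
        a = a_counts.get(pt, 0)
        apc = pt_totals[pt]
        b = n_exposed - a
        c = apc - a
        d = n - n_exposed - c
        rows.append((pt, a, b, c, d, (a + b) * (a + c) / n if n else 0.0))
    return pd.DataFrame(rows, columns=["pt", "a", "b", "c", "d", "E"])


def all_pair_tables(cases: Sequence[CaseReport]) -> pd.DataFrame:
    """Full 2x2 tables for every (primary-suspect drug, PT) pair.

    Columns: drug, pt, a, b, c, d, E.  Report-level counting; a case
    with several PS drugs contributes to each of their margins.
    """
    n = len(cases)
    drug_totals: dict[str, int] = {}
    pt_totals: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for case in cases:
        ps_drugs = {_norm_name(d.name) for d in case.drugs if d.role == "PS"}
        pts = _case_pts(case)
        for g in ps_drugs:
            drug_totals[g] = drug_totals.get(g, 0) + 1
        for pt in pts:
            pt_totals[pt] = pt_totals.get(pt, 0) + 1
        for g in ps_drugs:
            for pt in pts:
                pair_counts[(g, pt)] = pair_counts.get((g, pt), 0) + 1
    rows = []
    for (g, pt), a in sorted(pair_counts.items()):
        ng, npt = drug_totals[g], pt_totals[pt]
        rows.append((g, pt, a, ng - a, npt - a, n - ng - npt + a,
                     ng * npt / n))
    return pd.DataFrame(rows, columns=["drug", "pt", "a", "b", "c", "d", "E"])


def screen_all_pairs(tables: pd.DataFrame, prior: GpsPrior,
                     use_chi2_with_prr: bool = True) -> pd.DataFrame:
    """Vectorised four-method signal screen over many 2x2 tables.

    Applies the same criteria as the per-PT path — ROR lower CI > 1 with
    n >= 3; PRR >= 2 with Yates chi-square >= 4 and n >= 3; IC025 > 0;
    EBGM05 > 2 — to every row of an :func:`all_pair_tables` frame.  The
    EBGM05 flag is evaluated without root-finding: EBGM05 > 2 exactly
    when the posterior mixture CDF at 2 is below 0.05.
    """
    a = tables["a"].to_numpy(dtype=float)
    b = tables["b"].to_numpy(dtype=float)
    c = tables["c"].to_numpy(dtype=float)
    d = tables["d"].to_numpy(dtype=float)
    e = tables["E"].to_numpy(dtype=float)
    n_tot = a + b + c + d

    with np.errstate(divide="ignore", invalid="ignore"):
        pos = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        ror_pt = np.where(pos, a * d / np.where(pos, b * c, 1.0), np.nan)
        ror_se = np.sqrt(np.where(pos, 1 / np.where(a > 0, a, 1)
                                  + 1 / np.where(b > 0, b, 1)
                                  + 1 / np.where(c > 0, c, 1)
                                  + 1 / np.where(d > 0, d, 1), np.nan))
        ror_low = ror_pt * np.exp(-Z95 * ror_se)
        flag_ror = (a >= 3) & pos & (ror_low > 1.0)

        prr_ok = (a > 0) & (c > 0)
        prr_pt = np.where(prr_ok,
                          (a / (a + b)) / np.where(prr_ok, c / (c + d), 1.0),
                          np.where(a == 0, 0.0, np.nan))

        rows1, rows0 = a + b, c + d
        cols1, cols0 = a + c, b + d
        exp_a = rows1 * cols1 / n_tot
        exp_b = rows1 * cols0 / n_tot
        exp_c = rows0 * cols1 / n_tot
        exp_d = rows0 * cols0 / n_tot
        chi2 = np.zeros_like(a)
        valid = (rows1 > 0) & (rows0 > 0) & (cols1 > 0) & (cols0 > 0)
        for o, ex in ((a, exp_a), (b, exp_b), (c, exp_c), (d, exp_d)):
            dev = np.maximum(np.abs(o - ex) - 0.5, 0.0)
            chi2 += np.where(valid, dev * dev / np.where(ex > 0, ex, 1.0), 0.0)
        flag_prr = (a >= 3) & prr_ok & (prr_pt >= 2.0)
        if use_chi2_with_prr:
            flag_prr &= chi2 >= 4.0

        ic = np.log2((a + 0.5) / (e + 0.5))
        ic025 = ic - Z95 * np.sqrt(1.0 / (a + 0.5)) / LN2
        flag_ic = ic025 > 0.0

        l1 = _nb_logpmf(a, e, prior.alpha1, prior.beta1) + math.log(prior.w)
        l2 = _nb_logpmf(a, e, prior.alpha2, prior.beta2) + math.log1p(-prior.w)
        q1 = np.exp(l1 - np.logaddexp(l1, l2))
        s1, r1 = prior.alpha1 + a, prior.beta1 + e
        s2, r2 = prior.alpha2 + a, prior.beta2 + e
        ebgm_pt = np.exp(q1 * (special.digamma(s1) - np.log(r1))
                         + (1 - q1) * (special.digamma(s2) - np.log(r2)))
        cdf_at_2 = (q1 * special.gammainc(s1, 2.0 * r1)
                    + (1 - q1) * special.gammainc(s2, 2.0 * r2))
        flag_ebgm = cdf_at_2 < 0.05

    out = tables.copy()
    out["ror"] = ror_pt
    out["ror_low"] = ror_low
    out["prr"] = prr_pt
    out["chi2"] = chi2
    out["ic"] = ic
    out["ic025"] = ic025
    out["ebgm"] = ebgm_pt
    out["flag_ror"] = flag_ror
    out["flag_prr"] = flag_prr
    out["flag_ic"] = flag_ic
    out["flag_ebgm"] = flag_ebgm
    out["meets_all_four"] = flag_ror & flag_prr & flag_ic & flag_ebgm
    return out


def drug_event_counts(cases: Sequence[CaseReport]) -> pd.DataFrame:
    """(a, E) for every (primary-suspect drug, PT) pair in the universe.

    This is the input to :func:`gps_fit`: the MGPS prior is estimated
    from the whole database's pair counts, not only the target drug's.
    Drug identity is the normalised name of each PS-role row.
    """
    return all_pair_tables(cases)[["drug", "pt", "a", "E"]]
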