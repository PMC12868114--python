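"""Independent numerical oracles used by several test modules.

The EBGM oracle integrates the posterior of the relative reporting rate
by brute-force quadrature of density(lambda) proportional to
prior_pdf(lambda) * Poisson(a; lambda * E), with no use of gamma-Poisson
conjugacy, so it checks the closed-form implementation along a genuinely
different computational path.  Integration runs in u = log(lambda) to
tame the gamma density's singularity at zero for shape < 1.
"""

import numpy as np
from scipy import integrate, optimize, stats


def prior_pdf(lam, prior):
    g1 = stats.gamma(prior.alpha1, scale=1.0 / prior.beta1)
    g2 = stats.gamma(prior.alpha2, scale=1.0 / prior.beta2)
    return prior.w * g1.pdf(lam) + (1 - prior.w) * g2.pdf(lam)


def ebgm_by_quadrature(a, e, prior):
    """(ebgm, ebgm05) by direct integration of the posterior."""

    def f_log(u):
        lam = np.exp(u)
        return prior_pdf(lam, prior) * stats.poisson.pmf(a, lam * e) * lam

    ratio = (a + 1.0) / max(e, 1e-3)
    # lo must sit far below any gamma quantile: for shape < 1 the lower
    # tail decays only like lambda**shape, so truncating high biases the
    # mean of log(lambda) upward
    lo = -80.0
    hi = np.log(max(50.0, 20.0 * ratio))
    # adaptive quadrature needs hints: the posterior peak is narrow
    # (width ~ 1/sqrt(a)) inside a ~90-unit log interval
    u_mode = float(np.log(max(ratio, 1e-3)))
    peak_pts = [u_mode - 5.0, u_mode - 1.0, u_mode, u_mode + 1.0,
                u_mode + 5.0]

    def _quad(g, u_lo, u_hi):
        pts = [p for p in peak_pts if u_lo < p < u_hi]
        v, _ = integrate.quad(g, u_lo, u_hi, limit=400, points=pts or None,
                              epsabs=0.0, epsrel=1e-10)
        return v

    z = _quad(f_log, lo, hi)
    mlog = _quad(lambda u: u * f_log(u), lo, hi)
    ebgm = float(np.exp(mlog / z))

    def cdf(x):
        return _quad(f_log, lo, np.log(x)) / z

    q05 = optimize.brentq(lambda x: cdf(x) - 0.05, np.exp(lo + 1), np.exp(hi),
                          xtol=1e-13, rtol=1e-12)
    return ebgm, float(q05)
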