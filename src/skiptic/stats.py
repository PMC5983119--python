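"""Shared statistical helpers: FDR control, signed z-scores and the
beta-binomial likelihood machinery behind the differential splicing test."""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

_P_FLOOR = 1e-300


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate, excluded from
    the family)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def signed_z(effect_sign, pvalues) -> np.ndarray:
    """sign(effect) * Phi^{-1}(1 - p/2): a standardized signed effect used
    for cross-dataset concordance plots."""
    p = np.clip(np.asarray(pvalues, dtype=float), _P_FLOOR, 1.0)
    z = stats.norm.isf(p / 2.0)
    return np.sign(np.asarray(effect_sign, dtype=float)) * z


def betabinom_logpmf(x, n, mu, rho):
    """Log pmf of the beta-binomial with mean ``mu`` and intra-class
    correlation ``rho`` (a = mu(1-rho)/rho, b = (1-mu)(1-rho)/rho)."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-12, 1 - 1e-12)
    rho = np.clip(rho, 1e-9, 1 - 1e-9)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return (
        special.gammaln(n + 1)
        - special.gammaln(x + 1)
        - special.gammaln(n - x + 1)
        + special.betaln(x + a, n - x + b)
        - special.betaln(a, b)
    )


def betabinom_profile_mu(x, n, rho, mask=None, n_iter: int = 60):
    """Profile the beta-binomial log-likelihood over ``mu`` per row.

    ``x``/``n`` are (events, samples) arrays; ``mask`` marks informative
    samples.  Returns (mu_hat, loglik) per event, via golden-section search
    on the logit scale (the likelihood is unimodal in mu for fixed rho).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    if mask is None:
        mask = n > 0
    mask = np.atleast_2d(mask)

    def nll(theta):
        mu = special.expit(theta)[:, None]
        ll = betabinom_logpmf(x, n, mu, rho)
        return -np.where(mask, ll, 0.0).sum(axis=1)

    lo = np.full(x.shape[0], -14.0)
    hi = np.full(x.shape[0], 14.0)
    invphi = (np.sqrt(5.0) - 1) / 2
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = nll(c), nll(d)
    for _ in range(n_iter):
        left = fc < fd
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
        c_new = hi - invphi * (hi - lo)
        d_new = lo + invphi * (hi - lo)
        # only one endpoint moves per row; evaluate both (vectorized, cheap)
        fc_new, fd_new = nll(c_new), nll(d_new)
        c, d, fc, fd = c_new, d_new, fc_new, fd_new
    theta = (lo + hi) / 2
    mu = special.expit(theta)
    return mu, -nll(theta)


def betabinom_rho_mom(x, n, groups, mask=None):
    """Shared method-of-moments overdispersion across events.

    For each event/condition with >= 2 informative replicates, the binomial
    dispersion statistic sum((x - n*p)^2 / (n*p*(1-p))) has expectation
    (m-1) * (1 + rho*(nbar - 1)) under the beta-binomial; solving on the
    pooled statistic gives a single shared rho.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if mask is None:
        mask = n > 0
    chi_tot, df_tot, nsum, nct = 0.0, 0.0, 0.0, 0
    for g in np.unique(groups):
        sel = np.asarray(groups) == g
        xg, ng, mg = x[:, sel], n[:, sel], mask[:, sel]
        m = mg.sum(axis=1)
        nsafe = np.where(mg, ng, 0.0)
        xs = np.where(mg, xg, 0.0)
        tot = nsafe.sum(axis=1)
        ok = (m >= 2) & (tot > 0)
        p = np.where(tot > 0, xs.sum(axis=1) / np.maximum(tot, 1), 0.5)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = (xg - ng * p[:, None]) ** 2 / (ng * p[:, None] * (1 - p[:, None]))
        contrib = np.where(mg & (ng > 0), contrib, 0.0)
        chi = contrib.sum(axis=1)
        chi_tot += chi[ok].sum()
        df_tot += (m[ok] - 1).sum()
        nbar = np.where(m > 0, nsafe.sum(axis=1) / np.maximum(m, 1), 0.0)
        nsum += (nbar[ok] * (m[ok] - 1)).sum()
        nct += int(ok.sum())
    if df_tot <= 0 or nsum <= df_tot:
        return 1e-6
    nbar_w = nsum / df_tot
    rho = (chi_tot / df_tot - 1.0) / (nbar_w - 1.0)
    return float(np.clip(rho, 1e-6, 0.5))


def binomial_tail_p(k: int, n: int, rate: float) -> float:
    """One-sided upper binomial tail P(X >= k) for X ~ Binomial(n, rate)."""
    if n == 0:
        return float("nan")
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, rate))


def pearson_chi2(table):
    """Pearson chi-squared (no continuity correction) on a 2x2 (or RxC)
    table; returns (statistic, p).  Zero row/column margins are an error."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DataErrorZeroMargin("chi-squared undefined: zero row/column margin")
    expected = np.outer(rows, cols) / t.sum()
    statistic = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return statistic, float(stats.chi2.sf(statistic, df))


class DataErrorZeroMargin(ValueError):
    pass
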