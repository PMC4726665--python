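"""Beta-uniform mixture (BUM) modeling of a p-value distribution.

The combined p-values of all genes are modeled as a mixture of uniform
noise and a decreasing beta(a, 1) signal component:

    f(p) = lam + (1 - lam) * a * p**(a - 1),   0 < p <= 1,  0 < a < 1.

From the fit, an FDR level tau(fdr) on the p-value scale converts each
gene's p into an additive node score

    S(p) = (a - 1) * (ln p - ln tau),

positive for p < tau and negative above — the currency of the
maximum-scoring subnetwork search.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .datatypes import BumFit

EPS = 1e-5
_LAM_STARTS = (0.3, 0.5, 0.7, 0.9)
_A_STARTS = (0.1, 0.3, 0.5, 0.7)


def bum_density(p: np.ndarray, lam: float, a: float) -> np.ndarray:
    return lam + (1.0 - lam) * a * np.power(p, a - 1.0)


def bum_log_likelihood(p: np.ndarray, lam: float, a: float) -> float:
    return float(np.sum(np.log(bum_density(p, lam, a))))


def _neg_ll_and_grad(theta: np.ndarray, logp: np.ndarray) -> tuple[float, np.ndarray]:
    lam, a = theta
    pa1 = np.exp((a - 1.0) * logp)  # p**(a-1)
    f = lam + (1.0 - lam) * a * pa1
    nll = -np.sum(np.log(f))
    dlam = -(1.0 - a * pa1) / f
    da = -(1.0 - lam) * pa1 * (1.0 + a * logp) / f
    return nll, np.array([np.sum(dlam), np.sum(da)])


def fit_bum(p_values, min_n: int = 100) -> BumFit:
    """Maximum-likelihood BUM fit by bounded quasi-Newton from a start grid.

    Requires at least ``min_n`` p-values in (0, 1]; both parameters are
    constrained to (EPS, 1 - EPS) and the best of 16 multi-starts wins.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < min_n:
        raise ValueError(f"need >= {min_n} p-values for a stable mixture fit")

    logp = np.log(p)
    bounds = [(EPS, 1.0 - EPS)] * 2
    best = None
    for lam0 in _LAM_STARTS:
        for a0 in _A_STARTS:
            res = minimize(
                _neg_ll_and_grad, x0=np.array([lam0, a0]), args=(logp,),
                jac=True, method="L-BFGS-B", bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
    lam, a = best.x
    return BumFit(lam=float(lam), a=float(a), log_lik=float(-best.fun), n_pvalues=p.size)


def sample_bum(n: int, lam: float, a: float, rng: np.random.Generator) -> np.ndarray:
    """Draw p-values from the mixture (uniform with prob lam, else Beta(a, 1))."""
    u = rng.uniform(size=n)
    is_null = rng.uniform(size=n) < lam
    signal = np.power(rng.uniform(size=n), 1.0 / a)  # Beta(a,1) via inverse CDF
    return np.where(is_null, u, signal)


def score_threshold(fit: BumFit, fdr: float) -> float:
    """p-value threshold tau(fdr) at which the node score crosses zero."""
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    pi = fit.pi0
    num = pi - fdr * fit.lam
    if num <= 0:
        raise ValueError(
            "degenerate threshold: pi0 <= fdr * lambda; use a larger fdr level"
        )
    tau = (num / (fdr * (1.0 - fit.lam))) ** (1.0 / (fit.a - 1.0))
    tiny = np.nextafter(0, 1)
    return float(np.clip(tau, tiny, 1.0 - 1e-12))


def score_pvalues(p_values, fit: BumFit, fdr: float) -> np.ndarray:
    """Additive node scores S(p) = (a - 1) * (ln p - ln tau(fdr))."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    tau = score_threshold(fit, fdr)
    return (fit.a - 1.0) * (np.log(p) - np.log(tau))
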