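"""Independent oracles used only by the test suite.

Each oracle recomputes a quantity by a route disjoint from the package
implementation: exhaustive enumeration for Fisher's test, combinatorial
tail probabilities plus bisection for the exact-conditional CI, direct
formula evaluation for the Wald CI, and dense 2-D quadrature over
(intercept, slope) for the Bayesian posterior.
"""

from __future__ import annotations

from math import comb, exp, log, sqrt

import numpy as np
from scipy.stats import norm


def fisher_enum_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by exhaustive enumeration of all tables with
    the observed margins (probability-mass rule, relative slack 1e-7 as
    in standard software)."""
    n1, n2, m = a + b, c + d, a + c
    lo, hi = max(0, m - n2), min(m, n1)
    total = comb(n1 + n2, m)
    probs = {x: comb(n1, x) * comb(n2, m - x) / total for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def wald_ci(a: int, b: int, c: int, d: int, level: float) -> tuple[float, float]:
    z = norm.ppf(0.5 + level / 2)
    lo = log(a * d / (b * c)) - z * sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    hi = log(a * d / (b * c)) + z * sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return exp(lo), exp(hi)


def _nchg_tails(a: int, n1: int, n2: int, m: int, psi: float) -> tuple[float, float]:
    """(P(X >= a), P(X <= a)) under Fisher's noncentral hypergeometric
    law with odds psi, from binomial coefficients directly."""
    lo, hi = max(0, m - n2), min(m, n1)
    log_psi = log(psi)
    logs = [
        log(comb(n1, x)) + log(comb(n2, m - x)) + x * log_psi for x in range(lo, hi + 1)
    ]
    mx = max(logs)
    w = np.exp(np.array(logs) - mx)
    w /= w.sum()
    xs = np.arange(lo, hi + 1)
    return float(w[xs >= a].sum()), float(w[xs <= a].sum())


def exact_conditional_ci(
    a: int, b: int, c: int, d: int, level: float, tol: float = 1e-10
) -> tuple[float, float]:
    """Exact-conditional CI by bisection on the enumerated tail
    probabilities (grid-search bracketing, then interval halving)."""
    n1, n2, m = a + b, c + d, a + c
    lo_sup, hi_sup = max(0, m - n2), min(m, n1)
    alpha = (1 - level) / 2

    def solve(tail_index: int, target: float, increasing: bool) -> float:
        lo_lp, hi_lp = -60.0, 60.0
        for _ in range(200):
            mid = 0.5 * (lo_lp + hi_lp)
            val = _nchg_tails(a, n1, n2, m, exp(mid))[tail_index]
            if (val < target) == increasing:
                lo_lp = mid
            else:
                hi_lp = mid
            if hi_lp - lo_lp < tol:
                break
        return exp(0.5 * (lo_lp + hi_lp))

    lower = 0.0 if a == lo_sup else solve(0, alpha, increasing=True)
    upper = float("inf") if a == hi_sup else solve(1, alpha, increasing=False)
    return lower, upper


class QuadraturePosterior:
    """Dense-grid posterior over (intercept, slope) for one 2x2 table.

    Grid extents come from smoothed empirical logits and their Wald
    standard errors (capped by the prior scales), independent of the
    package's Laplace/Metropolis machinery.
    """

    def __init__(
        self,
        events_treat: int,
        n_treat: int,
        events_ctrl: int,
        n_ctrl: int,
        slope_scale: float = 2.5,
        intercept_scale: float = 10.0,
        n_grid: int = 1201,
        width: float = 8.0,
    ):
        a, c = events_treat, events_ctrl
        n1, n2 = n_treat, n_ctrl
        p1 = (a + 0.5) / (n1 + 1.0)
        p0 = (c + 0.5) / (n2 + 1.0)
        a0 = log(p0 / (1 - p0))
        b0 = log(p1 / (1 - p1)) - a0
        se_a = min(sqrt(1 / (c + 0.5) + 1 / (n2 - c + 0.5)), intercept_scale)
        se_b = min(
            sqrt(1 / (a + 0.5) + 1 / (n1 - a + 0.5)) + se_a, 2 * slope_scale
        )
        al = np.linspace(a0 - width * se_a, a0 + width * se_a, n_grid)
        be = np.linspace(b0 - width * se_b, b0 + width * se_b, n_grid)
        A, B = np.meshgrid(al, be, indexing="ij")
        sp = lambda x: np.logaddexp(0.0, x)
        lp = (
            a * (A + B)
            - n1 * sp(A + B)
            + c * A
            - n2 * sp(A)
            - 0.5 * (A / intercept_scale) ** 2
            - 0.5 * (B / slope_scale) ** 2
        )
        w = np.exp(lp - lp.max())
        w /= w.sum()
        self.beta_grid = be
        self.beta_marginal = w.sum(axis=0)
        self._cdf = np.cumsum(self.beta_marginal)

    @property
    def mean(self) -> float:
        return float((self.beta_marginal * self.beta_grid).sum())

    @property
    def sd(self) -> float:
        m = self.mean
        return float(sqrt((self.beta_marginal * self.beta_grid**2).sum() - m**2))

    def quantile(self, q) -> np.ndarray:
        return np.interp(q, self._cdf, self.beta_grid)

    @property
    def pd(self) -> float:
        above = float(self.beta_marginal[self.beta_grid > 0].sum())
        return max(above, 1 - above)

    def rope(self, or_low: float = 0.84, or_high: float = 1.20) -> float:
        mask = (self.beta_grid >= log(or_low)) & (self.beta_grid <= log(or_high))
        return float(self.beta_marginal[mask].sum())
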