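"""Closed-form machinery: establishment probability, Wright's stationary
distribution, and survival probabilities as functions of population size.

The survival probability of a population of size N initially at
mutation-selection-drift balance is

    P_survival = 1 - exp(-N pi(s_r) mu/delta)
                 * 1F1(2N mu, 4N mu, -2N s~) / 1F1(2N mu, 4N mu, -2N s_d)

where pi(s) is the branching-process establishment probability of a
single copy with advantage s, s_r = s_b - delta, and
s~ = s_d + (1 - mu/delta) pi(s_r)/2.  The same quantity is available by
direct quadrature of the conditional survival probability against
Wright's density, which serves as an independent numerical check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import integrate, optimize, special

from .params import ModelParams

__all__ = [
    "establishment_prob",
    "log_hyp1f1",
    "WrightDistribution",
    "wright_log_density",
    "normalization_log",
    "mean_frequency",
    "prob_at_least_one_copy",
    "survival_given_p",
    "survival_probability",
    "survival_probability_quadrature",
    "survival_components",
    "survival_restricted",
    "find_vulnerable_N",
    "SurvivalDecomposition",
    "SurvivalQuantities",
    "survival_quantities",
    "MinimumReport",
]

# scipy's hyp1f1 is reliable for modest positive arguments (all series
# terms positive, no cancellation); beyond this we go to arbitrary
# precision to avoid overflow of the unlogged value.
_SCIPY_HYP_MAX_Z = 600.0


def establishment_prob(s: float) -> float:
    """Establishment probability pi(s) of a single copy with advantage s.

    For a branching process with Poisson(1 + s) offspring, pi is the
    larger root of ``pi = 1 - exp(-(1 + s) pi)``.  Solved by bisection,
    which is unconditionally robust since the defect function is concave
    with a single positive root for s > 0.  Returns 0 for s <= 0
    (subcritical or critical lineages die out almost surely).
    """
    if s <= -1.0:
        raise ValueError(f"s must be > -1, got {s}")
    if s <= 0.0:
        return 0.0

    def defect(x: float) -> float:
        # expm1 keeps the sign reliable when x is tiny and the defect is O(s x)
        return -math.expm1(-(1.0 + s) * x) - x

    return float(optimize.bisect(defect, 1e-12, 1.0, xtol=1e-13, rtol=8.9e-16))


def _log_hyp1f1_series(a: float, b: float, z: float) -> float:
    """log 1F1(a, b, z) for a, b, z > 0 by log-space summation.

    Every series term is positive, so summing log-terms with logsumexp
    is free of cancellation and immune to overflow; the term magnitudes
    peak near k ~ z and then decay geometrically.
    """
    kmax = int(z + 20.0 * math.sqrt(z) + 500.0)
    k = np.arange(kmax)
    increments = (
        np.log(a + k) + math.log(z) - np.log(b + k) - np.log1p(k)
    )
    log_terms = np.concatenate(([0.0], np.cumsum(increments)))
    return float(special.logsumexp(log_terms))


def log_hyp1f1(a: float, b: float, z: float) -> float:
    """log of the confluent hypergeometric function 1F1(a, b, z).

    Negative arguments are routed through the Kummer transform
    ``1F1(a, b, z) = e^z 1F1(b - a, b, -z)`` so that the series is
    evaluated at a positive argument where every term is positive and no
    catastrophic cancellation occurs.  Arguments large enough to
    overflow the unlogged value are summed directly in log space, with
    arbitrary precision as a last resort.
    """
    if b <= 0.0:
        raise ValueError(f"b must be > 0, got {b}")
    if z < 0.0:
        return z + log_hyp1f1(b - a, b, -z)
    if z == 0.0:
        return 0.0
    if z <= _SCIPY_HYP_MAX_Z:
        v = special.hyp1f1(a, b, z)
        if np.isfinite(v) and v > 0.0:
            return float(np.log(v))
    if a > 0.0:
        v = _log_hyp1f1_series(a, b, z)
        if np.isfinite(v):
            return v
    import mpmath as mp

    with mp.workdps(30):
        v = mp.log(mp.hyp1f1(a, b, z, maxterms=10**6))
        if not mp.isfinite(v):
            raise ArithmeticError(
                f"1F1({a}, {b}, {z}) could not be evaluated in high precision"
            )
        return float(v)


@dataclass(frozen=True)
class WrightDistribution:
    """Wright's stationary allele-frequency distribution at size N.

    Density on (0, 1):  phi(p) = C exp(-gamma p) (p(1-p))^(alpha - 1)
    with alpha = 2 N mu, gamma = 2 N s_d.  For alpha < 1 (every regime
    of interest here) the density diverges integrably at both endpoints:
    small populations are typically fixed or nearly fixed for one of the
    two alleles.
    """

    N: float
    mu: float
    s_d: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.mu <= 0.0:
            raise ValueError("mu must be > 0")
        if self.s_d < 0.0:
            raise ValueError("s_d must be >= 0")

    @property
    def alpha(self) -> float:
        return 2.0 * self.N * self.mu

    @property
    def gamma(self) -> float:
        return 2.0 * self.N * self.s_d

    @property
    def log_norm(self) -> float:
        """log(1/C) = log[ 1F1(alpha, 2 alpha, -gamma) B(alpha, alpha) ]."""
        a = self.alpha
        return (
            log_hyp1f1(a, 2.0 * a, -self.gamma)
            + 2.0 * special.gammaln(a)
            - special.gammaln(2.0 * a)
        )

    @property
    def logC(self) -> float:
        return -self.log_norm

    def log_density(self, p):
        """Log of phi(p) for interior frequencies 0 < p < 1."""
        p = np.asarray(p, dtype=float)
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("log_density is defined on the open interval (0, 1)")
        a, g = self.alpha, self.gamma
        out = self.logC - g * p + (a - 1.0) * (np.log(p) + np.log1p(-p))
        return out if out.ndim else float(out)

    def density(self, p):
        return np.exp(self.log_density(p))

    def mean(self) -> float:
        """Mean allele frequency p_bar = 0.5 * 1F1(a+1, 2a+1, -g)/1F1(a, 2a, -g)."""
        a, g = self.alpha, self.gamma
        return 0.5 * math.exp(
            log_hyp1f1(a + 1.0, 2.0 * a + 1.0, -g) - log_hyp1f1(a, 2.0 * a, -g)
        )

    def prob_at_least_one_copy(self) -> float:
        """Stationary probability that >= 1 copy segregates: mass on [1/N, 1].

        The integrand is singular only at p = 1, handled with a
        Gauss-Jacobi (algebraic-endpoint) weight.
        """
        a, g, logC = self.alpha, self.gamma, self.logC

        def f(p: float) -> float:
            return math.exp(logC - g * p + (a - 1.0) * math.log(p))

        val, _ = integrate.quad(
            f,
            1.0 / self.N,
            1.0,
            weight="alg",
            wvar=(0.0, a - 1.0),
            epsabs=1e-11,
            epsrel=1e-11,
            limit=200,
        )
        return float(min(max(val, 0.0), 1.0))

    def expectation(self, log_weight, lo: float = 0.0, hi: float = 1.0,
                    epsabs: float = 1e-12) -> Tuple[float, float]:
        """Integrate exp(log phi(p) + log_weight(p)) over [lo, hi].

        Endpoint singularities of phi at 0 and/or 1 (when alpha < 1 or
        generally the (p(1-p))^(alpha-1) factor) are absorbed into an
        algebraic quadrature weight; ``log_weight`` must be finite on the
        closed interval.  Returns (value, quadrature error estimate).
        """
        a, g, logC = self.alpha, self.gamma, self.logC
        w_lo = a - 1.0 if lo == 0.0 else 0.0
        w_hi = a - 1.0 if hi == 1.0 else 0.0

        def f(p: float) -> float:
            extra = 0.0
            if w_lo == 0.0:
                extra += (a - 1.0) * math.log(p)
            if w_hi == 0.0:
                extra += (a - 1.0) * math.log1p(-p)
            return math.exp(logC - g * p + extra + log_weight(p))

        val, err = integrate.quad(
            f, lo, hi,
            weight="alg", wvar=(w_lo, w_hi),
            epsabs=epsabs, epsrel=1e-10, limit=200,
        )
        return float(val), float(err)


# ---------------------------------------------------------------------------
# module-level convenience wrappers (N, mu, s_d signatures)

def wright_log_density(p, dist: WrightDistribution):
    return dist.log_density(p)


def normalization_log(N: float, mu: float, s_d: float) -> float:
    """log(1/C) of Wright's density, computed via 1F1 in log space."""
    return WrightDistribution(N, mu, s_d).log_norm


def mean_frequency(N: float, mu: float, s_d: float) -> float:
    return WrightDistribution(N, mu, s_d).mean()


def prob_at_least_one_copy(N: float, mu: float, s_d: float) -> float:
    if N < 2:
        raise ValueError("N must be >= 2 for the presence probability")
    return WrightDistribution(N, mu, s_d).prob_at_least_one_copy()


# ---------------------------------------------------------------------------
# survival probabilities

def survival_given_p(p: float, N: float, params: ModelParams) -> float:
    """Survival probability conditional on initial frequency p.

    Each of the A_st = pN standing copies, and each of the
    A_dn = (1-p) N mu/delta copies expected from de novo mutation during
    the decline, independently founds a rescuing lineage with
    probability pi(s_r):

        P{survival | p} = 1 - exp(-N pi(s_r) (p + (1-p) mu/delta))
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if N < 1:
        raise ValueError("N must be >= 1")
    pi = establishment_prob(params.s_r)
    m = params.mu / params.delta
    return -math.expm1(-N * pi * (p + (1.0 - p) * m))


def _s_tilde(params: ModelParams, pi: float) -> float:
    return params.s_d + (1.0 - params.mu / params.delta) * pi / 2.0


@dataclass(frozen=True)
class SurvivalQuantities:
    """Intermediate quantities of the survival calculation at one (p, N).

    ``pi_sr`` is the establishment probability of a single copy,
    ``s_tilde`` the effective selection coefficient entering the closed
    form, ``A`` the per-individual de novo rescue weight pi mu/delta,
    and ``A_st``/``A_dn`` the expected rescuing copy numbers from
    standing variation and from mutation during the decline.
    """

    pi_sr: float
    s_tilde: float
    A: float
    A_st: float
    A_dn: float


def survival_quantities(p: float, N: float, params: ModelParams) -> SurvivalQuantities:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    pi = establishment_prob(params.s_r)
    return SurvivalQuantities(
        pi_sr=pi,
        s_tilde=_s_tilde(params, pi),
        A=pi * params.mu / params.delta,
        A_st=p * N,
        A_dn=(1.0 - p) * N * params.mu / params.delta,
    )


def survival_probability(N: float, params: ModelParams) -> float:
    """Marginal survival probability, closed form via 1F1 ratios."""
    if N < 1:
        raise ValueError("N must be >= 1")
    pi = establishment_prob(params.s_r)
    a = 2.0 * N * params.mu
    st = _s_tilde(params, pi)
    try:
        num = log_hyp1f1(a, 2.0 * a, -2.0 * N * st)
        den = log_hyp1f1(a, 2.0 * a, -2.0 * N * params.s_d)
    except ArithmeticError as exc:
        raise ArithmeticError(
            f"1F1 evaluation failed for N={N}, alpha={a}, "
            f"arguments {-2.0 * N * st} / {-2.0 * N * params.s_d}"
        ) from exc
    return -math.expm1(-N * pi * params.mu / params.delta + num - den)


def survival_probability_quadrature(N: float, params: ModelParams) -> float:
    """Marginal survival by direct quadrature against Wright's density.

    Independent numerical route to the closed form: integrates
    ``exp(-N pi (p (1 - mu/delta) + mu/delta))`` against phi(p) and
    subtracts from 1.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    pi = establishment_prob(params.s_r)
    m = params.mu / params.delta
    dist = WrightDistribution(N, params.mu, params.s_d)

    def logw(p: float) -> float:
        return -N * pi * (p * (1.0 - m) + m)

    val, err = dist.expectation(logw)
    if err > 1e-7:
        raise ArithmeticError(
            f"quadrature did not converge at N={N}: estimated error {err:g}"
        )
    return 1.0 - val


@dataclass(frozen=True)
class SurvivalDecomposition:
    """Standing-variation / de novo split of the survival probability.

    ``p_total`` composes the two routes as independent chances; it is
    close to, but not algebraically identical with, the closed-form
    marginal ``p_closed_form`` (the conditional probability used for the
    standing route drops the (1-p) weighting of de novo supply).
    """

    p_stand: float
    p_de_novo: float
    p_total: float
    p_closed_form: float


def survival_components(N: float, params: ModelParams) -> SurvivalDecomposition:
    """Survival via standing variation only, de novo only, and combined.

    The standing component switches mutation off in the conditional
    survival probability but *not* in the stationary density:

        P_stand = E_phi[ 1 - exp(-N pi(s_r) p) ]
                = 1 - 1F1(a, 2a, -(gamma + N pi)) / 1F1(a, 2a, -gamma)

    The de novo component is the conditional survival at p = 0, and
    P_total = P_stand + (1 - P_stand) P_de_novo.
    """
    pi = establishment_prob(params.s_r)
    a = 2.0 * N * params.mu
    g = 2.0 * N * params.s_d
    p_stand = -math.expm1(
        log_hyp1f1(a, 2.0 * a, -(g + N * pi)) - log_hyp1f1(a, 2.0 * a, -g)
    )
    p_de_novo = survival_given_p(0.0, N, params)
    p_total = p_stand + (1.0 - p_stand) * p_de_novo
    return SurvivalDecomposition(
        p_stand=p_stand,
        p_de_novo=p_de_novo,
        p_total=p_total,
        p_closed_form=survival_probability(N, params),
    )


def survival_restricted(N: float, params: ModelParams, p_max: float) -> float:
    """Marginal survival with the initial frequency conditioned on p < p_max.

    Renormalizes Wright's density on (0, p_max) before averaging the
    conditional survival probability.  With p_max = delta/s_b this keeps
    only scenarios in which the population is actually declining at the
    change (mean fitness below one), i.e. rescue in the strict sense.
    """
    if not 0.0 < p_max <= 1.0:
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    if p_max == 1.0:
        return survival_probability_quadrature(N, params)
    pi = establishment_prob(params.s_r)
    m = params.mu / params.delta
    dist = WrightDistribution(N, params.mu, params.s_d)
    mass, _ = dist.expectation(lambda p: 0.0, hi=p_max)
    if mass < 1e-12:
        raise ArithmeticError(
            f"degenerate conditioning: mass below p_max={p_max} is {mass:g}"
        )
    num, _ = dist.expectation(lambda p: -N * pi * (p * (1.0 - m) + m), hi=p_max)
    return 1.0 - num / mass


@dataclass(frozen=True)
class MinimumReport:
    """Rightmost interior local minimum of survival vs N, if any."""

    exists: bool
    n_star: Optional[float]
    p_at_min: Optional[float]
    search_range: Tuple[float, float]


def find_vulnerable_N(
    params: ModelParams,
    N_lo: float = 10.0,
    N_hi: float = 1e6,
    n_grid: int = 200,
    depth_tol: float = 1e-6,
) -> MinimumReport:
    """Locate the vulnerable intermediate population size, if one exists.

    Scans the closed-form survival probability on a log-spaced grid,
    keeps interior grid local minima whose depth below the flanking
    local maxima is at least ``depth_tol`` (screening out flat stretches
    where the probability has saturated), and refines the rightmost one
    by golden-section search in log N.  N is treated as continuous, as
    the closed form is a smooth function of it.
    """
    if not 1 <= N_lo < N_hi:
        raise ValueError("require 1 <= N_lo < N_hi")
    if n_grid < 3:
        raise ValueError("n_grid must be >= 3")
    grid = np.geomspace(N_lo, N_hi, n_grid)
    pvals = np.array([survival_probability(N, params) for N in grid])

    candidate = None
    for i in range(1, n_grid - 1):
        if pvals[i] <= pvals[i - 1] and pvals[i] <= pvals[i + 1]:
            depth = min(pvals[:i].max(), pvals[i + 1:].max()) - pvals[i]
            if depth >= depth_tol:
                candidate = i
    if candidate is None:
        return MinimumReport(False, None, None, (N_lo, N_hi))

    i = candidate

    def f(logN: float) -> float:
        return survival_probability(math.exp(logN), params)

    la, lb, lc = np.log(grid[i - 1]), np.log(grid[i]), np.log(grid[i + 1])
    if pvals[i] < pvals[i - 1] and pvals[i] < pvals[i + 1]:
        res = optimize.minimize_scalar(
            f, bracket=(la, lb, lc), method="golden",
            options={"xtol": 1e-10},
        )
        log_nstar, p_min = float(res.x), float(res.fun)
    else:  # flat tie at grid resolution: fall back to bounded search
        res = optimize.minimize_scalar(f, bounds=(la, lc), method="bounded")
        log_nstar, p_min = float(res.x), float(res.fun)
    n_star = math.exp(log_nstar)
    if not N_lo < n_star < N_hi:
        n_star = float(grid[i])
        p_min = float(pvals[i])
    return MinimumReport(True, n_star, p_min, (N_lo, N_hi))
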