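"""Stochastic validation of the closed-form survival probabilities.

A replicate starts at the moment of the environmental change with the
allele frequency drawn from a discretized Wright distribution, then
follows wild-type and survival-allele counts through Poisson
reproduction and symmetric mutation until the population is extinct or
the survival lineage has established.  A density-regulated (Ricker)
variant relaxes the branching-process assumption that survival lineages
reproduce independently of population size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate

from .core import WrightDistribution, survival_probability
from .params import ModelParams, RickerParams, SimulationConfig

__all__ = [
    "discretize_wright",
    "sample_initial_frequency",
    "simulate_branching",
    "simulate_ricker",
    "estimate_survival",
    "SimulationOutcome",
    "SurvivalEstimate",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(20)


@dataclass(frozen=True)
class SimulationOutcome:
    """Result of one replicate.

    ``survived`` is None when the replicate was censored (hit the
    generation cap without resolving); censored replicates are excluded
    from survival fractions rather than silently misclassified.
    """

    survived: Optional[bool]
    censored: bool
    generations: int
    initial_p: float
    final_wildtype: int
    final_mutant: int


@dataclass(frozen=True)
class SurvivalEstimate:
    """Monte-Carlo survival fraction with its binomial standard error."""

    N: int
    replicates: int
    survived: int
    censored: int
    fraction: float
    se: float


def discretize_wright(N: int, mu: float, s_d: float) -> np.ndarray:
    """Bin Wright's density into N + 1 masses at frequencies j/N.

    Bin j (1 <= j <= N-1) integrates phi over [(j-0.5)/N, (j+0.5)/N];
    the edge bins cover (0, 0.5/N] and [(N-0.5)/N, 1), where the density
    is steep (divergent for 2 N mu < 1).  Edge bins use singularity-
    absorbing algebraic-weight quadrature; interior bins use 20-point
    Gauss-Legendre, which is ample since phi is smooth away from the
    endpoints.  The result is renormalized to sum exactly to one.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    dist = WrightDistribution(N, mu, s_d)
    a, g, logC = dist.alpha, dist.gamma, dist.logC
    masses = np.empty(N + 1)

    def edge(lo: float, hi: float, wvar) -> float:
        def f(p: float) -> float:
            extra = (a - 1.0) * (math.log1p(-p) if wvar[1] == 0.0 else math.log(p))
            return math.exp(logC - g * p + extra)

        val, err = integrate.quad(
            f, lo, hi, weight="alg", wvar=wvar,
            epsabs=1e-13, epsrel=1e-10, limit=200,
        )
        if not np.isfinite(val):
            raise ArithmeticError(
                f"edge-bin quadrature failed on [{lo}, {hi}] (N={N})"
            )
        return val

    masses[0] = edge(0.0, 0.5 / N, (a - 1.0, 0.0))
    masses[N] = edge(1.0 - 0.5 / N, 1.0, (0.0, a - 1.0))

    # interior bins, vectorized: nodes shaped (bins, order)
    j = np.arange(1, N)
    lo = (j - 0.5) / N
    # map [-1, 1] -> [lo, lo + 1/N]
    pts = lo[:, None] + (1.0 / N) * (_GL_NODES[None, :] + 1.0) / 2.0
    logphi = logC - g * pts + (a - 1.0) * (np.log(pts) + np.log1p(-pts))
    masses[1:N] = (1.0 / N) / 2.0 * np.exp(logphi) @ _GL_WEIGHTS

    total = masses.sum()
    if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
        raise ArithmeticError(
            f"discretized masses sum to {total}, expected 1 (N={N})"
        )
    return masses / total


def sample_initial_frequency(masses: np.ndarray, rng: np.random.Generator) -> float:
    """Draw one frequency from the grid {0, 1/N, ..., 1}."""
    n = masses.size - 1
    idx = int(np.searchsorted(np.cumsum(masses), rng.random(), side="right"))
    return min(idx, n) / n


def _reproduce(L: int, M: int, w_L: float, w_M: float, mu: float,
               rng: np.random.Generator) -> tuple[int, int]:
    """One generation: Poisson offspring, then symmetric mutation.

    Mutation is applied by binomial thinning in both directions, which
    is distributionally identical to flipping each offspring's allele
    independently with probability mu.  Allele counts after mutation sum
    to the offspring total drawn before it.
    """
    Lo = rng.poisson(w_L * L) if L > 0 and w_L > 0.0 else 0
    Mo = rng.poisson(w_M * M) if M > 0 and w_M > 0.0 else 0
    if mu > 0.0:
        to_M = rng.binomial(Lo, mu) if Lo else 0
        to_L = rng.binomial(Mo, mu) if Mo else 0
        return Lo - to_M + to_L, Mo - to_L + to_M
    return Lo, Mo


def simulate_branching(
    N: int,
    params: ModelParams,
    config: SimulationConfig,
    rng: np.random.Generator,
    masses: Optional[np.ndarray] = None,
    initial_p: Optional[float] = None,
) -> SimulationOutcome:
    """One branching-process replicate from the environmental change.

    Wild-type offspring are Poisson with mean (1 - delta) L_i and the
    survival lineage Poisson with mean (1 - delta + s_b) M_i, followed
    by symmetric mutation at rate mu per offspring.  Terminates on
    extinction or when the survival lineage reaches the establishment
    threshold.  ``initial_p`` overrides the Wright draw (useful for
    conditioning on fixation etc.).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if initial_p is None:
        if masses is None:
            masses = discretize_wright(N, params.mu, params.s_d)
        p = sample_initial_frequency(masses, rng)
    else:
        if not 0.0 <= initial_p <= 1.0:
            raise ValueError("initial_p must be in [0, 1]")
        p = float(initial_p)
    M = int(round(p * N))
    L = N - M
    w_L = 1.0 - params.delta
    w_M = 1.0 - params.delta + params.s_b

    for gen in range(config.max_generations):
        if M >= config.threshold:
            return SimulationOutcome(True, False, gen, p, L, M)
        if L + M == 0:
            return SimulationOutcome(False, False, gen, p, L, M)
        L, M = _reproduce(L, M, w_L, w_M, params.mu, rng)
    return SimulationOutcome(None, True, config.max_generations, p, L, M)


def simulate_ricker(
    ricker: RickerParams,
    params: ModelParams,
    config: SimulationConfig,
    rng: np.random.Generator,
    masses: Optional[np.ndarray] = None,
    initial_p: Optional[float] = None,
) -> SimulationOutcome:
    """One density-regulated replicate.

    The population starts at the Wright stationary distribution with
    N_0 = K_0.  Wild-type per-capita mean offspring is
    exp(r [1 - N_t/K_t]) with K_t = K_0 (1 - delta)^t, while survival-
    allele carriers keep the undiminished capacity K_0.  Establishment
    is declared when the survival lineage reaches
    min(threshold, ceil(K_0/2)): at half of an undiminished carrying
    capacity the lineage is safe for all practical purposes even when
    K_0 is below the branching-process threshold.
    """
    K0 = ricker.K0
    if initial_p is None:
        if masses is None:
            masses = discretize_wright(K0, params.mu, params.s_d)
        p = sample_initial_frequency(masses, rng)
    else:
        if not 0.0 <= initial_p <= 1.0:
            raise ValueError("initial_p must be in [0, 1]")
        p = float(initial_p)
    M = int(round(p * K0))
    L = K0 - M
    goal = min(config.threshold, math.ceil(K0 / 2.0))
    log_decay = math.log1p(-params.delta)

    for gen in range(config.max_generations):
        if M >= goal:
            return SimulationOutcome(True, False, gen, p, L, M)
        Nt = L + M
        if Nt == 0:
            return SimulationOutcome(False, False, gen, p, L, M)
        Kt = K0 * math.exp(log_decay * gen)
        # clip exponents: once K_t is minuscule the wild type is gone anyway
        w_L = math.exp(min(max(ricker.r * (1.0 - Nt / Kt), -745.0), 50.0))
        w_M = math.exp(min(max(ricker.r * (1.0 - Nt / K0), -745.0), 50.0))
        L, M = _reproduce(L, M, w_L, w_M, params.mu, rng)
    return SimulationOutcome(None, True, config.max_generations, p, L, M)


def estimate_survival(
    N: int,
    params: ModelParams,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    ricker: Optional[RickerParams] = None,
) -> SurvivalEstimate:
    """Survival fraction over independent replicates, with binomial SE.

    One root generator spawns an independent sub-stream per replicate,
    so estimates are reproducible and order-independent.  Censored
    replicates (generation cap reached) are excluded from the fraction
    and reported in the count.  Pass ``ricker`` to use the density-
    regulated simulator (N is then ignored in favour of K0).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    size = ricker.K0 if ricker is not None else N
    masses = discretize_wright(size, params.mu, params.s_d)
    streams = rng.spawn(config.replicates)
    survived = censored = 0
    for sub in streams:
        if ricker is not None:
            out = simulate_ricker(ricker, params, config, sub, masses=masses)
        else:
            out = simulate_branching(N, params, config, sub, masses=masses)
        if out.censored:
            censored += 1
        elif out.survived:
            survived += 1
    effective = config.replicates - censored
    frac = survived / effective if effective else float("nan")
    se = math.sqrt(frac * (1.0 - frac) / effective) if effective else float("nan")
    return SurvivalEstimate(size, config.replicates, survived, censored, frac, se)
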