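"""Parameter containers for the rescue model and its simulators.

The scenario is a haploid population of size N hit by an abrupt
environmental change.  Wild-type absolute fitness drops from 1 to
1 - delta; a single biallelic "survival" locus carries an allele with
fitness 1 - delta + s_b after the change and cost s_d before it.
Mutation between the two alleles is symmetric at rate mu per
individual per generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the environmental-change scenario.

    Parameters
    ----------
    s_b : float
        Selective benefit of the survival allele after the change
        (per generation, dimensionless).  Must exceed ``delta`` so that
        the survival lineage grows on average.
    s_d : float
        Selective cost of the survival allele before the change
        (dimensionless, >= 0).
    delta : float
        Per-generation decline rate of the wild type after the change,
        in (0, 1).
    mu : float
        Symmetric per-individual per-generation mutation rate between
        the two alleles, in [0, delta).  mu = 0 switches mutation off,
        which is meaningful for the simulators and conditional survival
        probabilities; the stationary-distribution machinery requires
        mu > 0.
    """

    s_b: float = 0.05
    s_d: float = 0.001
    delta: float = 0.01
    mu: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError(f"mu must be in [0, 1), got {self.mu}")
        if self.s_d < 0.0:
            raise ValueError(f"s_d must be >= 0, got {self.s_d}")
        if self.s_b <= self.delta:
            raise ValueError(
                f"s_b must exceed delta (got s_b={self.s_b}, delta={self.delta}); "
                "otherwise the survival lineage declines too"
            )
        if self.mu >= self.delta:
            raise ValueError(
                f"mu must be smaller than delta (got mu={self.mu}, delta={self.delta})"
            )

    @property
    def s_r(self) -> float:
        """Net growth advantage of the survival allele after the change."""
        return self.s_b - self.delta

    @property
    def N_neut(self) -> float:
        """Neutrality threshold 1/s_d: below it the cost is drift-dominated."""
        return math.inf if self.s_d == 0.0 else 1.0 / self.s_d

    @property
    def N_mut(self) -> float:
        """Mutation-supply threshold 1/mu: one new copy per generation."""
        return math.inf if self.mu == 0.0 else 1.0 / self.mu


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the stochastic simulators.

    ``threshold`` is the survival-lineage count at which a replicate is
    declared rescued; results are insensitive to it provided it is large
    enough that a lineage of that size is very unlikely to be lost.
    Replicates that reach ``max_generations`` without resolving are
    reported as censored rather than classified.
    """

    threshold: int = 2000
    max_generations: int = 1_000_000
    seed: int = 0
    replicates: int = 1000

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass(frozen=True)
class RickerParams:
    """Density regulation for the Ricker variant of the simulator.

    Wild-type per-capita mean offspring is exp(r [1 - N_t/K_t]) with the
    carrying capacity decaying as K_t = K0 (1 - delta)^t after the
    change; carriers of the survival allele keep capacity K0.
    """

    K0: int
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.r <= 0.0:
            raise ValueError("r must be > 0")
        if self.K0 < 2:
            raise ValueError("K0 must be >= 2")

    def capacity(self, t: int, delta: float) -> float:
        """Carrying capacity of the wild type t generations after the change."""
        return self.K0 * (1.0 - delta) ** t
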