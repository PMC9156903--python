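"""Parameter sweeps producing numeric tables.

Each ``run_*`` function returns a pandas DataFrame; the CLI writes them
to CSV.  Analytic tables are deterministic and byte-identical across
reruns; simulation tables are reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import core
from .params import ModelParams, SimulationConfig
from .simulation import estimate_survival

__all__ = [
    "SweepSpec",
    "run_wright_panels",
    "run_survival_curves",
    "run_decomposition",
    "run_minimum_scan",
]

#: parameters a sweep may vary
_SWEEPABLE = ("N", "s_b", "s_d", "mu", "delta", "p_max")


@dataclass(frozen=True)
class SweepSpec:
    """One swept parameter against a log-spaced N grid.

    ``varied`` names the parameter taking the listed ``values`` while
    all others stay at ``base``.  ``n_grid`` is (lo, hi, points) for the
    population-size axis.
    """

    varied: str
    values: Sequence[float]
    base: ModelParams = field(default_factory=ModelParams)
    n_grid: Tuple[float, float, int] = (10.0, 1e6, 60)

    def __post_init__(self) -> None:
        if self.varied not in _SWEEPABLE:
            raise ValueError(f"varied must be one of {_SWEEPABLE}")
        vals = list(self.values)
        if not vals:
            raise ValueError("values must be non-empty")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("values must be strictly increasing")
        lo, hi, pts = self.n_grid
        if not (lo < hi and pts >= 2):
            raise ValueError("n_grid must satisfy lo < hi and points >= 2")

    def N_values(self) -> np.ndarray:
        lo, hi, pts = self.n_grid
        return np.geomspace(lo, hi, int(pts))

    def params_for(self, value: float) -> ModelParams:
        if self.varied in ("N", "p_max"):
            return self.base
        return replace(self.base, **{self.varied: value})


def run_wright_panels(spec: SweepSpec) -> pd.DataFrame:
    """Stationary-distribution summaries: mean frequency and presence
    probability per (N, mu, s_d)."""
    rows = []
    for value in spec.values:
        p = spec.params_for(value)
        for N in spec.N_values():
            rows.append(
                {
                    "varied": spec.varied,
                    "value": value,
                    "N": N,
                    "mu": p.mu,
                    "s_d": p.s_d,
                    "p_mean": core.mean_frequency(N, p.mu, p.s_d),
                    "p_at_least_one_copy": core.prob_at_least_one_copy(
                        max(N, 2.0), p.mu, p.s_d
                    ),
                }
            )
    return pd.DataFrame(rows)


def run_survival_curves(
    spec: SweepSpec,
    with_sim: bool = False,
    config: Optional[SimulationConfig] = None,
    sim_points: int = 12,
) -> pd.DataFrame:
    """Analytic survival vs N per swept value, optionally with
    Monte-Carlo points on a coarse sub-grid.

    When ``varied`` is ``p_max`` the analytic column is the
    rescue-restricted survival probability (density renormalized on
    p < p_max); otherwise it is the unrestricted closed form.
    """
    if with_sim and config is None:
        config = SimulationConfig()
    rows = []
    Ns = spec.N_values()
    if with_sim:
        sim_Ns = set(
            np.unique(np.geomspace(Ns[0], Ns[-1], sim_points).round().astype(int))
        )
    for value in spec.values:
        p = spec.params_for(value)
        for k, N in enumerate(Ns):
            if spec.varied == "p_max":
                analytic = core.survival_restricted(N, p, value)
            else:
                analytic = core.survival_probability(N, p)
            row = {
                "varied": spec.varied,
                "value": value,
                "N": N,
                "p_survival": analytic,
            }
            if with_sim:
                Ni = int(round(N))
                if Ni in sim_Ns and spec.varied != "p_max":
                    rng = np.random.default_rng([config.seed, Ni, k])
                    est = estimate_survival(Ni, p, config, rng=rng)
                    row.update(
                        reps=est.replicates,
                        survived=est.survived,
                        censored=est.censored,
                        fraction=est.fraction,
                        se=est.se,
                    )
                else:
                    row.update(
                        reps=0, survived=0, censored=0,
                        fraction=float("nan"), se=float("nan"),
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def run_decomposition(spec: SweepSpec) -> pd.DataFrame:
    """Standing/de novo decomposition table over the N grid.

    Columns follow the standard layout: N, p_survival, p_stand,
    p_de_novo, p_total, p_mean, p_at_least_one_copy.  The neutrality and
    mutation-supply thresholds are attached as ``attrs`` metadata
    (written as comment headers by the CLI).
    """
    base = spec.base
    rows = []
    for N in spec.N_values():
        dec = core.survival_components(N, base)
        rows.append(
            {
                "N": N,
                "p_survival": dec.p_closed_form,
                "p_stand": dec.p_stand,
                "p_de_novo": dec.p_de_novo,
                "p_total": dec.p_total,
                "p_mean": core.mean_frequency(N, base.mu, base.s_d),
                "p_at_least_one_copy": core.prob_at_least_one_copy(
                    max(N, 2.0), base.mu, base.s_d
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["N_neut"] = base.N_neut
    df.attrs["N_mut"] = base.N_mut
    return df


def run_minimum_scan(
    spec: SweepSpec,
    s_b_levels: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Vulnerable-N location per swept value and benefit level.

    ``varied`` must be ``mu`` or ``s_d``.  Rows report the rightmost
    interior local minimum of survival vs N, or ``exists = False`` when
    the curve is monotone (or any dip is below the depth threshold).
    """
    if spec.varied not in ("mu", "s_d"):
        raise ValueError("minimum scan sweeps mu or s_d")
    if s_b_levels is None:
        s_b_levels = [spec.base.s_b]
    lo, hi, pts = spec.n_grid
    rows = []
    for s_b in s_b_levels:
        for value in spec.values:
            p = replace(spec.base, s_b=s_b, **{spec.varied: value})
            rep = core.find_vulnerable_N(p, lo, hi, n_grid=max(int(pts), 200))
            rows.append(
                {
                    "varied": spec.varied,
                    "value": value,
                    "s_b": s_b,
                    "exists": rep.exists,
                    "n_star": rep.n_star if rep.exists else float("nan"),
                    "p_at_min": rep.p_at_min if rep.exists else float("nan"),
                    "N_lo": lo,
                    "N_hi": hi,
                }
            )
    return pd.DataFrame(rows)
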