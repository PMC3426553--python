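"""Library planning: cycles-to-complexity and multiplicity-of-infection statistics.

Planning uses the linear complexity formula: to reach p mutations per copy of
an n-nt target gene under a per-nt per-cycle rate m, run p/(m*n) cycles. The
exact Bernoulli-per-site complement n*(1-(1-m)^c) is also exposed because the
linear form overestimates once m*c grows, but the linear form is the default
planning rule.

The number of proviral copies a cell receives at a given MOI is modelled as
Poisson(MOI) — the standard single-hit model for VSV-G pseudotyped vectors.
The diversification phase runs at high MOI (>100, essentially every cell
multiply transduced, which enables recombination between co-packaged
genomes); the screening phase runs at low MOI (~0.03) so that transduced
cells almost surely carry a single variant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq


@dataclass(frozen=True)
class DesignQuery:
    """Target complexity query: p mutations wanted per gene copy of n nt at rate m."""

    p: float
    m: float
    n: int

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError("desired mutations per copy must be > 0")
        if self.m <= 0:
            raise ValueError("mutation rate must be > 0")
        if self.n < 1:
            raise ValueError("gene length must be >= 1 nt")


class CyclePlan(NamedTuple):
    cycles: float   # real-valued p/(m*n)
    ceiling: int    # integer recommendation

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.cycles


def cycles_required(p: float, m: float, n: int) -> CyclePlan:
    """Replication cycles needed for p expected mutations per n-nt gene copy.

    Evaluates p/(m*n) and also returns the ceiling as the integer
    recommendation an experimenter would run.
    """
    q = DesignQuery(p, m, n)
    cycles = q.p / (q.m * q.n)
    return CyclePlan(cycles=cycles, ceiling=math.ceil(cycles - 1e-12))


def expected_mutations(m: float, n: int, cycles: float, model: str = "linear") -> float:
    """Expected mutated positions per gene copy after ``cycles`` cycles.

    ``model="linear"`` gives m*n*cycles (the planning rule); ``model="exact"``
    gives the per-site no-mutation complement n*(1-(1-m)^cycles), which also
    accounts for repeat hits at a site. The two agree to better than 1% while
    m*cycles <= 0.01.
    """
    if m < 0 or n < 0 or cycles < 0:
        raise ValueError("all arguments must be non-negative")
    if model == "linear":
        return m * n * cycles
    if model == "exact":
        return n * -math.expm1(cycles * math.log1p(-m)) if m < 1 else float(n)
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class TransductionStats:
    """Poisson(MOI) transduction summary.

    p_transduced = P(>=1 provirus) = 1 - e^-moi;
    p_multi_given_transduced = P(>=2 | >=1), the fraction of transduced cells
    that carry more than one variant (to be minimized during screening).
    """

    moi: float
    p_transduced: float
    p_multi_given_transduced: float


def multiplicity_stats(moi: float) -> TransductionStats:
    """Closed-form Poisson multiplicity statistics for a given MOI."""
    if moi < 0:
        raise ValueError("MOI must be non-negative")
    if moi == 0:
        return TransductionStats(0.0, 0.0, 0.0)
    p_trans = -math.expm1(-moi)
    p_multi = (p_trans - moi * math.exp(-moi)) / p_trans
    return TransductionStats(moi, p_trans, max(0.0, p_multi))


def recommend_moi(max_multi_fraction: float, *, xtol: float = 1e-6) -> float:
    """Largest MOI keeping P(>=2 proviruses | transduced) at or below a tolerance.

    P(>=2 | >=1) is strictly increasing in the MOI, so the bound is attained at
    the unique root of the closed form, found by bracketed root-finding to the
    requested relative tolerance.
    """
    if not 0 < max_multi_fraction < 1:
        raise ValueError("tolerated multi-transduction fraction must lie in (0, 1)")

    def f(lam: float) -> float:
        return multiplicity_stats(lam).p_multi_given_transduced - max_multi_fraction

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - tolerance ~1 would be needed
            return hi
    return float(brentq(f, lo, hi, rtol=xtol))


def cycles_vs_size_curve(m: float, n_values, p: float = 1.0) -> np.ndarray:
    """Cycles required as a function of target size, for planning plots."""
    n_values = np.asarray(n_values, dtype=float)
    if (n_values < 1).any():
        raise ValueError("gene sizes must be >= 1 nt")
    if p <= 0 or m <= 0:
        raise ValueError("p and m must be > 0")
    return p / (m * n_values)
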