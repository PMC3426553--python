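"""Per-nucleotide per-cycle mutation-rate estimation from sequenced clone sets.

The estimator treats the total number of mutated positions M observed over C
clones of length L nt after G reverse-transcription cycles as a Poisson count
with exposure C*L*G site-cycles:

    rate = M / (C * L * G)

with an exact (Garwood) Poisson confidence interval on M rescaled by the
exposure — chosen over a normal approximation because M is small in practice
(tens of events). "Mutated positions" are summed over clones without
deduplicating positions shared between clones, matching how per-clone averages
are computed from sequencing tables.

Generation labels follow the F_k -> k+1 cycles convention: the production of
the parental vector stock is itself one error-prone copying step, so library
generation F8 has been through 9 cycles. This convention uniquely reproduces
the printed rates of the reference sequencing table from its printed counts.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import CloneRecord, ReferenceGene
from ._util import round_sig, trunc_sig


def cycles_for_label(label: str | int) -> int:
    """Map a generation label to reverse-transcription cycles (F_k -> k+1)."""
    if isinstance(label, int):
        k = label
    else:
        m = re.fullmatch(r"[Ff]?(-?\d+)", str(label).strip())
        if not m:
            raise ValueError(f"cannot parse generation label {label!r}")
        k = int(m.group(1))
    if k < 0:
        raise ValueError("generation number must be >= 0")
    return k + 1


def per_clone_average(M: int, C: int) -> float:
    """Average mutated positions per clone, M/C at full precision."""
    if C < 1:
        raise ValueError("need at least one clone")
    if M < 0:
        raise ValueError("mutation count must be non-negative")
    return M / C


class MutationRateModel:
    """Poisson-exposure model for the per-nt per-cycle substitution rate.

    Parameters
    ----------
    n_mutations : int
        Total mutated positions summed over the sequenced clones (M).
    n_clones : int
        Number of sequenced clones (C >= 1).
    gene_length : int
        Target-gene length in nt (L >= 1).
    generation_label : str or int, optional
        F-number; converted to cycles via the F_k -> k+1 convention.
    cycles : int, optional
        Explicit cycle count G, overriding the label convention.

    Examples
    --------
    >>> res = MutationRateModel(14, 16, 783, generation_label="F8").fit()
    >>> round(res.rate, 8)
    0.00012417
    """

    def __init__(self, n_mutations: int, n_clones: int, gene_length: int,
                 generation_label: str | int | None = None,
                 cycles: int | None = None) -> None:
        if n_clones < 1:
            raise ValueError("need at least one clone (C >= 1)")
        if gene_length < 1:
            raise ValueError("gene length must be >= 1 nt")
        if n_mutations < 0:
            raise ValueError("mutation count must be non-negative")
        if cycles is None:
            if generation_label is None:
                raise ValueError("give either a generation label or an explicit cycle count")
            cycles = cycles_for_label(generation_label)
        if cycles < 1:
            raise ValueError("rate undefined for 0 cycles")
        self.M = int(n_mutations)
        self.C = int(n_clones)
        self.L = int(gene_length)
        self.G = int(cycles)
        self.generation_label = (str(generation_label)
                                 if generation_label is not None else f"F{cycles - 1}")

    @classmethod
    def from_clones(cls, clones: Iterable[CloneRecord], reference: ReferenceGene,
                    generation_label: str | int | None = None,
                    cycles: int | None = None) -> "MutationRateModel":
        """Build the model from sequenced clones (counts their mutation events)."""
        clones = tuple(clones)
        if not clones:
            raise ValueError("need at least one clone")
        if generation_label is None and cycles is None:
            generation_label = clones[0].generation_label
        M = sum(c.n_mutations for c in clones)
        return cls(M, len(clones), reference.length,
                   generation_label=generation_label, cycles=cycles)

    @property
    def exposure(self) -> int:
        """Poisson exposure in site-cycles: C * L * G."""
        return self.C * self.L * self.G

    def fit(self, alpha: float = 0.05) -> "RateEstimationResults":
        """Estimate the rate with an exact Poisson (Garwood) 1-alpha interval."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        rate = self.M / self.exposure
        lo = 0.0 if self.M == 0 else stats.chi2.ppf(alpha / 2, 2 * self.M) / 2
        hi = stats.chi2.ppf(1 - alpha / 2, 2 * self.M + 2) / 2
        return RateEstimationResults(
            model=self, rate=rate,
            ci_low=lo / self.exposure, ci_high=hi / self.exposure, alpha=alpha,
        )


@dataclass(frozen=True)
class RateEstimationResults:
    """Rate estimate with exact Poisson uncertainty and table-style rendering."""

    model: MutationRateModel
    rate: float
    ci_low: float
    ci_high: float
    alpha: float

    @property
    def per_clone_mean(self) -> float:
        return per_clone_average(self.model.M, self.model.C)

    @property
    def expected_per_clone(self) -> float:
        """rate * L * G — the complexity the fitted rate implies per clone."""
        return self.rate * self.model.L * self.model.G

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def printed_rate(self, sig: int = 2) -> float:
        """Rate truncated to ``sig`` significant figures.

        Sequencing tables in this field truncate rather than round rates
        (e.g. 1.1457e-4 is printed as 1.14e-4 at 3 figures); rounding is used
        for per-clone averages. Full precision stays in ``rate``.
        """
        return trunc_sig(self.rate, sig)

    def printed_per_clone_mean(self, sig: int = 2) -> float:
        return round_sig(self.per_clone_mean, sig)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Mutation-rate estimate (Poisson exposure model)",
            "=" * 48,
            f"Generation            {m.generation_label} ({m.G} cycles)",
            f"Sequenced clones  C   {m.C}",
            f"Gene length       L   {m.L} nt",
            f"Mutated positions M   {m.M}",
            f"Exposure C*L*G        {m.exposure} site-cycles",
            f"Rate M/(C*L*G)        {self.rate:.4e} per nt per cycle",
            f"{100 * (1 - self.alpha):.0f}% exact Poisson CI  [{self.ci_low:.4e}, {self.ci_high:.4e}]",
            f"Mean positions/clone  {self.per_clone_mean:.4g}",
            f"rate*L*G per clone    {self.expected_per_clone:.4g}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class DispersionResult:
    """Variance/mean ratio of per-clone counts against the Poisson null."""

    index: float
    statistic: float
    pvalue: float              # two-sided, chi-square approximation
    pvalue_overdispersed: float  # one-sided (upper tail)
    n: int
    defined: bool = True

    @property
    def overdispersed(self) -> bool:
        return self.defined and self.pvalue_overdispersed < 0.05


def dispersion_test(per_clone_counts: Sequence[int]) -> DispersionResult:
    """Index of dispersion with the (C-1)*index ~ chi2(C-1) approximation.

    A mean of zero leaves the index undefined; the result is flagged rather
    than raising, since all-identical clone sets are legitimate data.
    """
    counts = np.asarray(per_clone_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two clones")
    mean = counts.mean()
    if mean == 0:
        return DispersionResult(math.nan, math.nan, math.nan, math.nan,
                                counts.size, defined=False)
    index = counts.var(ddof=1) / mean
    dof = counts.size - 1
    statistic = dof * index
    upper = stats.chi2.sf(statistic, dof)
    lower = stats.chi2.cdf(statistic, dof)
    return DispersionResult(
        index=float(index), statistic=float(statistic),
        pvalue=float(min(1.0, 2 * min(upper, lower))),
        pvalue_overdispersed=float(upper), n=counts.size,
    )
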