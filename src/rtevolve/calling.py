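"""Mutation calling and spectrum summaries.

Clones are fixed-length PCR amplicons of the target CDS, so calling is a
substitution-only, position-by-position comparison against the reference —
no alignment step, which keeps results aligner-independent. Coordinates are
1-based and CDS-relative throughout.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    BASES,
    CloneRecord,
    MutationEvent,
    ReferenceGene,
    SUBSTITUTION_TYPES,
    encode_sequence,
)


def call_mutations(clone: str | CloneRecord, reference: ReferenceGene) -> list[MutationEvent]:
    """Positions where the clone differs from the reference, ascending.

    Rejects length mismatches (indels are unsupported) and non-ACGT
    characters (ambiguity codes are rejected rather than skipped, so counts
    stay exact).
    """
    seq = clone.sequence if isinstance(clone, CloneRecord) else clone
    if len(seq) != reference.length:
        raise ValueError(
            f"clone length {len(seq)} != reference length {reference.length}; "
            "indels are unsupported by the substitution-only model"
        )
    clone_codes = encode_sequence(seq)
    ref_codes = reference.codes()
    diff = np.flatnonzero(clone_codes != ref_codes)
    return [
        MutationEvent(int(i) + 1, BASES[ref_codes[i]], BASES[clone_codes[i]])
        for i in diff
    ]


@dataclass(frozen=True)
class SpectrumSummary:
    """Counts and fractions per ordered substitution type.

    ``fractions`` is None when no events were supplied (the fractions are then
    undefined, and flagged rather than silently zero).
    """

    counts: dict[tuple[str, str], int]
    total: int

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def fractions(self) -> dict[tuple[str, str], float] | None:
        if not self.defined:
            return None
        return {t: c / self.total for t, c in self.counts.items()}

    def fraction(self, ref: str, alt: str) -> float:
        if not self.defined:
            raise ValueError("fractions undefined: no events")
        return self.counts[(ref, alt)] / self.total

    @property
    def g_to_a_fraction(self) -> float:
        return self.fraction("G", "A")

    @property
    def g_to_a_percent(self) -> float:
        """G>A fraction as a percentage, reported to 0.1%."""
        return round(100.0 * self.g_to_a_fraction, 1)

    @property
    def transition_fraction(self) -> float:
        if not self.defined:
            raise ValueError("fractions undefined: no events")
        ts = sum(self.counts[t] for t in self.counts
                 if t in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
        return ts / self.total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ref, alt in SUBSTITUTION_TYPES:
            c = self.counts[(ref, alt)]
            rows.append({
                "substitution": f"{ref}>{alt}",
                "count": c,
                "fraction": (c / self.total) if self.defined else float("nan"),
            })
        return pd.DataFrame(rows)


def summarize_spectrum(events: Iterable[MutationEvent]) -> SpectrumSummary:
    """Tabulate events by ordered substitution type (order-invariant)."""
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    total = 0
    for ev in events:
        counts[(ev.ref_base, ev.alt_base)] += 1
        total += 1
    return SpectrumSummary(counts=counts, total=total)


def position_histogram(events: Iterable[MutationEvent], length: int,
                       bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Binned counts of mutated positions along the CDS.

    Bin edges are half-open ``[start, end)`` with the final edge closed, so
    every position in ``[1, length]`` lands in exactly one bin and the bin
    total conserves the number of events.
    """
    if bins < 1:
        raise ValueError("bin count must be >= 1")
    positions = np.array([ev.position for ev in events], dtype=float)
    if positions.size and (positions.min() < 1 or positions.max() > length):
        raise ValueError(f"positions outside the [1, {length}] CDS")
    counts, edges = np.histogram(positions, bins=bins, range=(1, length + 1))
    return counts, edges


def positional_fit_test(events: Sequence[MutationEvent], length: int, bins: int = 10,
                        expected_site_weights: np.ndarray | None = None):
    """Chi-square goodness of fit of the mutated-position histogram.

    By default the null is positional uniformity. When the copying process has
    base-dependent hazards (any non-uniform spectrum), pass the per-site
    expected weights so the test is against the process's own positional law.
    Returns the scipy ``Power_divergenceResult`` (statistic, pvalue).
    """
    counts, edges = position_histogram(events, length, bins)
    if expected_site_weights is None:
        expected = np.full(bins, counts.sum() / bins)
    else:
        w = np.asarray(expected_site_weights, dtype=float)
        if w.shape != (length,):
            raise ValueError("expected_site_weights must have one entry per site")
        site_pos = np.arange(1, length + 1, dtype=float)
        bin_w, _ = np.histogram(site_pos, bins=bins, range=(1, length + 1), weights=w)
        expected = bin_w / bin_w.sum() * counts.sum()
    return stats.chisquare(counts, f_exp=expected)
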