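"""Substitution spectrum of the error-prone copying process.

The spectrum is stored as a *joint* probability mass over the 12 ordered base
changes: ``weights[ref, alt]`` is the fraction of all substitution events that
are ref->alt. Reverse transcription by HIV-1 RT is dominated by G>A
transitions, so the default places 62.3% of the total mass on G>A and spreads
the remainder uniformly over the other 11 types.

Because the joint mass fixes the marginal event-type distribution, per-site
hazards must depend on the (current) base: a site whose base carries more of
the substitution mass than its share of the composition mutates faster. The
multiplier for base b is ``mass_from(b) / composition(b)``, which keeps the
sequence-averaged per-site rate equal to the configured mutation rate while
making the sampled event types converge to the configured mass exactly.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np

from .core import BASE_INDEX, BASES, MutationEvent, ReferenceGene, SUBSTITUTION_TYPES

_ROW_TOL = 1e-9


class MutationSpectrum:
    """Joint distribution over the 12 ordered substitutions.

    Parameters
    ----------
    weights : (4, 4) array-like
        ``weights[i, j]`` = probability an event changes base i into base j
        (A, C, G, T order). Diagonal must be zero; total must be 1 within 1e-9.
    """

    def __init__(self, weights) -> None:
        w = np.array(weights, dtype=float)
        if w.shape != (4, 4):
            raise ValueError("weights must be a 4x4 matrix in ACGT order")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if np.abs(np.diag(w)).max() > 0:
            raise ValueError("self-substitutions are excluded (diagonal must be 0)")
        total = w.sum()
        if abs(total - 1.0) > _ROW_TOL:
            raise ValueError(f"weights must sum to 1 within {_ROW_TOL}; got {total}")
        self.weights = w / total

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_type_fractions(cls, fractions: Mapping[tuple[str, str], float]) -> "MutationSpectrum":
        w = np.zeros((4, 4))
        for (ref, alt), frac in fractions.items():
            w[BASE_INDEX[ref], BASE_INDEX[alt]] = frac
        return cls(w)

    @classmethod
    def g_to_a_biased(cls, g_to_a_fraction: float = 0.623) -> "MutationSpectrum":
        """G>A carries ``g_to_a_fraction`` of the mass; the 11 other types share
        the remainder uniformly. The default reproduces the G>A dominance of
        HIV-1 reverse transcription."""
        if not 0 <= g_to_a_fraction <= 1:
            raise ValueError("fraction must lie in [0, 1]")
        rest = (1.0 - g_to_a_fraction) / 11.0
        w = np.full((4, 4), rest)
        np.fill_diagonal(w, 0.0)
        w[BASE_INDEX["G"], BASE_INDEX["A"]] = g_to_a_fraction
        return cls(w)

    @classmethod
    def default(cls) -> "MutationSpectrum":
        return cls.g_to_a_biased()

    @classmethod
    def uniform(cls) -> "MutationSpectrum":
        w = np.full((4, 4), 1.0 / 12.0)
        np.fill_diagonal(w, 0.0)
        return cls(w)

    # -- views ------------------------------------------------------------
    def type_fraction(self, ref: str, alt: str) -> float:
        return float(self.weights[BASE_INDEX[ref], BASE_INDEX[alt]])

    def mass_from_base(self) -> np.ndarray:
        """Total substitution mass originating from each reference base."""
        return self.weights.sum(axis=1)

    def conditional_rows(self) -> np.ndarray:
        """P(alt | mutation at a site of given base); rows sum to 1.

        A base carrying zero mass gets a zero row (it never mutates).
        """
        mass = self.mass_from_base()
        rows = np.zeros_like(self.weights)
        nz = mass > 0
        rows[nz] = self.weights[nz] / mass[nz, None]
        return rows

    def site_rate_multipliers(self, composition) -> np.ndarray:
        """Per-base hazard multiplier relative to the mean rate.

        ``composition`` is the base-composition vector (fractions of A, C, G,
        T). The multipliers satisfy sum(composition * multiplier) == 1, so a
        mean rate m yields exactly m mutations per site per cycle on average.
        """
        f = np.asarray(composition, dtype=float)
        if f.shape != (4,) or abs(f.sum() - 1.0) > 1e-6 or (f < 0).any():
            raise ValueError("composition must be 4 non-negative fractions summing to 1")
        mass = self.mass_from_base()
        if ((mass > 0) & (f == 0)).any():
            missing = [BASES[i] for i in range(4) if mass[i] > 0 and f[i] == 0]
            raise ValueError(
                f"spectrum assigns mass to base(s) {missing} absent from the sequence"
            )
        mult = np.zeros(4)
        nz = f > 0
        mult[nz] = mass[nz] / f[nz]
        return mult

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g_to_a = self.type_fraction("G", "A")
        return f"MutationSpectrum(G>A={g_to_a:.3f})"


def sample_events(spectrum: MutationSpectrum, reference: ReferenceGene,
                  n_events: int, *, seed: int) -> list[MutationEvent]:
    """Draw substitution events on the reference from the configured spectrum.

    Positions are drawn proportionally to the per-site hazard and the observed
    base is drawn from the conditional row of the site's reference base, so the
    realized type frequencies converge to ``spectrum.weights``.
    """
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    rng = np.random.default_rng(seed)
    codes = reference.codes()
    mult = spectrum.site_rate_multipliers(reference.base_composition())
    site_w = mult[codes]
    p = site_w / site_w.sum()
    positions = rng.choice(reference.length, size=n_events, p=p)
    cum = np.cumsum(spectrum.conditional_rows(), axis=1)
    u = rng.random(n_events)
    alts = (u[:, None] < cum[codes[positions]]).argmax(axis=1)
    return [
        MutationEvent(int(pos) + 1, BASES[codes[pos]], BASES[alt])
        for pos, alt in zip(positions, alts)
    ]
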