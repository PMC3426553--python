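"""Stochastic simulator of mutation accumulation over retroviral replication cycles.

Each replication (reverse-transcription) cycle copies every genome in the
population once. During copying every site mutates independently — a Bernoulli
trial whose probability is the configured mean rate scaled by the base-specific
hazard of the substitution spectrum — and the new base is drawn from the
spectrum's conditional row. Back-mutation falls out naturally: a site that
reverts to the reference no longer counts as mutated. Optional ingredients:

* copy-choice recombination between co-packaged genomes (template switching at
  a per-position rate, active for the configured fraction of virions), and
* a cis-lethal mask: any substitution inside the masked positions removes the
  genome, which is replaced by a copy of a surviving genome (purifying
  selection on vector cis-acting regions; no positive selection is modelled).

Generation labels follow the convention that library generation F_k has been
through k+1 reverse-transcription cycles (the production of the parental
vector stock is itself one error-prone copying step).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core import BASES, CloneRecord, MutationEvent, ReferenceGene
from .spectrum import MutationSpectrum


class ExtinctionError(RuntimeError):
    """All genomes were removed by the cis-lethal mask."""


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of one simulated evolution experiment.

    Parameters
    ----------
    mutation_rate : float
        Mean substitution probability per nucleotide per replication cycle.
        Literature values for HIV-1 RT are 1–3.4e-5; the regime emulated here
        runs near 1e-4 per nt per infectious cycle.
    generations : int
        Number of reverse-transcription cycles to simulate (>= 0).
    population_size : int
        Genomes carried per generation.
    spectrum : MutationSpectrum
        Substitution-type mass; defaults to the G>A-dominated spectrum.
    recombination_switch_rate : float
        Per-position template-switch probability during copying.
    heterozygous_virion_fraction : float
        Probability that a genome is co-packaged with a distinct partner and
        therefore eligible for recombination. The source experiments run the
        diversification phase at high MOI, which favours heterozygous virions,
        but never quantify the fraction; the default of 0 is a placeholder.
    cis_lethal_mask : frozenset[int]
        1-based positions where any substitution removes the genome.
    seed : int
        Mandatory; there is no silent default for stochastic entry points.
    """

    mutation_rate: float
    generations: int
    population_size: int
    seed: int
    spectrum: MutationSpectrum = field(default_factory=MutationSpectrum.default)
    recombination_switch_rate: float = 0.0
    heterozygous_virion_fraction: float = 0.0
    cis_lethal_mask: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if not 0.0 <= self.recombination_switch_rate <= 1.0:
            raise ValueError("recombination_switch_rate must lie in [0, 1]")
        if not 0.0 <= self.heterozygous_virion_fraction <= 1.0:
            raise ValueError("heterozygous_virion_fraction must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        object.__setattr__(self, "cis_lethal_mask", frozenset(self.cis_lethal_mask))

    def validate_against(self, reference: ReferenceGene) -> None:
        bad = [p for p in self.cis_lethal_mask if not 1 <= p <= reference.length]
        if bad:
            raise ValueError(f"mask positions outside [1, {reference.length}]: {sorted(bad)[:5]}")


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation summary written by the simulator."""

    generation_label: str
    cycle_count: int
    mean_mutations_per_genome: float
    genomes_surviving: int


@dataclass(frozen=True)
class SimulatedLibrary:
    clones: tuple[CloneRecord, ...]
    generations: tuple[GenerationRecord, ...]
    reference: ReferenceGene
    config: EvolutionConfig


def generation_label(cycles: int) -> str:
    """Label for a library that has been through ``cycles`` copying steps."""
    return "parental" if cycles == 0 else f"F{cycles - 1}"


def _mosaic_states(k: int, n: int, switch_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean (k, n) matrix: False = copy parent A, True = parent B.

    Copying starts on a uniformly chosen parent and switches template at each
    subsequent position with probability ``switch_rate``.
    """
    start = rng.integers(0, 2, size=(k, 1))
    if n == 1:
        return start.astype(bool)
    switches = (rng.random((k, n - 1)) < switch_rate).astype(np.int64)
    cum = np.hstack([np.zeros((k, 1), dtype=np.int64), np.cumsum(switches, axis=1)])
    return ((start + cum) % 2).astype(bool)


def simulate_recombination(parent_a: str, parent_b: str, switch_rate: float,
                           *, seed: int) -> str:
    """Copy-choice recombination between two co-packaged sequences.

    The offspring is a mosaic of the two parents: every position equals the
    corresponding position of the currently copied template.
    """
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal length")
    if not 0.0 <= switch_rate <= 1.0:
        raise ValueError("switch_rate must lie in [0, 1]")
    if not parent_a:
        raise ValueError("zero-length parents are rejected")
    rng = np.random.default_rng(seed)
    a = np.frombuffer(parent_a.encode(), dtype="S1")
    b = np.frombuffer(parent_b.encode(), dtype="S1")
    state = _mosaic_states(1, len(a), switch_rate, rng)[0]
    return np.where(state, b, a).tobytes().decode()


def simulate_library(config: EvolutionConfig, reference: ReferenceGene) -> SimulatedLibrary:
    """Run the generation loop and return clones plus per-generation summaries.

    Deterministic given ``config.seed``. Raises :class:`ExtinctionError` if the
    cis-lethal mask removes every genome in some cycle.
    """
    config.validate_against(reference)
    rng = np.random.default_rng(config.seed)
    codes = reference.codes()
    n = reference.length
    pop = config.population_size

    mult = config.spectrum.site_rate_multipliers(reference.base_composition())
    if config.mutation_rate * mult.max() > 1.0:
        raise ValueError(
            "mutation_rate times the largest base-specific hazard exceeds 1; "
            "per-site Bernoulli probabilities must stay in [0, 1]"
        )
    cond_cum = np.cumsum(config.spectrum.conditional_rows(), axis=1)

    seq = np.tile(codes, (pop, 1))
    intro = np.zeros((pop, n), dtype=np.int32)  # cycle the current non-ref base arose; 0 = ref
    mask_idx = np.array(sorted(config.cis_lethal_mask), dtype=np.int64) - 1

    records: list[GenerationRecord] = []
    recombine = (config.heterozygous_virion_fraction > 0.0
                 and config.recombination_switch_rate > 0.0 and pop > 1)

    for cycle in range(1, config.generations + 1):
        if recombine:
            het = rng.random(pop) < config.heterozygous_virion_fraction
            partners = rng.integers(0, pop, size=pop)
            rows = np.flatnonzero(het & (partners != np.arange(pop)))
            if rows.size:
                a_seq = seq[rows].copy()
                b_seq = seq[partners[rows]]
                a_intro = intro[rows].copy()
                b_intro = intro[partners[rows]]
                state = _mosaic_states(rows.size, n, config.recombination_switch_rate, rng)
                seq[rows] = np.where(state, b_seq, a_seq)
                intro[rows] = np.where(state, b_intro, a_intro)

        if config.mutation_rate > 0.0:
            p = config.mutation_rate * mult[seq]
            hits = rng.random(seq.shape) < p
            gi, si = np.nonzero(hits)
            if gi.size:
                u = rng.random(gi.size)
                current = seq[gi, si]
                alts = (u[:, None] < cond_cum[current]).argmax(axis=1).astype(np.int8)
                seq[gi, si] = alts
                intro[gi, si] = np.where(alts == codes[si], 0, cycle)

        surviving = pop
        if mask_idx.size:
            dead = (seq[:, mask_idx] != codes[mask_idx]).any(axis=1)
            n_dead = int(dead.sum())
            surviving = pop - n_dead
            if surviving == 0:
                raise ExtinctionError(
                    f"cis-lethal mask removed all {pop} genomes at cycle {cycle} "
                    f"(generation {generation_label(cycle)})"
                )
            if n_dead:
                survivors = np.flatnonzero(~dead)
                repl = rng.choice(survivors, size=n_dead)
                dead_rows = np.flatnonzero(dead)
                seq[dead_rows] = seq[repl]
                intro[dead_rows] = intro[repl]

        mean_mut = float((seq != codes).sum(axis=1).mean())
        records.append(GenerationRecord(generation_label(cycle), cycle, mean_mut, surviving))

    label = generation_label(config.generations)
    width = max(4, len(str(pop)))
    ascii_lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    ascii_seq = ascii_lut[seq]

    clones = []
    diff_g, diff_s = np.nonzero(seq != codes)
    split = np.searchsorted(diff_g, np.arange(pop))
    bounds = np.append(split, diff_g.size)
    for i in range(pop):
        lo, hi = bounds[i], bounds[i + 1]
        sites = diff_s[lo:hi]
        muts = tuple(
            MutationEvent(int(s) + 1, BASES[codes[s]], BASES[seq[i, s]]) for s in sites
        )
        cycles = tuple(int(intro[i, s]) for s in sites)
        clones.append(
            CloneRecord(
                clone_id=f"{label}_clone{i:0{width}d}",
                generation_label=label,
                mutations=muts,
                sequence=ascii_seq[i].tobytes().decode(),
                mutation_cycles=cycles,
            )
        )
    return SimulatedLibrary(tuple(clones), tuple(records), reference, config)


def per_clone_counts(library: SimulatedLibrary | Iterable[CloneRecord]) -> np.ndarray:
    clones = library.clones if isinstance(library, SimulatedLibrary) else tuple(library)
    return np.array([c.n_mutations for c in clones], dtype=np.int64)
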