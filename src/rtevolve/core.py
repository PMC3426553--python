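"""Core sequence containers: reference gene, substitution events, sequenced clones.

Coordinates are 1-based and relative to the start of the coding sequence,
matching how positions are reported when Sanger-sequencing a fixed-length
PCR amplicon of the transgene. Only substitutions are modelled; indels are
rejected everywhere (clone and reference lengths must match).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: ordered substitution types (ref, alt) — 12 entries, row-major by reference base
SUBSTITUTION_TYPES = tuple((r, a) for r in BASES for a in BASES if r != a)
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

_ASCII = np.frombuffer("ACGT".encode(), dtype=np.uint8)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    codes = np.full(raw.shape, -1, dtype=np.int8)
    for i, b in enumerate(_ASCII):
        codes[raw == b] = i
    if (codes < 0).any():
        bad = int(np.flatnonzero(codes < 0)[0])
        raise ValueError(
            f"non-ACGT character {sequence[bad]!r} at position {bad + 1}; "
            "ambiguity codes are rejected, not skipped"
        )
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _ASCII[np.asarray(codes, dtype=np.int8)].tobytes().decode()


@dataclass(frozen=True)
class ReferenceGene:
    """The target coding sequence of the evolution experiment.

    Parameters
    ----------
    name : str
        Identifier used in FASTA output.
    sequence : str
        Upper-case sequence over the strict alphabet {A, C, G, T}.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError("zero-length reference is rejected")
        encode_sequence(self.sequence)  # validates the alphabet

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        return encode_sequence(self.sequence)

    def base_composition(self) -> np.ndarray:
        """Fraction of A, C, G, T in the sequence (sums to 1)."""
        counts = np.bincount(self.codes(), minlength=4)
        return counts / counts.sum()

    @classmethod
    def random(cls, length: int = 783, *, seed: int, name: str = "synthetic_gene",
               composition: np.ndarray | None = None) -> "ReferenceGene":
        """Generate a synthetic reference of the given length.

        The default emulates a 783-nt coding sequence (the size of the human
        deoxycytidine-kinase CDS) with near-uniform base composition. ``seed``
        is mandatory, as for every stochastic entry point in this package.
        """
        if length < 1:
            raise ValueError("length must be positive")
        rng = np.random.default_rng(seed)
        p = None if composition is None else np.asarray(composition, dtype=float)
        codes = rng.choice(4, size=length, p=p).astype(np.int8)
        return cls(name=name, sequence=decode_sequence(codes))

    @classmethod
    def balanced(cls, length: int = 780, *, seed: int,
                 name: str = "balanced_gene") -> "ReferenceGene":
        """Reference with exactly equal base counts (length must divide by 4)."""
        if length % 4:
            raise ValueError("balanced reference needs a length divisible by 4")
        rng = np.random.default_rng(seed)
        codes = np.repeat(np.arange(4, dtype=np.int8), length // 4)
        rng.shuffle(codes)
        return cls(name=name, sequence=decode_sequence(codes))


@dataclass(frozen=True, order=True)
class MutationEvent:
    """A single substitution: 1-based position, reference base, observed base."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based; got %d" % self.position)
        for b in (self.ref_base, self.alt_base):
            if b not in BASE_INDEX:
                raise ValueError(f"base {b!r} not in ACGT")
        if self.ref_base == self.alt_base:
            raise ValueError("self-substitutions are excluded")

    @property
    def is_transition(self) -> bool:
        return (self.ref_base, self.alt_base) in TRANSITIONS


@dataclass(frozen=True)
class CloneRecord:
    """A sequenced clone: its variant set relative to the reference.

    ``mutation_cycles`` is aligned with ``mutations`` and holds the replication
    cycle at which the currently observed base arose (simulator provenance;
    empty for clones read from FASTA).
    """

    clone_id: str
    generation_label: str
    mutations: tuple[MutationEvent, ...]
    sequence: str
    mutation_cycles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise ValueError("positions must be unique within a clone")
        if self.mutation_cycles and len(self.mutation_cycles) != len(self.mutations):
            raise ValueError("mutation_cycles must align with mutations")

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


def apply_mutations(reference: ReferenceGene | str, mutations) -> str:
    """Apply substitution events to the reference; inverse of mutation calling.

    Events must carry the correct reference base and occupy distinct positions.
    """
    seq = reference.sequence if isinstance(reference, ReferenceGene) else reference
    out = list(seq)
    seen: set[int] = set()
    for ev in mutations:
        if ev.position > len(seq):
            raise ValueError(f"position {ev.position} outside the {len(seq)}-nt CDS")
        if ev.position in seen:
            raise ValueError(f"duplicate position {ev.position}")
        seen.add(ev.position)
        if seq[ev.position - 1] != ev.ref_base:
            raise ValueError(
                f"reference base mismatch at {ev.position}: "
                f"sequence has {seq[ev.position - 1]}, event says {ev.ref_base}"
            )
        out[ev.position - 1] = ev.alt_base
    return "".join(out)
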