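"""File I/O: FASTA, mutation tables, plates, results, configuration.

All tabular files are TSV (UTF-8, Unix newlines) to avoid locale decimal
issues. Readers reject malformed data with the offending line/row number
rather than coercing it; writers are deterministic given their inputs.
Stored mutation tables state the coordinate convention in a header comment.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CloneRecord, MutationEvent, ReferenceGene
from .calling import call_mutations
from .screening import PLATE_COLUMNS, ViabilityPlate

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ("clone_id", "position", "ref", "alt", "cycle_introduced")
_COORDINATE_HEADER = "# positions are 1-based relative to the CDS start; substitutions only"
_LABEL_RE = re.compile(r"^(F\d+|parental)_")


def read_fasta(path) -> dict[str, str]:
    """Read named sequences, preserving record order; sequences uppercased.

    Alphabet validation happens downstream (mutation calling), so arbitrary
    IUPAC text survives reading. Malformed files fail with a line number;
    an empty file yields an empty collection with a warning.
    """
    path = Path(path)
    text = path.read_text()
    first_content = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            first_content = (lineno, line)
            break
    if first_content is None:
        logger.warning("empty FASTA file %s", path)
        return {}
    if not first_content[1].lstrip().startswith(">"):
        raise ValueError(
            f"{path}: malformed FASTA — line {first_content[0]} is sequence data "
            "before any '>' header"
        )
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 60) -> None:
    """Write sequences wrapped at ``width`` columns (round-trips read_fasta)."""
    seq_records = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    path = Path(path)
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def parse_generation_label(clone_id: str) -> str | None:
    """Extract the generation label encoded in ids like ``F16_clone0007``."""
    m = _LABEL_RE.match(clone_id)
    return m.group(1) if m else None


def write_mutation_tsv(clones: Iterable[CloneRecord], path) -> None:
    rows = []
    for clone in clones:
        cycles = clone.mutation_cycles or (None,) * len(clone.mutations)
        for ev, cyc in zip(clone.mutations, cycles):
            rows.append((clone.clone_id, ev.position, ev.ref_base, ev.alt_base,
                         "" if cyc is None else cyc))
    df = pd.DataFrame(rows, columns=list(MUTATION_COLUMNS))
    with Path(path).open("w") as fh:
        fh.write(_COORDINATE_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_mutation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"clone_id": str, "ref": str, "alt": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mutation table missing column(s) {missing}")
    df["position"] = pd.to_numeric(df["position"], errors="raise", downcast="integer")
    return df


def mutation_events_from_frame(df: pd.DataFrame) -> list[MutationEvent]:
    return [MutationEvent(int(r.position), str(r.ref), str(r.alt))
            for r in df.itertuples()]


def clones_from_fasta(path, reference: ReferenceGene) -> list[CloneRecord]:
    """Load clone sequences and derive their variant sets versus the reference."""
    clones = []
    for name, seq in read_fasta(path).items():
        label = parse_generation_label(name) or "unknown"
        clones.append(CloneRecord(
            clone_id=name, generation_label=label,
            mutations=tuple(call_mutations(seq, reference)), sequence=seq,
        ))
    return clones


def write_plate_tsv(plate: ViabilityPlate, path) -> None:
    plate.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_plate_tsv(path) -> ViabilityPlate:
    """Strictly-validated plate reader; numeric errors name the data row."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: plate is missing column(s) {missing}")
    for col in ("concentration_nM", "readout"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric {col} {df.loc[bad[0], col]!r} at data row "
                f"{int(bad[0]) + 2}"
            )
        if converted.isna().any():
            raise ValueError(f"{path}: missing {col} at data row "
                             f"{int(df.index[converted.isna()][0]) + 2}")
        df[col] = converted
    return ViabilityPlate(df)


def write_results_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_config(path) -> dict:
    import yaml

    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
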