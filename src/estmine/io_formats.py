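"""Readers and writers for the formats the pipeline touches.

Sequence collections travel as FASTA (ESTs and unigenes in DNA, mature miRNA
references in the miRBase RNA dialect), folded structures as a small
tab-separated fixture format (id, dot-bracket, MFE), and every report as
UTF-8 TSV with a commented header line naming the tool version.

Canonical in-memory alphabets: DNA for ESTs/unigenes, RNA for mature miRNAs.
Conversions happen only here, at the I/O boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from ._sequtils import DNA_ALPHABET, RNA_ALPHABET, dna_to_rna, rna_to_dna

TISSUES = ("root", "stem", "leaf", "flower", "other")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (bad header, illegal character, duplicate id)."""


class FixtureError(ValueError):
    """Raised for malformed structure fixtures (column count, unbalanced brackets)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One EST, read or unigene: id, DNA sequence and an optional tissue tag."""

    id: str
    seq: str
    tissue: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.tissue is not None and self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue label {self.tissue!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA reference entry (RNA alphabet, 19-25 nt)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("mature miRNA id must be non-empty")
        if not 19 <= len(self.seq) <= 25:
            raise ValueError(
                f"{self.id}: mature length {len(self.seq)} outside 19-25 nt"
            )
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: illegal RNA characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def source_species(self) -> Optional[str]:
        """Three-letter species prefix of a miRBase-style name, when present."""
        head, _, rest = self.id.partition("-")
        return head if rest and len(head) == 3 and head.isalpha() else None


@dataclass(frozen=True)
class StructureFixture:
    """Precomputed secondary structure: dot-bracket plus MFE in kcal/mol."""

    id: str
    structure: str
    mfe: float

    def __post_init__(self) -> None:
        _check_balanced(self.structure, self.id)


def _check_balanced(structure: str, name: str) -> None:
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FixtureError(f"{name}: unbalanced brackets in structure")
        elif ch != ".":
            raise FixtureError(f"{name}: illegal structure character {ch!r}")
    if depth != 0:
        raise FixtureError(f"{name}: unbalanced brackets in structure")


def _normalize(seq: str, alphabet: Literal["dna", "rna"]) -> str:
    seq = seq.upper()
    if alphabet == "dna":
        seq = rna_to_dna(seq)
        allowed = DNA_ALPHABET
    elif alphabet == "rna":
        seq = dna_to_rna(seq)
        allowed = RNA_ALPHABET
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown alphabet {alphabet!r}")
    bad = set(seq) - allowed
    if bad:
        raise FastaParseError(f"illegal {alphabet.upper()} characters {sorted(bad)}")
    return seq


def read_fasta(
    path: str | Path,
    alphabet: Literal["dna", "rna"] = "dna",
    tissue: Optional[str] = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased and projected onto the requested alphabet
    (U->T for DNA, T->U for RNA).  The record id is the first
    whitespace-delimited header token; the remainder is kept as description.
    Duplicate ids and illegal characters are rejected with the offending
    record named.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FastaParseError(f"{path}: record {i} has an empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            seq = _normalize(str(rec.seq), alphabet)
        except FastaParseError as exc:
            raise FastaParseError(f"{path}: record {rec.id!r}: {exc}") from None
        desc = rec.description[len(rec.id) :].strip()
        records.append(SequenceRecord(id=rec.id, seq=seq, tissue=tissue, description=desc))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def read_mature_fasta(path: str | Path) -> list[MatureMirna]:
    """Read a mature-miRNA reference (miRBase 'mature' dialect, RNA alphabet)."""
    return [
        MatureMirna(id=r.id, seq=r.seq, description=r.description)
        for r in read_fasta(path, alphabet="rna")
    ]


def write_fasta(
    records: Sequence[SequenceRecord] | Sequence[MatureMirna],
    path: str | Path,
    width: int = 60,
) -> Path:
    """Write records as multi-line FASTA; round-trips exactly through read_fasta."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    if width < 1:
        raise ValueError("line width must be positive")
    path = Path(path)
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
    return path


def read_structure_fixtures(path: str | Path) -> list[StructureFixture]:
    """Read a TSV of (id, dot-bracket, mfe) structure fixtures.

    Comment lines starting with '#' and a literal header row are skipped;
    bracket balance is validated on read.
    """
    path = Path(path)
    fixtures: list[StructureFixture] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if row == ["id", "structure", "mfe"]:
                continue
            if len(row) != 3:
                raise FixtureError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            ident, structure, mfe_text = row
            try:
                mfe = float(mfe_text)
            except ValueError:
                raise FixtureError(f"{path}:{lineno}: bad MFE value {mfe_text!r}") from None
            fixtures.append(StructureFixture(id=ident, structure=structure, mfe=mfe))
    return fixtures


def write_structure_fixtures(
    fixtures: Iterable[StructureFixture], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(tsv_header(["id", "structure", "mfe"]))
        for fx in fixtures:
            fh.write(f"{fx.id}\t{fx.structure}\t{fx.mfe:g}\n")
    return path


def tsv_header(columns: Sequence[str]) -> str:
    """Standard two-line TSV prologue: tool-version comment plus column names."""
    from . import __version__

    return f"# estmine {__version__}\n" + "\t".join(columns) + "\n"
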