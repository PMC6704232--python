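"""FASTA input/output and nucleotide sequence containers.

All sequences are normalized to the RNA alphabet internally (``T`` -> ``U``,
case folded to upper) because the silencing machinery operates on RNA, while
trigger constructs are usually synthesized and cloned as DNA.  The original
alphabet of each record is remembered so sequences can be written back out
the way they came in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Unambiguous RNA alphabet.
RNA_BASES = frozenset("ACGU")

#: IUPAC ambiguity codes tolerated in transcripts (no pairing energy is
#: defined for them, so windows containing them are skipped downstream).
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")

_ALLOWED = RNA_BASES | AMBIGUITY_CODES

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class FastaError(ValueError):
    """Raised for malformed or otherwise unusable FASTA input."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated nucleotide sequence in the internal RNA alphabet.

    Parameters
    ----------
    identifier:
        Record identifier (first whitespace-delimited token of the header).
    residues:
        Upper-case RNA residues; may contain IUPAC ambiguity codes.
    original_alphabet:
        ``"DNA"`` if the input contained ``T``, else ``"RNA"``.
    description:
        Remainder of the FASTA header after the identifier.
    """

    identifier: str
    residues: str
    original_alphabet: str = "RNA"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("sequence identifier must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.identifier!r} is empty")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r} contains invalid symbols: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_ambiguous(self) -> bool:
        """True if any residue is an IUPAC ambiguity code."""
        return not set(self.residues) <= RNA_BASES

    @classmethod
    def from_raw(
        cls, identifier: str, raw: str, description: str = ""
    ) -> "NucleotideSequence":
        """Build a sequence from raw input, normalizing DNA to RNA."""
        residues, alphabet = normalize_residues(raw)
        return cls(identifier, residues, alphabet, description)

    def as_input_alphabet(self) -> str:
        """Residues written back in the alphabet the record arrived in."""
        if self.original_alphabet == "DNA":
            return self.residues.replace("U", "T")
        return self.residues


def normalize_residues(raw: str) -> tuple[str, str]:
    """Uppercase a raw sequence and map ``T`` to ``U``.

    Returns the normalized residues and the detected source alphabet
    (``"DNA"`` when the raw sequence contained ``T``/``t``).
    """
    upper = raw.upper()
    alphabet = "DNA" if "T" in upper else "RNA"
    residues = upper.replace("T", "U")
    bad = set(residues) - _ALLOWED
    if bad:
        raise FastaError(f"invalid sequence symbols: {sorted(bad)}")
    return residues, alphabet


def reverse_complement(s: NucleotideSequence | str) -> NucleotideSequence | str:
    """Reverse complement in the RNA alphabet (A<->U, C<->G).

    Accepts and returns either a plain string or a
    :class:`NucleotideSequence`; an involution in both cases.
    """
    if isinstance(s, str):
        return s.translate(_COMPLEMENT)[::-1]
    rc = s.residues.translate(_COMPLEMENT)[::-1]
    return replace(s, residues=rc)


@dataclass
class TranscriptDatabase:
    """An ordered, identifier-unique collection of transcripts."""

    entries: list[NucleotideSequence] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        self._by_id: dict[str, NucleotideSequence] = {}
        for entry in self.entries:
            if entry.identifier in self._by_id:
                raise FastaError(
                    f"duplicate sequence identifier {entry.identifier!r}"
                )
            self._by_id[entry.identifier] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[NucleotideSequence]:
        return iter(self.entries)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._by_id

    def __getitem__(self, identifier: str) -> NucleotideSequence:
        try:
            return self._by_id[identifier]
        except KeyError:
            raise KeyError(
                f"unknown transcript identifier {identifier!r}"
            ) from None

    @property
    def identifiers(self) -> list[str]:
        return [e.identifier for e in self.entries]


def _precheck_fasta(path: Path) -> None:
    """Light syntactic check so parse errors can name the offending line.

    Bio.SeqIO is deliberately permissive; this catches the common failure
    modes (no header, stray sequence before the first header).
    """
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                seen_header = True
                if len(stripped) == 1:
                    raise FastaError(f"{path}: empty FASTA header at line {lineno}")
            elif not seen_header:
                raise FastaError(
                    f"{path}: sequence data before first '>' header at line {lineno}"
                )
        if not seen_header:
            raise FastaError(f"{path}: no FASTA records found")


def read_fasta(path: str | Path) -> TranscriptDatabase:
    """Read a (multi-)FASTA file into a :class:`TranscriptDatabase`.

    Records are normalized (T->U, upper case), order is preserved and the
    description after the first whitespace is retained.  Duplicate
    identifiers, empty files and malformed records raise :class:`FastaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _precheck_fasta(path)
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        if len(record.seq) == 0:
            raise FastaError(f"{path}: record {record.id!r} has no sequence")
        description = record.description
        if description.startswith(record.id):
            description = description[len(record.id) :].strip()
        try:
            entries.append(
                NucleotideSequence.from_raw(record.id, str(record.seq), description)
            )
        except FastaError as exc:
            raise FastaError(f"{path}: record {record.id!r}: {exc}") from None
    db = TranscriptDatabase(entries, source_path=str(path))
    logger.info("read %d records from %s", len(db), path)
    return db


def write_fasta(
    sequences: Iterable[NucleotideSequence] | TranscriptDatabase,
    path: str | Path,
    line_width: int = 60,
    input_alphabet: bool = False,
) -> None:
    """Write sequences as FASTA, wrapped at ``line_width`` columns.

    With ``input_alphabet=True`` each record is written in the alphabet it
    was read in (DNA records get their ``T`` back).
    """
    records = []
    for seq in sequences:
        residues = seq.as_input_alphabet() if input_alphabet else seq.residues
        records.append(
            SeqRecord(Seq(residues), id=seq.identifier, description=seq.description)
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)
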