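"""FASTA input/output with alphabet validation.

Thin wrappers around :mod:`Bio.SeqIO` that enforce the alphabets used by the
pipeline (nucleotide ``ACGTN``, protein = 20 canonical residues plus ``X``)
and parse headers as ``id`` + ``description`` at the first whitespace.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from npmine.errors import ValidationError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

Alphabet = Literal["nucleotide", "protein"]

_ALPHABETS: dict[str, frozenset[str]] = {
    "nucleotide": NUCLEOTIDE_ALPHABET,
    "protein": PROTEIN_ALPHABET,
}


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA entry: ``id`` is the header token before the first space."""

    id: str
    description: str
    sequence: str


def validate_sequence(seq: str, alphabet: Alphabet, name: str = "?") -> str:
    """Uppercase *seq* and reject characters outside *alphabet*."""
    seq = seq.upper()
    allowed = _ALPHABETS[alphabet]
    bad = set(seq) - allowed
    if bad:
        raise ValidationError(
            f"record {name!r}: illegal {alphabet} characters {sorted(bad)}"
        )
    if not seq:
        raise ValidationError(f"record {name!r}: empty sequence")
    return seq


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[FastaRecord]:
    """Read a FASTA file, tolerant of wrapped lines and CRLF endings.

    Raises :class:`ValidationError` on an empty file or on a record whose
    sequence contains characters outside the requested alphabet.
    """
    path = Path(path)
    text = path.read_text().replace("\r\n", "\n")
    records: list[FastaRecord] = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        desc = rec.description
        # SeqIO's description includes the id; keep only the free text.
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        seq = validate_sequence(str(rec.seq), alphabet, name=rec.id)
        records.append(FastaRecord(id=rec.id, description=desc, sequence=seq))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[tuple[str, str, str]] | Iterable[FastaRecord],
    path: str | Path,
    width: int = 60,
) -> int:
    """Write records (``(id, description, sequence)`` tuples or
    :class:`FastaRecord`) as wrapped FASTA. Returns the number written."""
    path = Path(path)
    seqrecs = []
    for rec in records:
        if isinstance(rec, FastaRecord):
            rid, desc, seq = rec.id, rec.description, rec.sequence
        else:
            rid, desc, seq = rec
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        count = writer.write_file(seqrecs)
    return count
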