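"""Packaged text fixtures: the published precursor inventory and the
printed mature-peptide table, used both as regression anchors and as the
unit library for the synthetic-transcriptome generator.

The printed peptide rows include their flanking basic residues and mark
sulfated tyrosines with an inline ``(SOH)`` token after the residue;
helpers here strip the tokens and recover the marked positions.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class PrecursorInventoryRow:
    """One precursor in the published inventory."""

    name: str
    family_label: str
    family: str
    contigs: tuple[str, ...]
    transcript_length_bp: int
    reference_accession: str
    race5: bool
    race3: bool
    evalue: float
    score: float
    genbank_accession: str


@dataclass(frozen=True)
class MaturePeptideRow:
    """One printed mature-peptide (variant) row."""

    precursor: str
    table1_name: str
    variant: str
    printed_sequence: str

    @property
    def stripped_sequence(self) -> str:
        return strip_ptm_tokens(self.printed_sequence)


def _read_tsv(name: str) -> list[dict[str, str]]:
    text = resources.files("npmine.data").joinpath(name).read_text()
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


def strip_ptm_tokens(printed: str) -> str:
    """Remove inline ``(SOH)`` sulfation tokens from a printed sequence."""
    return re.sub(r"\(SOH\)", "", printed)


def sulfation_marked_positions(printed: str) -> list[int]:
    """1-based positions (in the stripped sequence) of residues marked
    ``(SOH)`` in a printed peptide row."""
    positions = []
    stripped_len = 0
    for token in re.split(r"(\(SOH\))", printed):
        if token == "(SOH)":
            positions.append(stripped_len)
        else:
            stripped_len += len(token)
    return positions


def load_precursor_inventory() -> list[PrecursorInventoryRow]:
    """The published 11-precursor inventory."""
    rows = []
    for rec in _read_tsv("table1_precursors.tsv"):
        rows.append(
            PrecursorInventoryRow(
                name=rec["name"],
                family_label=rec["family_label"],
                family=rec["family"],
                contigs=tuple(rec["contigs"].split(",")),
                transcript_length_bp=int(rec["transcript_length_bp"]),
                reference_accession=rec["reference_accession"],
                race5=rec["race5"] == "+",
                race3=rec["race3"] == "+",
                evalue=float(rec["evalue"]),
                score=float(rec["score"]),
                genbank_accession=rec["genbank_accession"],
            )
        )
    return rows


def load_mature_peptides() -> list[MaturePeptideRow]:
    """The printed mature-peptide rows (flanks included, PTM tokens kept)."""
    return [
        MaturePeptideRow(
            precursor=rec["precursor"],
            table1_name=rec["table1_name"],
            variant=rec["variant"],
            printed_sequence=rec["printed_sequence"],
        )
        for rec in _read_tsv("table2_mature_peptides.tsv")
    ]


def mature_peptides_by_precursor() -> dict[str, list[MaturePeptideRow]]:
    grouped: dict[str, list[MaturePeptideRow]] = {}
    for row in load_mature_peptides():
        grouped.setdefault(row.precursor, []).append(row)
    return grouped


def fixture_precursor_groups():
    """Process every printed peptide row (trim flank, terminal PTMs) and
    group by precursor, ready for family classification. Single-row
    precursors get their internal cleavage sites counted, as the GPB5 rule
    requires."""
    from npmine.families import PrecursorPeptides
    from npmine.maturation import apply_terminal_ptms, trim_basic_flank
    from npmine.precursor import find_cleavage_sites

    groups = []
    for precursor, rows in mature_peptides_by_precursor().items():
        peptides = []
        pos = 0
        for row in rows:
            pep, flank = trim_basic_flank(row.stripped_sequence)
            peptides.append(
                apply_terminal_ptms(pep, flank, source_span=(pos, pos + len(pep)))
            )
            pos += len(pep) + len(flank)
        n_sites = (
            len(find_cleavage_sites(rows[0].stripped_sequence))
            if len(rows) == 1
            else len(rows) - 1
        )
        groups.append(
            PrecursorPeptides(
                subject_id=precursor, peptides=peptides, n_cleavage_sites=n_sites
            )
        )
    return groups
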