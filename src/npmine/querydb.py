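"""Curated query-set construction for the translated homology search.

Known neuropeptide / peptide-hormone protein records (identifier + free-text
description + sequence) are filtered by keyword: a record is kept when its
description contains at least one include term and no exclude term. Exclude
terms always dominate. Short all-caps terms such as ``NP`` are matched as
whole words (word boundaries) so that two-letter abbreviations do not fire on
accidental substrings; every other term is a plain case-insensitive
substring. The surviving records form the local peptide database that is
written out as protein FASTA.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from npmine.errors import ConfigurationError, ValidationError
from npmine.io import PROTEIN_ALPHABET, FastaRecord, read_fasta, write_fasta

logger = logging.getLogger(__name__)

#: Include / exclude keywords used to curate the query database of known
#: secreted peptides, mirroring a UniProt keyword search for neuropeptides
#: and hormones while dropping receptors, enzymes and generic annotations.
DEFAULT_INCLUDE_TERMS = ("np", "hormone", "neurohormone")
DEFAULT_EXCLUDE_TERMS = (
    "receptor",
    "receptor associated",
    "hypothetical",
    "uncharacterized",
    "signal",
    "cytochrome",
    "esterase",
    "transferase",
    "binding protein",
    "hydrolase",
    "lipase",
    "inducible protein",
    "methyltransferase",
    "transmembrane",
)


@dataclass(frozen=True)
class AnnotationRecord:
    """A known-peptide database entry used as a search query."""

    accession: str
    description: str
    sequence: str
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.accession}: non-canonical residues {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


def _is_word_term(term: str) -> bool:
    # single short tokens are matched with word boundaries; phrases and
    # longer words as substrings
    return " " not in term and len(term) <= 3


@dataclass(frozen=True)
class KeywordFilter:
    """Case-insensitive description filter; exclusion dominates inclusion."""

    include_terms: tuple[str, ...] = DEFAULT_INCLUDE_TERMS
    exclude_terms: tuple[str, ...] = DEFAULT_EXCLUDE_TERMS

    def __post_init__(self) -> None:
        if not self.include_terms:
            raise ConfigurationError("KeywordFilter needs at least one include term")
        object.__setattr__(
            self, "include_terms", tuple(t.lower() for t in self.include_terms)
        )
        object.__setattr__(
            self, "exclude_terms", tuple(t.lower() for t in self.exclude_terms)
        )

    @staticmethod
    def _matches(term: str, description: str) -> bool:
        if _is_word_term(term):
            return re.search(rf"\b{re.escape(term)}\b", description) is not None
        return term in description

    def accepts(self, description: str) -> bool:
        desc = description.lower()
        if any(self._matches(t, desc) for t in self.exclude_terms):
            return False
        return any(self._matches(t, desc) for t in self.include_terms)

    @classmethod
    def from_file(cls, path: str | Path) -> "KeywordFilter":
        """Load ``include_terms`` / ``exclude_terms`` from YAML or JSON."""
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        if not isinstance(data, dict) or "include_terms" not in data:
            raise ConfigurationError(f"{path}: expected a mapping with include_terms")
        return cls(
            include_terms=tuple(data["include_terms"]),
            exclude_terms=tuple(data.get("exclude_terms", ())),
        )


@dataclass
class QuerySet:
    """Filtered, accession-deduplicated query records plus their provenance."""

    records: list[AnnotationRecord] = field(default_factory=list)
    provenance: KeywordFilter | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def filter_annotation_records(
    records: list[AnnotationRecord], kw_filter: KeywordFilter
) -> QuerySet:
    """Apply the keyword filter, preserving input order.

    Records failing validation (empty sequence) are skipped with a warning;
    duplicate accessions collapse to the first occurrence. Duplicate
    *sequences* under distinct accessions are retained — the search stage
    deduplicates by hit, not by query.
    """
    seen: set[str] = set()
    kept: list[AnnotationRecord] = []
    skipped = 0
    for rec in records:
        if not rec.sequence:  # defensive: AnnotationRecord normally rejects this
            skipped += 1
            logger.warning("skipping %s: empty sequence", rec.accession)
            continue
        if rec.accession in seen:
            continue
        if kw_filter.accepts(rec.description):
            kept.append(rec)
            seen.add(rec.accession)
    if skipped:
        logger.warning("%d record(s) skipped during filtering", skipped)
    return QuerySet(records=kept, provenance=kw_filter)


def write_query_fasta(qs: QuerySet, destination: str | Path) -> int:
    """Write the query set as 60-column protein FASTA; returns the count."""
    return write_fasta(
        [(r.accession, r.description, r.sequence) for r in qs.records],
        destination,
    )


def read_query_fasta(path: str | Path) -> QuerySet:
    """Read a protein FASTA back into an (unfiltered) :class:`QuerySet`."""
    try:
        recs = read_fasta(path, "protein")
    except ValidationError as err:
        if "no FASTA records" in str(err):
            return QuerySet(records=[])
        raise
    return QuerySet(
        records=[
            AnnotationRecord(accession=r.id, description=r.description, sequence=r.sequence)
            for r in recs
        ]
    )
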