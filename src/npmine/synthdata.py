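"""Synthetic transcriptomes with embedded precursors and ground truth.

Each synthetic precursor follows the canonical preprohormone layout: a Met,
a hydrophobic signal peptide whose last residues satisfy the (−3,−1)
small-residue rule, then repeated peptide units each followed by a basic
convertase flank. The peptide units come from the packaged mature-peptide
fixture table, one template per family, so synthetic tests double as
fixture tests. Proteins are back-translated with uniformly sampled
synonymous codons, wrapped in random UTRs (an in-frame stop guards the 5'
end so the encoded ORF is unambiguous) and embedded among two kinds of
decoys: uniform-random transcripts at matched length and GC, and
dinucleotide-shuffled copies of the precursor transcripts themselves
(hard decoys preserving local composition).

The ground truth for each precursor — signal boundary, CDS coordinates and
expected mature peptides — is derived by running the package's own
processing rules on the embedded protein, so truth is self-consistent by
construction and any pipeline disagreement is a genuine stage failure.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data import CodonTable

from npmine.errors import ValidationError
from npmine.fixtures import mature_peptides_by_precursor, strip_ptm_tokens
from npmine.maturation import (
    MaturePeptide,
    process_precursor_protein,
    trim_basic_flank,
)
from npmine.querydb import AnnotationRecord, QuerySet
from npmine.search import Transcript, translate_frame

_ACCEPTED_FLANKS = ("", "KR", "KK", "RR", "KKR")
_SIGNAL_CORE_RESIDUES = "LIV"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)


@dataclass(frozen=True)
class PrecursorSpec:
    """Blueprint of one synthetic precursor transcript."""

    name: str
    family: str
    signal_length: int
    peptide_units: tuple[tuple[str, str, int], ...]  # (unit, flank, copies)
    utr5_len: int = 30
    utr3_len: int = 40

    def __post_init__(self) -> None:
        if not self.peptide_units:
            raise ValidationError(f"{self.name}: no peptide units")
        if not 15 <= self.signal_length <= 30:
            raise ValidationError(f"{self.name}: signal length outside 15-30")
        for unit, flank, copies in self.peptide_units:
            if flank not in _ACCEPTED_FLANKS:
                raise ValidationError(f"{self.name}: invalid flank motif {flank!r}")
            if copies < 1:
                raise ValidationError(f"{self.name}: copies must be >= 1")
            if not unit:
                raise ValidationError(f"{self.name}: empty peptide unit")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one synthetic transcript."""

    transcript_id: str
    is_precursor: bool
    family: str = ""
    template: str = ""
    signal_length: int = 0
    cds_span: tuple[int, int] = (0, 0)  # 0-based half-open, forward strand
    protein: str = ""
    peptides: tuple[str, ...] = ()


@dataclass
class DatasetTruth:
    """Truth table for a generated dataset."""

    rows: list[TruthRow] = field(default_factory=list)

    def precursor_ids(self) -> set[str]:
        return {r.transcript_id for r in self.rows if r.is_precursor}

    def by_id(self) -> dict[str, TruthRow]:
        return {r.transcript_id: r for r in self.rows}

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(
                "transcript_id\tis_precursor\tfamily\ttemplate\tsignal_length"
                "\tcds_start\tcds_end\tprotein\tpeptides\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.transcript_id}\t{int(r.is_precursor)}\t{r.family}"
                    f"\t{r.template}\t{r.signal_length}\t{r.cds_span[0] + 1}"
                    f"\t{r.cds_span[1]}\t{r.protein}\t{'|'.join(r.peptides)}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DatasetTruth":
        rows = []
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            f = line.split("\t")
            rows.append(
                TruthRow(
                    transcript_id=f[0],
                    is_precursor=f[1] == "1",
                    family=f[2],
                    template=f[3],
                    signal_length=int(f[4]),
                    cds_span=(int(f[5]) - 1, int(f[6])),
                    protein=f[7],
                    peptides=tuple(f[8].split("|")) if f[8] else (),
                )
            )
        return cls(rows=rows)


def family_templates() -> list[PrecursorSpec]:
    """One precursor blueprint per peptide family, with units taken from
    the packaged mature-peptide fixture rows."""
    table2 = mature_peptides_by_precursor()

    def units(precursor: str, copies: int = 1):
        out = []
        for row in table2[precursor]:
            unit, flank = trim_basic_flank(strip_ptm_tokens(row.printed_sequence))
            out.append((unit, flank, copies))
        return tuple(out)

    return [
        PrecursorSpec(
            name="FDSIG_like",
            family="pedal_orcokinin_FDSIG",
            signal_length=24,
            peptide_units=units("BnFDSIG-like", copies=2),
        ),
        PrecursorSpec(
            name="NPF_like",
            family="NPF",
            signal_length=25,
            peptide_units=units("BnNPFL"),
        ),
        PrecursorSpec(
            name="VP_like",
            family="vasopressin",
            signal_length=22,
            peptide_units=units("BnVP-like"),
        ),
        PrecursorSpec(
            name="GPB5",
            family="GPB5",
            signal_length=24,
            peptide_units=units("BnGHB5"),
        ),
        PrecursorSpec(
            name="ILP_A",
            family="insulin_like",
            signal_length=23,
            peptide_units=units("BnILP-A"),
        ),
    ]


def benchmark_queries() -> QuerySet:
    """Query peptides for the synthetic benchmark: the template units,
    posing as entries of a known-peptide database."""
    records = []
    for spec in family_templates():
        for k, (unit, _flank, _copies) in enumerate(spec.peptide_units, start=1):
            records.append(
                AnnotationRecord(
                    accession=f"Q_{spec.name}_{k}",
                    description=f"{spec.family} neuropeptide hormone unit {k}",
                    sequence=unit,
                )
            )
    return QuerySet(records=records)


def build_precursor_protein(
    spec: PrecursorSpec, rng_seed: int
) -> tuple[str, list[MaturePeptide]]:
    """Construct the precursor protein and its expected mature peptides.

    Layout: Met, a sampled hydrophobic core (L/I/V), then Ala-Leu-Ala
    closing the signal so the (−3,−1) rule holds at the true boundary,
    then the (unit + flank) blocks. Expected peptides are derived by the
    package's own default processing rules applied at the true signal
    boundary. Deterministic under a fixed seed.
    """
    rng = random.Random(rng_seed)
    core = "".join(
        rng.choice(_SIGNAL_CORE_RESIDUES) for _ in range(spec.signal_length - 4)
    )
    signal = "M" + core + "ALA"
    assert len(signal) == spec.signal_length
    body = "".join(
        (unit + flank) * copies for unit, flank, copies in spec.peptide_units
    )
    protein = signal + body
    _sites, peptides = process_precursor_protein(protein, spec.signal_length)
    return protein, peptides


def back_translate_and_embed(
    protein: str, spec: PrecursorSpec, rng_seed: int, transcript_id: str = "synthetic"
) -> Transcript:
    """Encode *protein* as a transcript: uniformly sampled synonymous
    codons, a TAA stop, and random UTRs of the blueprint's lengths. When the 5'
    UTR has room, its last three bases are an in-frame TAA so the ORF
    cannot extend upstream of the intended start."""
    rng = random.Random(rng_seed)
    if protein[0] != "M":
        raise ValidationError("protein must start with Met")
    cds = "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein) + "TAA"
    utr5 = _random_nt(rng, max(0, spec.utr5_len - 3))
    if spec.utr5_len >= 3:
        utr5 += "TAA"
    utr3 = _random_nt(rng, spec.utr3_len)
    return Transcript(id=transcript_id, sequence=utr5 + cds + utr3)


def _random_nt(rng: random.Random, n: int, gc: float = 0.5) -> str:
    out = []
    for _ in range(n):
        if rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AT"))
    return "".join(out)


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Altschul–Erikson shuffle: a uniform-ish random sequence preserving
    the exact dinucleotide counts (hence length and base composition)."""
    if len(seq) <= 2:
        return seq
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(adj)
    for _ in range(1000):
        # pick a candidate "final edge" per vertex; must form an arborescence
        # into the terminal vertex for an Eulerian trail to exist
        final_edge = {
            v: rng.choice(adj[v]) for v in vertices if v != last
        }
        ok = True
        for v in final_edge:
            u, hops = v, 0
            while u != last and hops <= 4:
                u = final_edge.get(u)
                hops += 1
                if u is None:
                    break
            if u != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - alphabet of 4, trail always found in practice
        return seq
    order: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(adj[v])
        if v != last:
            edges.remove(final_edge[v])
        rng.shuffle(edges)
        if v != last:
            edges.append(final_edge[v])
        order[v] = edges
    out = [seq[0]]
    pos = {v: 0 for v in vertices}
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = order[v][pos[v]]
        pos[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def generate_dataset(
    n_precursors: int, n_decoys: int, seed: int
) -> tuple[list[Transcript], DatasetTruth]:
    """Generate a shuffled synthetic transcriptome plus its truth table.

    Precursors cycle through the five family templates. Decoys alternate
    between uniform-random transcripts matched in length and GC to a
    precursor transcript, and dinucleotide-shuffled copies of precursor
    transcripts. All transcripts receive neutral ids (``contig_NNNN``) in a
    seed-determined shuffled order.
    """
    if n_precursors < 0 or n_decoys < 0:
        raise ValidationError("counts must be >= 0")
    rng = random.Random(seed)
    templates = family_templates()
    entries: list[tuple[Transcript, TruthRow]] = []
    precursor_seqs: list[str] = []
    for i in range(n_precursors):
        spec = templates[i % len(templates)]
        protein, peptides = build_precursor_protein(spec, rng.randrange(2**31))
        tx = back_translate_and_embed(protein, spec, rng.randrange(2**31))
        cds_start = spec.utr5_len
        truth = TruthRow(
            transcript_id="",
            is_precursor=True,
            family=spec.family,
            template=spec.name,
            signal_length=spec.signal_length,
            cds_span=(cds_start, cds_start + 3 * len(protein) + 3),
            protein=protein,
            peptides=tuple(p.sequence for p in peptides),
        )
        entries.append((tx, truth))
        precursor_seqs.append(tx.sequence)
    for j in range(n_decoys):
        if precursor_seqs and j % 2 == 1:
            src = precursor_seqs[(j // 2) % len(precursor_seqs)]
            seq = dinucleotide_shuffle(src, rng)
        else:
            if precursor_seqs:
                src = precursor_seqs[(j // 2) % len(precursor_seqs)]
                n, gc = len(src), _gc_fraction(src)
            else:
                n, gc = 300, 0.5
            seq = _random_nt(rng, n, gc)
        entries.append(
            (Transcript(id="tmp", sequence=seq), TruthRow("", is_precursor=False))
        )
    rng.shuffle(entries)
    transcripts: list[Transcript] = []
    truth_rows: list[TruthRow] = []
    for k, (tx, row) in enumerate(entries):
        tid = f"contig_{k + 1:04d}"
        transcripts.append(Transcript(id=tid, sequence=tx.sequence))
        truth_rows.append(
            TruthRow(
                transcript_id=tid,
                is_precursor=row.is_precursor,
                family=row.family,
                template=row.template,
                signal_length=row.signal_length,
                cds_span=row.cds_span,
                protein=row.protein,
                peptides=row.peptides,
            )
        )
    return transcripts, DatasetTruth(rows=truth_rows)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Recovery of embedded precursors by the pipeline."""

    candidate_recall: float
    candidate_precision: float
    signal_exact_rate: float
    peptide_set_exact_rate: float
    n_true: int
    n_detected: int
    n_false: int

    def as_dict(self) -> dict:
        return {
            "candidate_recall": self.candidate_recall,
            "candidate_precision": self.candidate_precision,
            "signal_exact_rate": self.signal_exact_rate,
            "peptide_set_exact_rate": self.peptide_set_exact_rate,
            "n_true": self.n_true,
            "n_detected": self.n_detected,
            "n_false": self.n_false,
        }


def evaluate_recovery(report, truth: DatasetTruth) -> RecoveryMetrics:
    """Score a pipeline report against the dataset truth.

    Candidate recall/precision are transcript-level. The signal-boundary and
    peptide-set exact-match rates are computed over the *detected* true
    precursors (they are 0.0 when nothing was detected). Precision is 1.0
    for an empty report (no false positives).
    """
    truth_ids = {r.transcript_id for r in truth.rows}
    report_ids = [row.transcript_id for row in report.rows]
    unknown = set(report_ids) - truth_ids
    if unknown:
        raise ValidationError(f"report contains unknown transcript ids {sorted(unknown)}")
    true_ids = truth.precursor_ids()
    detected = [row for row in report.rows if row.transcript_id in true_ids]
    n_true, n_det = len(true_ids), len(detected)
    n_false = len(report_ids) - n_det
    by_id = truth.by_id()
    sig_ok = sum(
        1
        for row in detected
        if row.signal_cleavage_after == by_id[row.transcript_id].signal_length
    )
    pep_ok = sum(
        1
        for row in detected
        if {p.sequence for p in row.peptides}
        == set(by_id[row.transcript_id].peptides)
    )
    return RecoveryMetrics(
        candidate_recall=n_det / n_true if n_true else 1.0,
        candidate_precision=n_det / len(report_ids) if report_ids else 1.0,
        signal_exact_rate=sig_ok / n_det if n_det else 0.0,
        peptide_set_exact_rate=pep_ok / n_det if n_det else 0.0,
        n_true=n_true,
        n_detected=n_det,
        n_false=n_false,
    )
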