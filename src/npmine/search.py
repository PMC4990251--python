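"""Six-frame translated homology search with E-value candidate selection.

This is a desk-scale, exact reimplementation of a tblastn-style screen:
every transcript is translated in all six frames, each frame is split at
stop codons into segments, and every query peptide is aligned against every
segment with an optimal affine-gap Smith–Waterman. Raw scores are turned
into E-values with the Karlin–Altschul closed form

    E = K * m * n * exp(-lambda * S)

using configurable ``lambda``/``K`` constants (defaults are the standard
gapped BLOSUM62 values). The statistics are a plumbing device for ranking:
no claim is made that they reproduce NCBI BLAST's internal edge-corrected
estimates, which depend on database composition. Per query, the lowest-E
hits below the E-value ceiling (default 0.01, keeping at most three) become
precursor candidates.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from npmine.errors import ValidationError
from npmine.io import NUCLEOTIDE_ALPHABET

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class Transcript:
    """A nucleotide contig (A, C, G, T, N; uppercase)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValidationError(f"{self.id}: illegal nucleotides {sorted(bad)}")
        if not seq:
            raise ValidationError(f"{self.id}: empty sequence")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SearchParams:
    """Scoring and selection parameters for the translated search."""

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0  # gap existence cost; a length-L gap costs open + L*extend
    gap_extend: float = 1.0
    lambda_param: float = 0.267
    k_param: float = 0.041
    evalue_max: float = 0.01
    max_hits_per_query: int = 3
    min_alignment_length: int = 8

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be > 0")
        if self.max_hits_per_query < 1:
            raise ValidationError("max_hits_per_query must be >= 1")
        if self.lambda_param <= 0 or self.k_param <= 0:
            raise ValidationError("lambda_param and k_param must be > 0")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("gap costs must be positive")


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal local alignment between two peptides (0-based half-open spans)."""

    raw_score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    aligned_query: str
    aligned_target: str

    @property
    def length(self) -> int:
        return len(self.aligned_query)


@dataclass(frozen=True)
class AlignmentHit:
    """A scored hit of one query peptide in one translated frame.

    Spans are 0-based half-open; ``target_span`` is in residue coordinates
    of the translated frame (not the nucleotide sequence).
    """

    query_id: str
    transcript_id: str
    frame: int
    raw_score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    aligned_query: str
    aligned_target: str


# --- translation -----------------------------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
_CODON_MAP.update({c: "*" for c in _STANDARD_TABLE.stop_codons})


def translate_frame(nt: str, frame: int) -> str:
    """Translate one frame (+1..+3 forward, -1..-3 on the reverse
    complement); codons containing N become ``X``; stops become ``*``;
    trailing partial codons are dropped."""
    if frame < 0:
        nt = str(Seq(nt).reverse_complement())
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append("X" if "N" in codon else _CODON_MAP[codon])
    return "".join(out)


def six_frame_translate(t: Transcript) -> dict[int, str]:
    """All six translated frames keyed by frame number."""
    return {frame: translate_frame(t.sequence, frame) for frame in FRAMES}


# --- scoring ---------------------------------------------------------------


@functools.lru_cache(maxsize=4)
def _matrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    sub = substitution_matrices.load(name)
    alphabet = str(sub.alphabet)
    index = {aa: i for i, aa in enumerate(alphabet)}
    return np.asarray(sub, dtype=np.float64), index


def _encode(pep: str, index: dict[str, int], name: str) -> np.ndarray:
    try:
        return np.fromiter((index[a] for a in pep), dtype=np.intp, count=len(pep))
    except KeyError as err:
        raise ValidationError(f"residue {err} not in matrix {name}") from None


def local_align(query_pep: str, target_pep: str, params: SearchParams) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment with affine gaps.

    The dynamic program is evaluated exactly (no heuristic seeding) over
    anti-diagonal wavefronts. Traceback is deterministic: the start cell is
    the first maximum in row-major order, and at each step the preference is
    diagonal, then up (gap in target), then left (gap in query).
    """
    if not query_pep or not target_pep:
        raise ValidationError("local_align requires non-empty peptides")
    sub, index = _matrix(params.substitution_matrix)
    q = _encode(query_pep.upper(), index, params.substitution_matrix)
    t = _encode(target_pep.upper(), index, params.substitution_matrix)
    m, n = len(q), len(t)
    S = sub[q[:, None], t[None, :]]

    go = params.gap_open + params.gap_extend  # cost of a length-1 gap
    ge = params.gap_extend
    NEG = -1e30
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # alignment ends with gap in target (up)
    F = np.full((m + 1, n + 1), NEG)  # alignment ends with gap in query (left)

    for d in range(2, m + n + 1):
        i0, i1 = max(1, d - n), min(m, d - 1)
        if i0 > i1:
            continue
        ii = np.arange(i0, i1 + 1)
        jj = d - ii
        E[ii, jj] = np.maximum(H[ii - 1, jj] - go, E[ii - 1, jj] - ge)
        F[ii, jj] = np.maximum(H[ii, jj - 1] - go, F[ii, jj - 1] - ge)
        diag = H[ii - 1, jj - 1] + S[ii - 1, jj - 1]
        H[ii, jj] = np.maximum(0.0, np.maximum(diag, np.maximum(E[ii, jj], F[ii, jj])))

    best = float(H.max())
    if best <= 0.0:
        return LocalAlignment(0.0, (0, 0), (0, 0), "", "")
    flat = int(np.argmax(H))  # row-major: first max has smallest i, then j
    i, j = divmod(flat, n + 1)
    end_q, end_t = i, j

    aq: list[str] = []
    at: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            if H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                aq.append(query_pep[i - 1])
                at.append(target_pep[j - 1])
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # up: query residue against a gap
            aq.append(query_pep[i - 1])
            at.append("-")
            closes = E[i, j] == H[i - 1, j] - go
            i -= 1
            if closes:
                state = "H"
        else:  # "F" — left: gap in query
            aq.append("-")
            at.append(target_pep[j - 1])
            closes = F[i, j] == H[i, j - 1] - go
            j -= 1
            if closes:
                state = "H"
    if state == "H" and (i == 0 or j == 0):
        pass  # ran into the matrix edge exactly at the local start
    return LocalAlignment(
        raw_score=best,
        query_span=(i, end_q),
        target_span=(j, end_t),
        aligned_query="".join(reversed(aq)),
        aligned_target="".join(reversed(at)),
    )


def estimate_evalue(
    raw_score: float, query_len: int, database_len: int, params: SearchParams
) -> tuple[float, float]:
    """Karlin–Altschul E-value and bit score for a raw alignment score.

    Returns ``(evalue, bit_score)`` with ``E = K·m·n·exp(-λ·S)`` and
    ``bits = (λ·S − ln K) / ln 2``.
    """
    if query_len < 1 or database_len < 1:
        raise ValidationError("sequence lengths must be >= 1")
    lam, k = params.lambda_param, params.k_param
    evalue = k * query_len * database_len * math.exp(-lam * raw_score)
    bit_score = (lam * raw_score - math.log(k)) / math.log(2)
    return evalue, bit_score


# --- search ----------------------------------------------------------------


def _frame_segments(frame_pep: str, min_len: int) -> list[tuple[int, str]]:
    """Split a translated frame at stop codons; return (offset, segment)
    pairs for segments long enough to ever meet ``min_alignment_length``."""
    segments = []
    start = 0
    for part in frame_pep.split("*"):
        if len(part) >= min_len:
            segments.append((start, part))
        start += len(part) + 1
    return segments


def _hit_sort_key(hit: AlignmentHit):
    return (hit.evalue, -hit.raw_score, hit.transcript_id)


def run_search(
    transcripts: list[Transcript], qs, params: SearchParams | None = None
) -> list[AlignmentHit]:
    """Align every query against every transcript frame; score and rank.

    Frames are split at stop codons before alignment, so no hit crosses a
    stop. For each (query, transcript, frame) the best-scoring segment
    alignment is kept when it reaches ``min_alignment_length`` columns.
    Hits are returned grouped by query in input-query order, each group
    sorted by ascending E-value (ties: descending raw score, then
    transcript id).
    """
    params = params or SearchParams()
    if not transcripts:
        raise ValidationError("run_search requires at least one transcript")
    records = list(qs)
    if not records:
        raise ValidationError("run_search requires a non-empty query set")

    frames = {t.id: six_frame_translate(t) for t in transcripts}
    database_len = sum(
        len(pep) for per_t in frames.values() for pep in per_t.values()
    )
    hits: list[AlignmentHit] = []
    by_query: dict[str, list[AlignmentHit]] = {r.accession: [] for r in records}
    for rec in records:
        for t in transcripts:
            for frame in FRAMES:
                best: LocalAlignment | None = None
                best_off = 0
                for off, segment in _frame_segments(
                    frames[t.id][frame], params.min_alignment_length
                ):
                    aln = local_align(rec.sequence, segment, params)
                    if best is None or aln.raw_score > best.raw_score:
                        best, best_off = aln, off
                if (
                    best is None
                    or best.raw_score <= 0
                    or best.length < params.min_alignment_length
                ):
                    continue
                evalue, bits = estimate_evalue(
                    best.raw_score, len(rec.sequence), database_len, params
                )
                by_query[rec.accession].append(
                    AlignmentHit(
                        query_id=rec.accession,
                        transcript_id=t.id,
                        frame=frame,
                        raw_score=best.raw_score,
                        bit_score=bits,
                        evalue=evalue,
                        query_span=best.query_span,
                        target_span=(
                            best_off + best.target_span[0],
                            best_off + best.target_span[1],
                        ),
                        aligned_query=best.aligned_query,
                        aligned_target=best.aligned_target,
                    )
                )
    for rec in records:
        hits.extend(sorted(by_query[rec.accession], key=_hit_sort_key))
    return hits


@dataclass
class CandidateSet:
    """Per-query selected hits plus the merged candidate transcript list.

    ``transcripts`` maps each candidate transcript id to its best
    (lowest-E) supporting hit across all queries.
    """

    per_query: dict[str, list[AlignmentHit]] = field(default_factory=dict)
    transcripts: dict[str, AlignmentHit] = field(default_factory=dict)


def select_candidates(
    hits: list[AlignmentHit], params: SearchParams | None = None
) -> CandidateSet:
    """Keep, per query, the lowest-E hits below ``evalue_max`` (at most
    ``max_hits_per_query``); merge hit transcripts into a deduplicated
    candidate list carrying the best evidence for each."""
    params = params or SearchParams()
    grouped: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    selected = CandidateSet()
    for query_id, group in grouped.items():
        group = sorted(group, key=_hit_sort_key)
        kept = [h for h in group if h.evalue < params.evalue_max][
            : params.max_hits_per_query
        ]
        if kept:
            selected.per_query[query_id] = kept
        for hit in kept:
            prev = selected.transcripts.get(hit.transcript_id)
            if prev is None or _hit_sort_key(hit) < _hit_sort_key(prev):
                selected.transcripts[hit.transcript_id] = hit
    return selected
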