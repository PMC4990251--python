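"""Translated search: frames, optimal local alignment, E-values, selection.

The Smith–Waterman implementation is validated two independent ways: a
memoized recursive oracle over all local-alignment paths, and Biopython's
PairwiseAligner configured with the same scoring.
"""

import random
from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from npmine.errors import ValidationError
from npmine.querydb import AnnotationRecord, QuerySet
from npmine.search import (
    AlignmentHit,
    SearchParams,
    Transcript,
    estimate_evalue,
    local_align,
    run_search,
    select_candidates,
    six_frame_translate,
    translate_frame,
)

PARAMS = SearchParams()
BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_score(q: str, t: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Independent oracle: best local alignment score by recursive
    enumeration over all alignment paths (a path starts and ends on a
    match/mismatch column; gaps cost open+extend for the first residue)."""
    first = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def from_here(i: int, j: int, state: str) -> float:
        best = 0.0  # stopping is always allowed (local alignment)
        if i < len(q) and j < len(t):
            best = max(
                best, BLOSUM62[q[i], t[j]] + from_here(i + 1, j + 1, "M")
            )
        if i < len(q):
            best = max(
                best,
                -(gap_extend if state == "U" else first) + from_here(i + 1, j, "U"),
            )
        if j < len(t):
            best = max(
                best,
                -(gap_extend if state == "L" else first) + from_here(i, j + 1, "L"),
            )
        return best

    best = 0.0
    for i in range(len(q)):
        for j in range(len(t)):
            best = max(best, BLOSUM62[q[i], t[j]] + from_here(i + 1, j + 1, "M"))
    return best


def biopython_score(q: str, t: str) -> float:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return float(aligner.score(q, t))


# --- translation -----------------------------------------------------------


@pytest.mark.parametrize(
    ("nt", "frame", "pep"),
    [
        ("ATGAAA", 1, "MK"),
        ("ATGTAA", 1, "M*"),
        ("AATGAAA", 2, "MK"),
        ("ATGNAA", 1, "MX"),  # N-containing codon is ambiguous
        ("ATGAA", 1, "M"),  # trailing partial codon dropped
    ],
)
def test_translate_frame_examples(nt, frame, pep):
    assert translate_frame(nt, frame) == pep


@given(st.text(alphabet="ACGT", min_size=3, max_size=60))
@settings(max_examples=50, deadline=None)
def test_reverse_frames_translate_the_reverse_complement(nt):
    rc = str(Seq(nt).reverse_complement())
    for k in (1, 2, 3):
        assert translate_frame(nt, -k) == translate_frame(rc, k)


def test_six_frame_translate_rejects_bad_letters():
    with pytest.raises(ValidationError):
        Transcript(id="t", sequence="ATGU")


# --- local alignment -------------------------------------------------------


def test_self_alignment_scores_sum_of_diagonal_entries():
    pep = "FDSIG"
    expected = sum(float(BLOSUM62[a, a]) for a in pep)
    aln = local_align(pep, pep, PARAMS)
    assert aln.raw_score == expected
    assert aln.aligned_query == pep and aln.aligned_target == pep
    assert aln.query_span == (0, 5) and aln.target_span == (0, 5)


def test_no_positive_pair_gives_empty_alignment():
    aln = local_align("MKWVFF", "PPP", PARAMS)
    assert aln.raw_score == 0.0
    assert aln.aligned_query == "" and aln.aligned_target == ""


def test_empty_input_rejected():
    with pytest.raises(ValidationError):
        local_align("", "MK", PARAMS)


def test_alignment_matches_brute_force_oracle_small_peptides():
    rng = random.Random(42)
    for _ in range(120):
        q = "".join(rng.choice(AA) for _ in range(rng.randint(1, 8)))
        t = "".join(rng.choice(AA) for _ in range(rng.randint(1, 8)))
        got = local_align(q, t, PARAMS).raw_score
        assert got == brute_force_score(q, t), (q, t)


def test_alignment_matches_biopython_on_longer_peptides():
    rng = random.Random(17)
    for _ in range(40):
        q = "".join(rng.choice(AA) for _ in range(rng.randint(5, 40)))
        t = "".join(rng.choice(AA) for _ in range(rng.randint(5, 60)))
        assert local_align(q, t, PARAMS).raw_score == biopython_score(q, t)


@given(
    st.text(alphabet=AA, min_size=1, max_size=12),
    st.text(alphabet=AA, min_size=1, max_size=12),
)
@settings(max_examples=60, deadline=None)
def test_score_is_symmetric(q, t):
    assert (
        local_align(q, t, PARAMS).raw_score == local_align(t, q, PARAMS).raw_score
    )


def rescore(aligned_q: str, aligned_t: str, params: SearchParams) -> float:
    """Re-score a pair of gapped strings under the matrix and gap costs."""
    total, in_gap = 0.0, False
    for a, b in zip(aligned_q, aligned_t):
        if a == "-" or b == "-":
            total -= params.gap_extend + (0 if in_gap else params.gap_open)
            in_gap = True
        else:
            total += float(BLOSUM62[a, b])
            in_gap = False
    return total


def test_stored_alignment_rescoring_equals_raw_score():
    rng = random.Random(3)
    for _ in range(60):
        q = "".join(rng.choice(AA) for _ in range(rng.randint(4, 25)))
        t = "".join(rng.choice(AA) for _ in range(rng.randint(4, 25)))
        aln = local_align(q, t, PARAMS)
        if aln.raw_score > 0:
            assert rescore(aln.aligned_query, aln.aligned_target, PARAMS) == (
                aln.raw_score
            )


# --- E-values --------------------------------------------------------------


def test_evalue_closed_form_and_monotonicity():
    e0, _ = estimate_evalue(0.0, 10, 1000, PARAMS)
    assert e0 == PARAMS.k_param * 10 * 1000
    e_double, _ = estimate_evalue(0.0, 10, 2000, PARAMS)
    assert e_double == pytest.approx(2 * e0)
    scores = [0, 10, 20, 40, 80]
    evals = [estimate_evalue(s, 10, 1000, PARAMS)[0] for s in scores]
    assert all(a > b for a, b in zip(evals, evals[1:]))
    with pytest.raises(ValidationError):
        estimate_evalue(10.0, 0, 1000, PARAMS)


# --- search and selection --------------------------------------------------


def _embed(pep: str, frame: int, pad5: str, pad3: str) -> str:
    codons = {  # one codon per residue, enough for the test peptides
        "M": "ATG", "K": "AAA", "W": "TGG", "V": "GTT", "F": "TTT",
        "D": "GAT", "S": "TCT", "I": "ATT", "G": "GGT", "N": "AAT",
        "P": "CCT", "L": "CTT", "E": "GAA", "R": "CGT", "Y": "TAT",
    }
    cds = "".join(codons[a] for a in pep)
    seq = pad5 + cds + pad3
    if frame < 0:
        seq = str(Seq(seq).reverse_complement())
    return seq


def test_embedded_query_is_top_hit_in_the_right_frame():
    query = AnnotationRecord("Q1", "test hormone", "SFDSIGNGPIGLKRSFDSIGNGPIGL")
    target = Transcript(id="hit", sequence=_embed(query.sequence, -2, "A", "GTACG"))
    decoy = Transcript(id="decoy", sequence="ACGT" * 30)
    hits = run_search([target, decoy], QuerySet(records=[query]), PARAMS)
    assert hits and hits[0].transcript_id == "hit"
    assert hits[0].frame == -2
    assert hits[0].aligned_target == query.sequence


def test_transcript_without_positive_hits_yields_nothing():
    query = AnnotationRecord("Q1", "test hormone", "WWWWWWWWWW")
    t = Transcript(id="t", sequence="CCGCCGCCGCCGCCGCCGCCGCCGCCGCCG")  # all Pro
    assert run_search([t], QuerySet(records=[query]), PARAMS) == []


def _hit(query, tid, evalue, raw=50.0):
    return AlignmentHit(
        query_id=query, transcript_id=tid, frame=1, raw_score=raw,
        bit_score=10.0, evalue=evalue, query_span=(0, 10),
        target_span=(0, 10), aligned_query="A" * 10, aligned_target="A" * 10,
    )


def test_select_candidates_rank_and_threshold():
    evalues = [1e-5, 1e-4, 5e-3, 8e-3, 2e-2]
    hits = [_hit("Q1", f"t{i}", e) for i, e in enumerate(evalues)]
    sel = select_candidates(hits, PARAMS)
    kept = [h.evalue for h in sel.per_query["Q1"]]
    assert kept == [1e-5, 1e-4, 5e-3]  # top three, 8e-3 by rank, 2e-2 by both
    sel_all_bad = select_candidates([_hit("Q1", "t", 0.5)], PARAMS)
    assert sel_all_bad.per_query == {}


def test_select_candidates_tie_break_by_score_then_id():
    hits = [
        _hit("Q1", "tB", 1e-4, raw=40.0),
        _hit("Q1", "tA", 1e-4, raw=40.0),
        _hit("Q1", "tC", 1e-4, raw=60.0),
    ]
    sel = select_candidates(hits, PARAMS)
    assert [h.transcript_id for h in sel.per_query["Q1"]] == ["tC", "tA", "tB"]


def test_candidate_monotonicity_in_evalue_threshold():
    hits = [_hit("Q1", f"t{i}", e) for i, e in enumerate([1e-6, 1e-4, 5e-3])]
    strict = select_candidates(hits, SearchParams(evalue_max=1e-3))
    loose = select_candidates(hits, SearchParams(evalue_max=1e-2))
    strict_ids = {h.transcript_id for h in strict.per_query.get("Q1", [])}
    loose_ids = {h.transcript_id for h in loose.per_query.get("Q1", [])}
    assert strict_ids <= loose_ids
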