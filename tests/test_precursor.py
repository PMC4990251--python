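"""ORF finding, signal-peptide heuristic and convertase-site detection."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from npmine.errors import ValidationError
from npmine.precursor import (
    CleavageRuleSet,
    find_cleavage_sites,
    find_orfs,
    predict_signal_peptide,
)
from npmine.search import Transcript


# --- ORFs ------------------------------------------------------------------


def test_minimal_orf():
    orfs = find_orfs(Transcript(id="t", sequence="ATGAAATAA"), min_aa=1)
    assert len(orfs) == 1
    orf = orfs[0]
    assert orf.protein == "MK" and orf.frame == 1 and orf.has_stop
    assert orf.nt_span == (0, 9)  # 3*len + 3: the stop codon is included


def test_no_start_codon_means_no_orf():
    assert find_orfs(Transcript(id="t", sequence="CCCCCCCCC"), min_aa=1) == []


def test_nested_orfs_share_a_stop():
    # M-A-M-K-* : two Mets before one stop
    nt = "ATGGCTATGAAATAA"
    t = Transcript(id="t", sequence=nt)
    default = find_orfs(t, min_aa=1)
    in_frame1 = [o for o in default if o.frame == 1]
    assert [o.protein for o in in_frame1] == ["MAMK"]  # longest only
    nested = [o for o in find_orfs(t, min_aa=1, include_nested=True) if o.frame == 1]
    assert sorted(o.protein for o in nested) == ["MAMK", "MK"]


@given(st.text(alphabet="ACGT", min_size=9, max_size=90))
@settings(max_examples=40, deadline=None)
def test_orfs_mirror_on_reverse_complement(nt):
    t = Transcript(id="t", sequence=nt)
    rc = Transcript(id="t", sequence=str(Seq(nt).reverse_complement()))
    fwd = {(o.protein, -o.frame, (len(nt) - o.nt_span[1], len(nt) - o.nt_span[0]))
           for o in find_orfs(t, min_aa=1)}
    rev = {(o.protein, o.frame, o.nt_span) for o in find_orfs(rc, min_aa=1)}
    assert fwd == rev


# --- signal peptide --------------------------------------------------------


def test_signal_cleavage_follows_hydrophobic_core_and_small_residues():
    protein = "M" + "L" * 12 + "ASA" + "Q" * 30
    sig = predict_signal_peptide(protein)
    assert sig.present and sig.cleavage_after == 16


def test_acidic_nterminus_has_no_signal():
    sig = predict_signal_peptide("M" + "DE" * 20)
    assert not sig.present


def test_short_protein_reports_reason_not_error():
    sig = predict_signal_peptide("MKWVFFALLF")
    assert not sig.present and "shorter" in sig.reason


def test_non_met_start_is_rejected():
    with pytest.raises(ValidationError):
        predict_signal_peptide("KWVFFALLF" * 5)


def test_scoring_ignores_residues_beyond_the_scan_region():
    base = "M" + "L" * 18 + "ALA" + "S" * 40
    mutated = base[:53] + "W" * (len(base) - 53)
    a, b = predict_signal_peptide(base), predict_signal_peptide(mutated)
    assert (a.cleavage_after, a.score) == (b.cleavage_after, b.score)


# --- cleavage sites --------------------------------------------------------


def test_tandem_repeat_precursor_has_one_site_per_kr():
    sites = find_cleavage_sites("SFDSIGNGPIGLKRSFDGIGNGPIGLKR")
    assert [(s.position, s.motif) for s in sites] == [(14, "KR"), (28, "KR")]
    assert all(s.cls == "dibasic" for s in sites)


def test_cys_knot_hormone_has_no_dibasic_sites(table2):
    ghb = table2["BnGHB5"][0].stripped_sequence
    assert find_cleavage_sites(ghb) == []


def test_multibasic_run_yields_a_single_site():
    sites = find_cleavage_sites("AAKKRAA")
    assert [(s.position, s.motif, s.cls) for s in sites] == [(5, "KKR", "multibasic")]


def test_monobasic_and_rk_are_opt_in():
    seq = "AAADRAAADAARKAAD"
    assert find_cleavage_sites(seq) == []
    mono = find_cleavage_sites(
        seq, CleavageRuleSet(allow_monobasic_R=True)
    )
    assert [s.motif for s in mono] == ["R"]
    rk = find_cleavage_sites(
        seq, CleavageRuleSet(accept_dibasic=frozenset({"KR", "RR", "KK", "RK"}))
    )
    assert [s.motif for s in rk] == ["RK"]


def test_short_segment_between_sites_is_suppressed():
    # KR then KK only two residues later: second site suppressed by default
    sites = find_cleavage_sites("AAAAKRAAKKAAAA")
    assert [s.motif for s in sites] == ["KR"]
    permissive = find_cleavage_sites(
        "AAAAKRAAKKAAAA", CleavageRuleSet(min_peptide_len=1)
    )
    assert [s.motif for s in permissive] == ["KR", "KK"]


@given(st.text(alphabet="AKRGS", min_size=1, max_size=40))
@settings(max_examples=80, deadline=None)
def test_monobasic_toggle_only_adds_sites(seq):
    # the rule-gate monotonicity is assessed with length suppression off,
    # which otherwise couples neighbouring sites
    base = CleavageRuleSet(min_peptide_len=0)
    mono = CleavageRuleSet(min_peptide_len=0, allow_monobasic_R=True)
    without = {(s.position, s.motif) for s in find_cleavage_sites(seq, base)}
    with_mono = {(s.position, s.motif) for s in find_cleavage_sites(seq, mono)}
    assert without <= with_mono


@given(st.text(alphabet="ACDEFGKRLS", min_size=1, max_size=60))
@settings(max_examples=80, deadline=None)
def test_site_motifs_are_maximal_basic_runs(seq):
    for site in find_cleavage_sites(seq):
        start = site.position - len(site.motif)
        assert seq[start : site.position] == site.motif
        assert site.position == len(seq) or seq[site.position] not in "KR"
        assert start == 0 or seq[start - 1] not in "KR"
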