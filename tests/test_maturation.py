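"""Peptide excision, terminal PTMs, sulfation, disulfides, B-C-A layout."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npmine.errors import InternalConsistencyError
from npmine.fixtures import sulfation_marked_positions
from npmine.maturation import (
    apply_terminal_ptms,
    detect_insulin_architecture,
    excise_peptides,
    predict_disulfides,
    predict_tyr_sulfation,
    process_precursor_protein,
    trim_basic_flank,
)
from npmine.precursor import (
    CleavageRuleSet,
    CleavageSite,
    SignalPrediction,
    find_cleavage_sites,
)


def _signal(n):
    return SignalPrediction(present=n > 0, cleavage_after=n, score=0.0)


# --- excision --------------------------------------------------------------


def test_tandem_unit_yields_twelve_residue_peptide(table2):
    printed = table2["BnFDSIG-like"][0].stripped_sequence  # unit with KR flank
    pep, flank = trim_basic_flank(printed)
    assert pep == "SFDSIGNGPIGL" and len(pep) == 12 and flank == "KR"


def test_npf_peptide_is_35_residues_after_trimming(table2):
    stripped = table2["BnNPFL"][0].stripped_sequence
    pep, flank = trim_basic_flank(stripped)
    assert len(pep) == 35 and flank == "KR"


def test_excision_reconstructs_the_precursor():
    protein = "M" + "L" * 20 + "ALA" + "SFDSIGNGPIGLKR" * 3 + "QHLKGSGENSLP"
    signal = _signal(24)
    sites = find_cleavage_sites(protein[24:])
    segments = excise_peptides(protein, signal, sites)
    rebuilt = protein[:24] + "".join(s.peptide + s.flank for s in segments)
    assert rebuilt == protein
    kept = [s.peptide for s in segments if s.kept]
    assert kept == ["SFDSIGNGPIGL"] * 3 + ["QHLKGSGENSLP"]
    for seg in segments:
        assert protein[seg.span[0] : seg.span[1]] == seg.peptide


def test_overlapping_sites_are_an_internal_error():
    sites = [CleavageSite(5, "KR", "dibasic"), CleavageSite(4, "KK", "dibasic")]
    with pytest.raises(InternalConsistencyError):
        excise_peptides("A" * 30, _signal(0), sites)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_reconstruction_holds_for_generated_precursors(seed):
    from npmine.synthdata import build_precursor_protein, family_templates

    spec = family_templates()[seed % 5]
    protein, _ = build_precursor_protein(spec, seed)
    sites = find_cleavage_sites(protein[spec.signal_length :])
    segments = excise_peptides(protein, _signal(spec.signal_length), sites)
    assert protein[: spec.signal_length] + "".join(
        s.peptide + s.flank for s in segments
    ) == protein


# --- terminal PTMs ---------------------------------------------------------


@pytest.mark.parametrize(
    ("segment", "flank", "sequence", "amidated", "pyroglu"),
    [
        ("YLERIGSGNELVG", "KR", "YLERIGSGNELV", True, False),
        ("QHLKGSGENSLP", "", "QHLKGSGENSLP", False, True),
        ("SFDSIGNGPIGL", "KR", "SFDSIGNGPIGL", False, False),
        ("EPSGFLSQ", "KR", "EPSGFLSQ", False, False),  # E needs opting in
    ],
)
def test_terminal_ptm_calls(segment, flank, sequence, amidated, pyroglu):
    pep = apply_terminal_ptms(segment, flank)
    assert (pep.sequence, pep.amidated, pep.pyroglutamate) == (
        sequence,
        amidated,
        pyroglu,
    )


def test_pyroglutamate_from_glu_is_a_switch():
    from npmine.maturation import PTMOptions

    pep = apply_terminal_ptms(
        "EPSGFLSQ", "KR", PTMOptions(pyroglutamate_from_E=True)
    )
    assert pep.pyroglutamate


def test_amidation_requires_an_exposed_flank():
    # terminal segment of a precursor: no flank was removed, Gly stays
    pep = apply_terminal_ptms("YLERIGSGNELVG", "")
    assert not pep.amidated and pep.sequence.endswith("G")


def test_amidated_peptides_never_end_in_gly_or_basic(benchmark):
    _tx, _truth, report = benchmark
    peptides = [p for row in report.rows for p in row.peptides]
    assert peptides
    for p in peptides:
        assert not p.sequence.endswith(("K", "R")) or p.amidated
        if p.amidated:
            assert not p.sequence.endswith("G")
            assert p.pre_amidation.endswith("G") and p.flank_removed


# --- sulfation -------------------------------------------------------------


def test_sulfation_rule_reproduces_printed_marks(table2):
    row = table2["BnNPFL"][0]
    marked = sulfation_marked_positions(row.printed_sequence)
    assert marked == [25, 28]
    assert predict_tyr_sulfation(row.stripped_sequence) == marked


@pytest.mark.parametrize(
    ("peptide", "positions"),
    [
        ("EYE", [2]),
        ("GGGYGGG", []),
        ("YDAAAAY", [1]),
        ("AAAA", []),
    ],
)
def test_sulfation_examples(peptide, positions):
    assert predict_tyr_sulfation(peptide) == positions


# --- disulfides and insulin layout -----------------------------------------


def test_insulin_chains_carry_four_bridges(table2):
    chains = [r.stripped_sequence for r in table2["BnILP-A"]]
    pred = predict_disulfides(chains)
    assert pred.bridge_count == 4 and pred.unpaired is None


def test_vasopressin_ring_pairs_cys_1_and_6(table2):
    pep, flank = trim_basic_flank(table2["BnVP-like"][0].stripped_sequence)
    pred = predict_disulfides([pep])
    assert pred.bridge_count == 1
    assert pred.pairing == (((0, 1), (0, 6)),)


def test_no_cysteines_no_bridges():
    pred = predict_disulfides(["AAAA", "GGGG"])
    assert pred.bridge_count == 0 and pred.pairing == ()


def test_bridge_count_is_chain_order_invariant(table2):
    chains = [r.stripped_sequence for r in table2["BnILP-A"]]
    counts = {
        predict_disulfides(list(order)).bridge_count
        for order in ((chains[0], chains[1], chains[2]),
                      (chains[2], chains[0], chains[1]),
                      (chains[1], chains[2], chains[0]))
    }
    assert counts == {4}


def test_insulin_architecture_detection(table2):
    chains = [
        trim_basic_flank(r.stripped_sequence)[0] for r in table2["BnILP-A"]
    ]
    arch = detect_insulin_architecture(chains)
    assert arch is not None
    assert arch.c_chain.count("C") == 0
    assert arch.disulfide_count == 4
    assert detect_insulin_architecture(["CACA", "AAA", "AAAA"]) is None  # no CC
    assert detect_insulin_architecture(chains[:2]) is None  # needs 3 chains


def test_process_precursor_protein_matches_manual_stages():
    protein = "M" + "I" * 19 + "ALA" + "CYIRTCDLGILGKR" + "QHLKGSGENSLP"
    sites, peptides = process_precursor_protein(protein, 23)
    assert [s.motif for s in sites] == ["KR"]
    assert [p.sequence for p in peptides] == ["CYIRTCDLGIL", "QHLKGSGENSLP"]
    assert peptides[0].amidated and peptides[1].pyroglutamate
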