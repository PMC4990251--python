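"""Peptide-family assignment by motif and architecture rules.

Five secreted-peptide families are recognized, in decreasing order of rule
specificity:

``insulin_like``
    three excised chains in B-C-A order, with the disulfide-forming Cys
    pattern (A chain with a CC doublet) — the connecting C chain is
    Cys-poor. Precursors whose B chain is fragmentary are still called
    insulin-like from the A/C chain layout, at reduced confidence.
``vasopressin``
    a short peptide (9–16 residues) with the canonical Cys1–Cys6 ring.
``GPB5``
    a glycoprotein-hormone beta-subunit: one long Cys-rich mature region
    (80–130 residues, ≥9 Cys) processed without any convertase site.
``pedal_orcokinin_FDSIG``
    pedal-peptide/orcokinin-type units of 10–16 residues sharing the IGxG
    core motif.
``NPF``
    neuropeptide F / NPY-type: an amidated C-terminal RxR(F/Y), or — for
    divergent members in which that motif degenerated — a 30–40 residue
    peptide carrying at least two sulfation-eligible tyrosines.

Anything matching no rule is returned as ``unclassified`` (never a guessed
family). Rules are data: profiles can be loaded from a YAML file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from npmine.errors import ConfigurationError, ValidationError
from npmine.maturation import MaturePeptide, detect_insulin_architecture

UNCLASSIFIED = "unclassified"

CONFIDENCE_MOTIF_ARCH = "motif+architecture"
CONFIDENCE_MOTIF = "motif-only"
CONFIDENCE_POSITIONAL = "positional-only"


@dataclass(frozen=True)
class FamilyProfile:
    """One family's rule parameters; ``positional_rules`` are structured
    predicates (length ranges, Cys counts/positions, architecture flags)."""

    name: str
    motif_patterns: tuple[str, ...] = ()
    positional_rules: dict = field(default_factory=dict)


DEFAULT_PROFILES: tuple[FamilyProfile, ...] = (
    FamilyProfile(
        "insulin_like",
        positional_rules={"allow_partial_b_chain": True},
    ),
    FamilyProfile(
        "vasopressin",
        positional_rules={"cys_positions": (1, 6), "length_range": (9, 16)},
    ),
    FamilyProfile(
        "GPB5",
        positional_rules={"length_range": (80, 130), "min_cys": 9},
    ),
    FamilyProfile(
        "pedal_orcokinin_FDSIG",
        motif_patterns=("IG.G",),
        positional_rules={"length_range": (10, 16)},
    ),
    FamilyProfile(
        "NPF",
        motif_patterns=(r"R.R[FY]$",),
        positional_rules={
            "fallback_length_range": (30, 40),
            "fallback_min_sulfated_tyr": 2,
        },
    ),
)


@dataclass(frozen=True)
class FamilyCall:
    """Classification outcome for one precursor (or bare peptide set)."""

    subject_id: str
    family: str
    evidence: tuple[str, ...] = ()
    confidence: str = ""


@dataclass
class PrecursorPeptides:
    """The processed peptide set of one precursor, plus the number of
    internal convertase sites found on it (needed by the GPB5 rule)."""

    subject_id: str
    peptides: list[MaturePeptide]
    n_cleavage_sites: int = 0


def count_cysteines(sequence: str) -> int:
    """Number of Cys residues in a sequence."""
    if not sequence:
        raise ValidationError("empty sequence")
    return sequence.count("C")


def load_profiles(path: str | Path) -> tuple[FamilyProfile, ...]:
    """Load family profiles from YAML: a list of mappings with keys
    ``name``, optional ``motif_patterns`` and ``positional_rules``."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise ConfigurationError(f"{path}: expected a list of family profiles")
    profiles = []
    for entry in data:
        profiles.append(
            FamilyProfile(
                name=entry["name"],
                motif_patterns=tuple(entry.get("motif_patterns", ())),
                positional_rules=dict(entry.get("positional_rules", {})),
            )
        )
    return tuple(profiles)


def _ordered_sequences(pp: PrecursorPeptides) -> list[MaturePeptide]:
    return sorted(pp.peptides, key=lambda p: p.source_span)


def _eval_insulin(pp: PrecursorPeptides, profile: FamilyProfile):
    chains = [p.sequence for p in _ordered_sequences(pp)]
    arch = detect_insulin_architecture(chains) if len(chains) == 3 else None
    if arch is not None:
        return (
            [f"b_c_a_architecture", f"disulfide_count={arch.disulfide_count}"],
            CONFIDENCE_MOTIF_ARCH,
        )
    if profile.positional_rules.get("allow_partial_b_chain") and len(chains) == 3:
        b, c, a = chains
        if "CC" in a and a.count("C") >= 3 and c.count("C") <= 1:
            return (
                ["a_chain_cc_doublet", "c_chain_cys_poor", "partial_b_chain"],
                CONFIDENCE_POSITIONAL,
            )
    return None


def _eval_vasopressin(pp: PrecursorPeptides, profile: FamilyProfile):
    pos = profile.positional_rules.get("cys_positions", (1, 6))
    lo, hi = profile.positional_rules.get("length_range", (9, 16))
    for pep in pp.peptides:
        seq = pep.pre_amidation
        if not lo <= len(seq) <= hi:
            continue
        if all(p <= len(seq) and seq[p - 1] == "C" for p in pos):
            return (
                [f"cys_at_{'_'.join(map(str, pos))}", f"length_{len(seq)}"],
                CONFIDENCE_POSITIONAL,
            )
    return None


def _eval_gpb5(pp: PrecursorPeptides, profile: FamilyProfile):
    lo, hi = profile.positional_rules.get("length_range", (80, 130))
    min_cys = profile.positional_rules.get("min_cys", 9)
    if len(pp.peptides) != 1 or pp.n_cleavage_sites != 0:
        return None
    seq = pp.peptides[0].pre_amidation
    n_cys = count_cysteines(seq) if seq else 0
    if lo <= len(seq) <= hi and n_cys >= min_cys:
        return (
            ["single_uncleaved_mature_region", f"length_{len(seq)}", f"cys_{n_cys}"],
            CONFIDENCE_POSITIONAL,
        )
    return None


def _eval_pedal(pp: PrecursorPeptides, profile: FamilyProfile):
    patterns = profile.motif_patterns or ("IG.G",)
    lo, hi = profile.positional_rules.get("length_range", (10, 16))
    for pep in pp.peptides:
        seq = pep.pre_amidation
        if lo <= len(seq) <= hi and any(re.search(p, seq) for p in patterns):
            return ([f"motif_IGxG", f"length_{len(seq)}"], CONFIDENCE_MOTIF)
    return None


def _eval_npf(pp: PrecursorPeptides, profile: FamilyProfile):
    patterns = profile.motif_patterns or (r"R.R[FY]$",)
    lo, hi = profile.positional_rules.get("fallback_length_range", (30, 40))
    min_sulf = profile.positional_rules.get("fallback_min_sulfated_tyr", 2)
    for pep in pp.peptides:
        if pep.amidated and any(re.search(p, pep.sequence) for p in patterns):
            return (["cterm_RxRF_amide"], CONFIDENCE_MOTIF)
    for pep in pp.peptides:
        n_sulf = len(pep.sulfated_tyr)
        if lo <= pep.trimmed_length <= hi and n_sulf >= min_sulf:
            return (
                [
                    "motif_match=false",
                    f"length_{pep.trimmed_length}",
                    f"sulfated_tyr_{n_sulf}",
                ],
                CONFIDENCE_POSITIONAL,
            )
    return None


_EVALUATORS = {
    "insulin_like": _eval_insulin,
    "vasopressin": _eval_vasopressin,
    "GPB5": _eval_gpb5,
    "pedal_orcokinin_FDSIG": _eval_pedal,
    "NPF": _eval_npf,
}


def classify_family(
    precursors: list[PrecursorPeptides],
    profiles: tuple[FamilyProfile, ...] | None = None,
) -> list[FamilyCall]:
    """Assign each precursor's peptide set to a family.

    Profiles are evaluated in order (default: insulin → vasopressin → GPB5 →
    pedal/orcokinin → NPF); the first match wins and its satisfied rules are
    recorded as evidence. Peptide order within a precursor is normalised by
    source span, so classification is invariant to input shuffles.
    """
    profiles = profiles or DEFAULT_PROFILES
    calls = []
    for pp in precursors:
        call = FamilyCall(subject_id=pp.subject_id, family=UNCLASSIFIED)
        for profile in profiles:
            evaluator = _EVALUATORS.get(profile.name)
            if evaluator is None:
                raise ConfigurationError(f"no evaluator for family {profile.name!r}")
            result = evaluator(pp, profile)
            if result is not None:
                evidence, confidence = result
                call = FamilyCall(
                    subject_id=pp.subject_id,
                    family=profile.name,
                    evidence=tuple(evidence),
                    confidence=confidence,
                )
                break
        calls.append(call)
    return calls
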