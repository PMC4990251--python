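"""Mature-peptide derivation and post-translational-modification calls.

Processing model: the signal peptide is removed, the propeptide is cut
C-terminal to each convertase site, carboxypeptidase-like trimming removes
the exposed basic flank, a C-terminal Gly exposed by trimming is converted
to an amide, an N-terminal Gln (optionally Glu) is flagged as cyclizing to
pyroglutamate, and Tyr residues in acidic context are flagged as sulfated.
Disulfide bridges are counted as ``floor(total Cys / 2)``; the nested
first-with-last pairing reported alongside is a low-confidence heuristic.

All sulfation/disulfide calls here are transparent local rules intended to
mirror how such features are read off a precursor by eye; they are not
re-implementations of external predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from npmine.errors import InternalConsistencyError, ValidationError
from npmine.precursor import CleavageRuleSet, CleavageSite, SignalPrediction

logger = logging.getLogger(__name__)

_BASIC = frozenset("KR")


@dataclass(frozen=True)
class PTMOptions:
    """Switches for terminal modifications."""

    amidation: bool = True
    pyroglutamate_from_Q: bool = True
    pyroglutamate_from_E: bool = False


@dataclass(frozen=True)
class RawSegment:
    """A peptide segment excised from a precursor, basic flank removed.

    ``span`` is the 0-based half-open location of the trimmed peptide in the
    full precursor protein. Segments that fall below the minimum peptide
    length keep ``kept=False`` so that precursor reconstruction stays exact.
    """

    peptide: str
    flank: str
    span: tuple[int, int]
    kept: bool = True


@dataclass(frozen=True)
class MaturePeptide:
    """A processed peptide with its PTM flags.

    ``pre_amidation`` is the basic-trimmed segment before the amide Gly is
    removed; peptide lengths are conventionally reported on that form, so
    both are kept. ``sulfated_tyr`` positions are 1-based on
    ``pre_amidation``.
    """

    sequence: str
    pre_amidation: str
    source_span: tuple[int, int]
    flank_removed: str
    amidated: bool = False
    pyroglutamate: bool = False
    sulfated_tyr: tuple[int, ...] = ()

    @property
    def trimmed_length(self) -> int:
        return len(self.pre_amidation)


@dataclass(frozen=True)
class DisulfidePrediction:
    """Bridge count plus heuristic nested pairing of Cys positions.

    Each Cys is identified as ``(chain_index, 1-based position)``. Only the
    count is treated as reliable; the pairing is reported as heuristic
    evidence.
    """

    bridge_count: int
    pairing: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()
    unpaired: tuple[int, int] | None = None


@dataclass(frozen=True)
class InsulinArchitecture:
    """B-C-A chain organisation of an insulin-like precursor."""

    b_chain: str
    c_chain: str
    a_chain: str
    disulfide_count: int


def trim_basic_flank(segment: str) -> tuple[str, str]:
    """Split off the trailing run of K/R residues: ``(peptide, flank)``."""
    i = len(segment)
    while i > 0 and segment[i - 1] in _BASIC:
        i -= 1
    return segment[:i], segment[i:]


def excise_peptides(
    protein: str,
    signal: SignalPrediction,
    sites: list[CleavageSite],
    rules: CleavageRuleSet | None = None,
) -> list[RawSegment]:
    """Cut the mature region at the convertase sites and trim basic flanks.

    Site positions are relative to the mature region (the protein after the
    signal peptide). The returned list covers the mature region completely:
    ``signal + Σ(peptide + flank)`` reconstructs the precursor exactly, with
    sub-minimum-length segments present but flagged ``kept=False``.
    """
    rules = rules or CleavageRuleSet()
    sig_end = signal.cleavage_after if signal.present else 0
    mature = protein[sig_end:]
    positions = [s.position for s in sites]
    if positions != sorted(positions) or len(set(positions)) != len(positions):
        raise InternalConsistencyError("cleavage sites overlap or are unsorted")
    for site in sites:
        motif_at = mature[site.position - len(site.motif) : site.position]
        if motif_at != site.motif:
            raise InternalConsistencyError(
                f"site motif {site.motif!r} not found at position {site.position}"
            )
    segments: list[RawSegment] = []
    start = 0
    boundaries = positions + [len(mature)]
    for k, end in enumerate(boundaries):
        if k < len(sites):
            flank = sites[k].motif
            peptide = mature[start : end - len(flank)]
        else:  # C-terminal segment: trim whatever basic run is exposed
            if start >= end:
                break
            segment = mature[start:end]
            peptide, flank = trim_basic_flank(segment)
        kept = len(peptide) >= rules.min_peptide_len
        if not kept:
            logger.info(
                "dropping sub-minimum segment %r at %d-%d", peptide, start, end
            )
        segments.append(
            RawSegment(
                peptide=peptide,
                flank=flank,
                span=(sig_end + start, sig_end + start + len(peptide)),
                kept=kept,
            )
        )
        start = end
    return segments


def apply_terminal_ptms(
    segment: str,
    flank: str,
    options: PTMOptions | None = None,
    source_span: tuple[int, int] = (0, 0),
) -> MaturePeptide:
    """Apply amidation / pyroglutamate calls to a basic-trimmed segment.

    A C-terminal Gly exposed by flank removal (flank non-empty) is dropped
    and the peptide flagged as amidated; an N-terminal Gln (or Glu when
    enabled) sets the pyroglutamate flag without changing the sequence.
    Tyr sulfation is evaluated on the pre-amidation segment.
    """
    options = options or PTMOptions()
    sequence = segment
    amidated = False
    if options.amidation and flank and segment.endswith("G") and len(segment) > 1:
        sequence = segment[:-1]
        amidated = True
    pyroglu = bool(segment) and (
        (options.pyroglutamate_from_Q and segment[0] == "Q")
        or (options.pyroglutamate_from_E and segment[0] == "E")
    )
    return MaturePeptide(
        sequence=sequence,
        pre_amidation=segment,
        source_span=source_span,
        flank_removed=flank,
        amidated=amidated,
        pyroglutamate=pyroglu,
        sulfated_tyr=tuple(predict_tyr_sulfation(segment)),
    )


def predict_tyr_sulfation(peptide: str) -> list[int]:
    """1-based positions of Tyr residues in acidic context.

    A Tyr is called sulfated when at least one Asp/Glu occurs within ±2
    positions (window clipped at the peptide ends).
    """
    if not peptide:
        raise ValidationError("empty peptide")
    positions = []
    for i, aa in enumerate(peptide):
        if aa != "Y":
            continue
        window = peptide[max(0, i - 2) : i + 3]
        if any(b in "DE" for b in window):
            positions.append(i + 1)
    return positions


def predict_disulfides(chains: list[str]) -> DisulfidePrediction:
    """Count and heuristically pair Cys residues across peptide chains.

    ``bridge_count = floor(total Cys / 2)``; an odd total leaves the middle
    Cys of the concatenated list unpaired. Pairing is nested
    (first-with-last, recursively) and is reported as heuristic only.
    """
    if not chains:
        raise ValidationError("predict_disulfides requires at least one chain")
    cys: list[tuple[int, int]] = []
    for ci, chain in enumerate(chains):
        cys.extend((ci, i + 1) for i, aa in enumerate(chain) if aa == "C")
    pairs = []
    lo, hi = 0, len(cys) - 1
    while lo < hi:
        pairs.append((cys[lo], cys[hi]))
        lo += 1
        hi -= 1
    unpaired = cys[lo] if lo == hi else None
    return DisulfidePrediction(
        bridge_count=len(cys) // 2, pairing=tuple(pairs), unpaired=unpaired
    )


def process_precursor_protein(
    protein: str,
    signal_length: int,
    rules: CleavageRuleSet | None = None,
    options: PTMOptions | None = None,
) -> tuple[list["CleavageSite"], list[MaturePeptide]]:
    """Full deterministic processing of a precursor with a known signal
    boundary: cleavage-site search, excision, flank trimming and terminal
    PTMs. Returns the sites and the kept mature peptides."""
    from npmine.precursor import find_cleavage_sites

    rules = rules or CleavageRuleSet()
    signal = SignalPrediction(
        present=signal_length > 0, cleavage_after=signal_length, score=0.0
    )
    sites = find_cleavage_sites(protein[signal_length:], rules)
    segments = excise_peptides(protein, signal, sites, rules)
    peptides = [
        apply_terminal_ptms(s.peptide, s.flank, options, s.span)
        for s in segments
        if s.kept
    ]
    return sites, peptides


def detect_insulin_architecture(
    segments: list[str],
) -> InsulinArchitecture | None:
    """Recognize a B-C-A insulin-like chain layout among excised peptides.

    Requires exactly three chains in precursor order where the last (A)
    carries a CC doublet and at least three Cys, the first (B) at least two
    Cys, and the middle (C, excised connecting peptide) at most one Cys.
    """
    if len(segments) != 3:
        return None
    b, c, a = segments
    if "CC" not in a or a.count("C") < 3:
        return None
    if b.count("C") < 2 or c.count("C") > 1:
        return None
    bearing = [s for s in (b, c, a) if "C" in s]
    bridges = predict_disulfides(bearing).bridge_count
    return InsulinArchitecture(
        b_chain=b, c_chain=c, a_chain=a, disulfide_count=bridges
    )
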