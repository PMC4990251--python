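"""Precursor annotation: ORFs, signal peptides, convertase cleavage sites.

A secreted peptide precursor (preprohormone) is expected to show a
Met-initiated open reading frame, an N-terminal signal peptide, and basic
prohormone-convertase processing sites (KR / RR / KK pairs or longer K/R
runs) that delimit the peptide units.

The signal-peptide predictor is a transparent local heuristic, not a
reimplementation of any HMM/neural tool: candidate cleavage positions
15–45 are scored as the mean Kyte–Doolittle hydropathy of the 8 residues
preceding the final signal residue, plus a fixed bonus when the residues at
the −3 and −1 positions relative to the cut are small (A, G, S, C, T — the
classic (−3,−1) rule of von Heijne). The best position above a threshold is
reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from npmine.errors import ValidationError
from npmine.search import FRAMES, Transcript, translate_frame

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: Small residues allowed at the −3/−1 positions of a signal-peptidase site.
SMALL_RESIDUES = frozenset("AGSCT")

#: Default acceptance threshold for the signal score (hydropathy units +
#: bonus) and the bonus granted by the (−3,−1) rule.
SIGNAL_SCORE_THRESHOLD = 1.6
SIGNAL_SMALL_BONUS = 1.0
SIGNAL_SCAN_RANGE = (15, 45)
_SIGNAL_WINDOW = 8
_MIN_SIGNAL_PROTEIN = 25


@dataclass(frozen=True)
class OpenReadingFrame:
    """A Met-initiated ORF; ``nt_span`` is 0-based half-open on the forward
    strand of the transcript (the stop codon is included when present)."""

    transcript_id: str
    frame: int
    nt_span: tuple[int, int]
    protein: str
    aa_start: int = 0  # residue index of the Met in the frame translation
    has_start: bool = True
    has_stop: bool = False

    def __len__(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class SignalPrediction:
    """Predicted signal peptide; ``cleavage_after`` is the 1-based index of
    the last signal residue (0 when absent)."""

    present: bool
    cleavage_after: int
    score: float
    reason: str = ""


@dataclass(frozen=True)
class CleavageRuleSet:
    """Which basic motifs count as prohormone-convertase sites.

    Defaults: dibasic KR, RR and KK; runs of three or more basics always
    cleave; single Arg (monobasic) is off. RK is recognized only when added
    to ``accept_dibasic`` explicitly.
    """

    accept_dibasic: frozenset[str] = frozenset({"KR", "RR", "KK"})
    allow_multibasic_runs: bool = True
    allow_monobasic_R: bool = False
    min_peptide_len: int = 3

    def __post_init__(self) -> None:
        pairs = frozenset(self.accept_dibasic)
        bad = pairs - {"KR", "RR", "KK", "RK"}
        if bad:
            raise ValidationError(f"unknown dibasic motifs {sorted(bad)}")
        if not pairs:
            raise ValidationError("at least one dibasic motif must be enabled")
        object.__setattr__(self, "accept_dibasic", pairs)


@dataclass(frozen=True)
class CleavageSite:
    """One processing site. ``position`` is the 0-based index of the first
    residue AFTER the maximal basic run; ``motif`` is the run itself."""

    position: int
    motif: str
    cls: str  # dibasic | multibasic | monobasic


def find_orfs(
    t: Transcript, min_aa: int = 1, include_nested: bool = False
) -> list[OpenReadingFrame]:
    """All Met-initiated ORFs of at least ``min_aa`` residues in six frames.

    Within one stop-delimited region only the longest (5'-most Met) ORF is
    reported unless ``include_nested`` is set. Results are ordered
    longest-first (ties: frame order +1..-3, then coordinate).
    """
    if min_aa < 1:
        raise ValidationError("min_aa must be >= 1")
    L = len(t.sequence)
    orfs: list[OpenReadingFrame] = []
    for frame in FRAMES:
        pep = translate_frame(t.sequence, frame)
        offset = abs(frame) - 1
        region_start = 0
        for match in re.finditer(r"\*", pep + "*"):
            stop = match.start()
            has_stop = stop < len(pep)
            region = pep[region_start:stop]
            met_positions = [
                region_start + m.start() for m in re.finditer("M", region)
            ]
            if not include_nested:
                met_positions = met_positions[:1]
            for a in met_positions:
                protein = pep[a:stop]
                if len(protein) < min_aa:
                    continue
                nt0 = offset + 3 * a
                nt1 = offset + 3 * stop + (3 if has_stop else 0)
                span = (nt0, nt1) if frame > 0 else (L - nt1, L - nt0)
                orfs.append(
                    OpenReadingFrame(
                        transcript_id=t.id,
                        frame=frame,
                        nt_span=span,
                        protein=protein,
                        aa_start=a,
                        has_stop=has_stop,
                    )
                )
            region_start = stop + 1
    frame_order = {f: i for i, f in enumerate(FRAMES)}
    orfs.sort(key=lambda o: (-len(o.protein), frame_order[o.frame], o.nt_span))
    return orfs


def predict_signal_peptide(
    protein: str,
    threshold: float = SIGNAL_SCORE_THRESHOLD,
    small_bonus: float = SIGNAL_SMALL_BONUS,
) -> SignalPrediction:
    """Score candidate signal-peptidase cleavage positions 15–45.

    A candidate position ``c`` (1-based last signal residue) scores the mean
    Kyte–Doolittle hydropathy of residues ``c−8 … c−1`` plus ``small_bonus``
    when residues at −3 and −1 relative to the cut (positions ``c−2`` and
    ``c``) are both small. The highest-scoring position wins (ties: the
    earliest); ``present`` requires the score to reach ``threshold``.
    """
    if not protein or protein[0] != "M":
        raise ValidationError("signal prediction expects a Met-initiated protein")
    if len(protein) < _MIN_SIGNAL_PROTEIN:
        return SignalPrediction(
            present=False, cleavage_after=0, score=0.0,
            reason=f"protein shorter than {_MIN_SIGNAL_PROTEIN} residues",
        )
    lo, hi = SIGNAL_SCAN_RANGE
    best_c, best_score = 0, float("-inf")
    for c in range(lo, min(hi, len(protein) - 1) + 1):
        window = protein[c - 1 - _SIGNAL_WINDOW : c - 1]
        hydro = sum(KYTE_DOOLITTLE.get(a, 0.0) for a in window) / _SIGNAL_WINDOW
        score = hydro
        if protein[c - 1] in SMALL_RESIDUES and protein[c - 3] in SMALL_RESIDUES:
            score += small_bonus
        if score > best_score:
            best_c, best_score = c, score
    if best_score >= threshold:
        return SignalPrediction(present=True, cleavage_after=best_c, score=best_score)
    return SignalPrediction(
        present=False, cleavage_after=0, score=best_score,
        reason="no candidate position reached the score threshold",
    )


def find_cleavage_sites(
    protein_after_signal: str, rules: CleavageRuleSet | None = None
) -> list[CleavageSite]:
    """Locate convertase sites on the mature region of a precursor.

    Maximal runs of K/R are examined left to right. A run yields one site,
    cleaving C-terminal to the entire run, when (a) it is at least dibasic
    and its terminal pair is accepted, (b) it has length ≥ 3 and multibasic
    runs are allowed, or (c) it is a lone Arg and monobasic cleavage is
    enabled. A site whose peptide segment back to the previous accepted
    site would be shorter than ``min_peptide_len`` is suppressed; the first
    site is exempt because the segment abutting the signal peptide has a
    fuzzy N-terminal boundary.
    """
    if not protein_after_signal:
        raise ValidationError("empty mature region")
    rules = rules or CleavageRuleSet()
    sites: list[CleavageSite] = []
    prev_boundary: int | None = None  # first site is never suppressed
    for match in re.finditer(r"[KR]+", protein_after_signal):
        run = match.group()
        start, end = match.span()
        n = len(run)
        accepted = False
        cls = ""
        if n >= 2 and run[-2:] in rules.accept_dibasic:
            accepted = True
            cls = "dibasic" if n == 2 else "multibasic"
        elif n >= 3 and rules.allow_multibasic_runs:
            accepted = True
            cls = "multibasic"
        elif n == 1 and run == "R" and rules.allow_monobasic_R:
            accepted = True
            cls = "monobasic"
        if not accepted:
            continue
        if prev_boundary is not None and start - prev_boundary < rules.min_peptide_len:
            continue
        sites.append(CleavageSite(position=end, motif=run, cls=cls))
        prev_boundary = end
    return sites
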