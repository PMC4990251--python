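# Methods

`npmine` reimplements, as a tested desk-scale pipeline, the classic *in
silico* procedure for discovering neuropeptide (NP) and peptide-hormone
precursor transcripts in a transcriptome assembly. This note documents the
models, the parameters that matter, and the design decisions taken where
the procedure is usually left to external web tools.

## The discovery model

A secreted peptide precursor (preprohormone) is assumed to show four
hallmarks: a Met-initiated open reading frame; an N-terminal signal
peptide; prohormone-convertase processing sites (basic residue runs) that
delimit the peptide units; and short mature peptides carrying
characteristic post-translational modifications (PTMs). The pipeline
stages mirror that model:

1. **Query curation** (`querydb`). Known-peptide records are filtered by
   description keywords: keep records matching any include term
   (defaults: `NP`, `hormone`, `neurohormone`) and no exclude term
   (`receptor`, `hypothetical`, `uncharacterized`, enzyme names, …).
   Exclusion dominates. Short tokens (≤ 3 characters, e.g. `NP`) are
   matched at word boundaries so a two-letter abbreviation cannot fire
   inside an unrelated word; all other terms are plain case-insensitive
   substrings. Whether the original screens matched keyword fields or
   full description lines is not documented anywhere we could rely on;
   substring-on-description is our reproducible stand-in and is not
   claimed to be the historical mechanism.

2. **Translated search** (`search`). Every transcript is translated in
   six frames (codons containing N become X; stops become `*`), each
   frame is split at stops, and every query is aligned against every
   segment with an exact affine-gap Smith–Waterman (BLOSUM62, gap
   existence 11, extension 1 — a length-L gap costs 11 + L). The dynamic
   program runs over anti-diagonal wavefronts and the traceback is
   deterministic (first maximum in row-major order; diagonal preferred
   over up over left). Raw scores become E-values through the
   Karlin–Altschul closed form `E = K·m·n·exp(−λS)` with the standard
   gapped-BLOSUM62 constants λ = 0.267, K = 0.041, where `n` is the total
   residue count of all translated frames. These statistics rank hits;
   they deliberately do not reproduce NCBI BLAST's edge-corrected,
   composition-dependent estimates, so published E-values from full-size
   searches are not comparison targets. Per query, at most 3 hits with
   E < 0.01 are kept; candidate transcripts hit by several queries are
   merged, retaining the best evidence. `min_alignment_length` (default 8
   columns) suppresses spurious micro-hits.

3. **Precursor annotation** (`precursor`). ORFs are Met-initiated,
   reported longest-first; nested starts sharing a stop collapse to the
   longest unless requested otherwise. The signal-peptide call is a
   transparent heuristic, not an HMM: candidate cleavage positions
   15–45 score the mean Kyte–Doolittle hydropathy of the 8 residues
   preceding the final signal residue, plus a bonus of 1.0 when the −3
   and −1 residues are small (A, G, S, C, T). The best position must
   reach 1.6 (hydropathy units + bonus). The threshold and bonus were
   fixed against the synthetic precursor construction (hydrophobic core
   of L/I/V closed by Ala-Leu-Ala); no equivalence with SignalP is
   claimed, and real signal peptides with weak hydrophobic cores will be
   missed. Convertase sites are maximal K/R runs: a run cleaves
   C-terminal to the *whole* run when its terminal pair is KR, RR or KK,
   or when it is length ≥ 3 (multibasic); lone Arg is off by default and
   RK must be enabled explicitly. One site per run avoids zero-length
   peptides; carboxypeptidase trimming removes the basics regardless. A
   site whose peptide back to the previous accepted site would be shorter
   than `min_peptide_len` (default 3) is suppressed — except the first
   site, because the segment abutting the signal peptide has a fuzzy
   N-terminal boundary and legitimate precursors can open with a short
   spacer.

4. **Maturation** (`maturation`). Segments between boundaries are
   trimmed of their trailing basic run (the whole maximal run is removed,
   even the occasional 6-residue run seen in insulin-like precursors; a
   hard 4-residue cap would leave basic-ended "mature" peptides).
   Reconstruction is exact by construction: signal + Σ(peptide + flank)
   equals the precursor, with sub-minimum segments retained in the
   accounting but flagged as dropped. A C-terminal Gly exposed by
   trimming becomes an amide (the des-Gly form is reported alongside the
   pre-amidation segment; lengths are conventionally reported on the
   pre-amidation, basic-trimmed form). N-terminal Gln flags
   pyroglutamate (Glu optionally). Tyr is called sulfated when an
   Asp/Glu lies within ±2 residues; this local rule exactly separates
   the marked from unmarked tyrosines in the packaged printed-peptide
   table and is documented as a heuristic, not a Sulfinator equivalent.
   Disulfides are counted as `floor(total Cys / 2)`; the nested
   first-with-last pairing is reported as low-confidence evidence only.

5. **Family classification** (`families`). Profiles are data (YAML) and
   evaluate in specificity order: insulin-like (three chains in B-C-A
   order, A chain with a CC doublet and ≥ 3 Cys, Cys-poor C chain, B
   chain with ≥ 2 Cys), vasopressin-type (Cys at positions 1 and 6,
   length 9–16), GPB5 (a single 80–130-residue mature region with ≥ 9
   Cys and no convertase site), pedal/orcokinin (IGxG motif, length
   10–16), NPF (amidated C-terminal RxR(F/Y), or — for divergent members
   whose motif degenerated — a 30–40-mer with ≥ 2 sulfation-eligible
   Tyr). Anything else is `unclassified`, never a guess. Because
   fragmentary assemblies can truncate the B chain, the insulin rule has
   a relaxed branch (partial B tolerated when the A/C layout is intact)
   reported at `positional-only` confidence; the strict detector is
   unchanged. Cross-species "conserved residue" arguments require
   homolog alignments and are out of scope; all rules are within-sequence.

## Synthetic benchmark

The generator (`synthdata`) emulates the canonical precursor
organisation: Met + hydrophobic signal core (L/I/V, closed by Ala-Leu-Ala
so the (−3,−1) rule holds at the true boundary) + repeated
(unit + basic flank) blocks. Units come from the packaged printed-peptide
table, one template per family (the pedal-type template uses the
FDSIG-like precursor's four variants × 2 copies, matching its published
8-peptide organisation; signal lengths follow the published values where
stated: 24 for FDSIG-like and GPB5, 25 for NPF-like). Proteins are
back-translated with uniformly sampled synonymous codons, given a TAA
stop and random UTRs (30/40 nt by default; an in-frame stop guards the 5′
end so the encoded ORF is unambiguous). Decoys are uniform-random
transcripts matched in length and GC to the precursor transcripts, plus
dinucleotide-shuffled (Altschul–Erikson) copies of the precursor
transcripts as hard decoys. Ground truth is derived by running the
package's own processing rules on the embedded protein, so truth is
self-consistent by construction and any pipeline/truth disagreement is a
genuine stage failure, not a fixture artifact.

The standard benchmark is 5 precursors + 20 decoys (seed 7 in the test
suite; the acceptance script takes the seed on the command line). The
full run takes about ten seconds. What passing shows: the search ranks
true precursors first, the signal heuristic recovers constructed
boundaries exactly, and excision/PTM logic reproduces the expected
peptide sets. What it does not show: performance on fragmented contigs,
non-AUG starts, weakly hydrophobic signals, codon-usage bias, sequencing
error — none of which the generator simulates.

## Numerical and degenerate-input choices

- Alignment ties: first maximum in row-major order; diagonal > up > left
  during traceback; gap closure preferred over extension when equal.
- No positive-scoring pair → score 0 and an explicitly empty alignment.
- X scores by the substitution matrix's own X column; stops are never
  aligned across (frames are pre-split at `*`).
- Coordinates are 0-based half-open in memory and 1-based inclusive in
  every written file.
- Empty query sets or candidate-free runs produce empty reports, exit 0.
- Reports are byte-identical across reruns with the same inputs and
  config (sorted keys, no timestamps).

## Known limitations and noted ambiguities

- The monotonicity of the monobasic-Arg switch ("enabling it only adds
  sites") holds for the rule gate itself but can be violated once
  minimum-length suppression couples neighbouring sites; the property is
  therefore verified with suppression disabled.
- A vasopressin-type unit whose segment ends in Gly is amidated; the
  printed row of the vasopressin-like peptide counts 14 residues with its
  KR flank, 12 after trimming, 11 after amidation — the report carries
  both the pre-amidation and amidated forms rather than adjudicating
  which the "mature" length should be.
- The published inventory used here standardizes on the 11-precursor
  table (its Results text mentions a larger tally in one place; the
  table is the consistent source).
- E-values are comparable only within a run of this implementation.
- The insulin pairing heuristic does not attempt DiANNA-style learned
  pairing; only the bridge count is used downstream.
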