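# npmine

In silico discovery of neuropeptide (NP) and peptide-hormone precursor
transcripts in nucleotide transcriptome assemblies.

Invertebrate neuropeptidomes are routinely mined from assembled
transcriptomes rather than purified peptide extracts: a curated set of
known peptide sequences is searched against the assembly in translated
(tblastn-style) mode, candidate transcripts are screened for precursor
hallmarks — a Met-initiated ORF, an N-terminal signal peptide, basic
prohormone-convertase processing sites — and the mature peptides are
predicted together with their post-translational modifications
(C-terminal amidation at exposed Gly, N-terminal pyroglutamate from
Gln/Glu, tyrosine sulfation in acidic context, disulfide bridges). This
package implements that whole workflow as a reusable, fully tested
library plus CLI, for researchers who want a transparent, scriptable
version of a pipeline that is usually stitched together from web tools.

## The core computations

- **Translated homology search.** Six-frame translation, frames split at
  stop codons, exact affine-gap Smith–Waterman against every query
  (BLOSUM62; a gap of length *L* costs 11 + *L*). Significance uses the
  Karlin–Altschul form *E = K·m·n·e^(−λS)* (λ = 0.267, K = 0.041). Per
  query the best three hits with *E* < 0.01 become precursor candidates.
- **Precursor annotation.** Met-initiated ORFs; a signal-peptide
  heuristic scoring Kyte–Doolittle hydropathy of the 8 residues before
  each candidate cleavage position (scan 15–45) plus a (−3,−1)
  small-residue bonus; convertase sites as maximal K/R runs whose
  terminal pair is KR/RR/KK (or any run of ≥ 3 basics), cleaving
  C-terminal to the run.
- **Maturation.** Basic-flank trimming, amidation/pyroglutamate flags,
  ±2-acidic-context Tyr sulfation, disulfide counting
  (⌊Cys/2⌋, nested pairing as heuristic evidence), and B-C-A
  insulin-architecture detection.
- **Family classification.** Data-driven profiles, most specific first:
  insulin-like → vasopressin-type → glycoprotein-hormone β5 →
  pedal/orcokinin (IGxG) → NPF (RxR[F/Y]-amide or the sulfo-Tyr
  fallback) → unclassified.
- **Synthetic benchmarking.** A generator builds precursor transcripts
  (signal + repeated peptide units + basic flanks, back-translated with
  random synonymous codons and UTRs) among uniform-random and
  dinucleotide-shuffled decoys, with a machine-readable truth table, so
  every stage is testable without downloads.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Generate the standard synthetic benchmark (5 precursors among 20
decoys), mine it, and score the recovery:

```sh
npmine simulate --n-precursors 5 --n-decoys 20 --seed 7 --out-dir demo
npmine run-all demo/transcripts.fasta demo/queries.fasta --out-dir demo/out
npmine evaluate demo/transcripts.fasta demo/queries.fasta demo/truth.tsv
```

which prints

```json
{
  "candidate_precision": 1.0,
  "candidate_recall": 1.0,
  "n_detected": 5,
  "n_false": 0,
  "n_true": 5,
  "peptide_set_exact_rate": 1.0,
  "signal_exact_rate": 1.0
}
```

— all five embedded precursors were recovered, with the signal-peptide
boundary and the full mature peptide set of each reproduced exactly, and
none of the 20 decoys was reported. The report (`demo/out/report.tsv`)
interleaves precursor rows with their peptide sub-rows; for the
insulin-like precursor it reads (columns abridged):

```text
precursor  contig_0002  insulin_like  motif+architecture  Q_ILP_A_1  1.33e-22  +1  31  399  23  3
peptide    contig_0002  DFEHMCVHEDFSRSGAYSSCGSRLTSLVISKCDGNPYLASR  24   65  KR  amidated
peptide    contig_0002  DLEKISLTTESANSYLRP                         68   85  KR
peptide    contig_0002  NYEYVEDGMGVGIICECCVNTCTIRELDQYCES          88  120  KR  sulfoY=2,4,30
```

i.e. a candidate found in frame +1 with E ≈ 10⁻²², a 23-residue signal
peptide, three convertase sites, and the three excised chains of a
B-C-A insulin-like architecture (the peptide spans are 1-based positions
on the precursor protein). `run-all` also writes `report.json`,
`peptides.fasta` (PTM flags in headers) and a GFF3-like annotation; all
output formats have readers in the package and round-trip.

The hit table written by `npmine search` (and by `run-all
--keep-intermediates`) is a BLAST outfmt-6-like TSV with columns
`query_id, transcript_id, frame, raw_score, bit_score, evalue, q_start,
q_end, t_start, t_end`, spans 1-based inclusive in the translated-frame
coordinates.

Other subcommands: `build-queries` (keyword-filter a known-peptide FASTA
into a query database), `annotate`, `mature`, `classify` (stage-wise
analysis of transcripts or precursor proteins). Every command accepts
`--config` with a YAML parameter file; `-v/-vv` raise log verbosity on
stderr.

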