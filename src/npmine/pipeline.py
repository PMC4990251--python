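"""Pipeline orchestration, report containers and standard-format output.

``run_pipeline`` chains the stages: query filtering → six-frame translated
search → E-value candidate selection → per-candidate ORF choice, signal
prediction and convertase-site detection → peptide excision with PTM calls
→ family classification. Reports serialize to TSV and JSON (and optionally
peptide FASTA and a GFF3-like annotation table); all coordinates in written
output are 1-based inclusive, while the in-memory objects are 0-based
half-open. Rerunning with identical inputs and config produces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from npmine.errors import ConfigurationError, ValidationError
from npmine.families import (
    DEFAULT_PROFILES,
    FamilyCall,
    FamilyProfile,
    PrecursorPeptides,
    classify_family,
)
from npmine.io import read_fasta, write_fasta
from npmine.maturation import (
    MaturePeptide,
    PTMOptions,
    apply_terminal_ptms,
    excise_peptides,
)
from npmine.precursor import (
    CleavageRuleSet,
    CleavageSite,
    OpenReadingFrame,
    SIGNAL_SCORE_THRESHOLD,
    SIGNAL_SMALL_BONUS,
    find_cleavage_sites,
    find_orfs,
    predict_signal_peptide,
)
from npmine.querydb import QuerySet, read_query_fasta
from npmine.search import (
    AlignmentHit,
    SearchParams,
    Transcript,
    run_search,
    select_candidates,
)

logger = logging.getLogger(__name__)

HIT_TSV_COLUMNS = (
    "query_id",
    "transcript_id",
    "frame",
    "raw_score",
    "bit_score",
    "evalue",
    "q_start",
    "q_end",
    "t_start",
    "t_end",
)


@dataclass
class PipelineConfig:
    """Complete, serializable parameter set for one pipeline run."""

    search: SearchParams = field(default_factory=SearchParams)
    cleavage: CleavageRuleSet = field(default_factory=CleavageRuleSet)
    ptm: PTMOptions = field(default_factory=PTMOptions)
    signal_threshold: float = SIGNAL_SCORE_THRESHOLD
    signal_bonus: float = SIGNAL_SMALL_BONUS
    min_orf_aa: int = 40
    profiles: tuple[FamilyProfile, ...] = DEFAULT_PROFILES
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "search": dataclasses.asdict(self.search),
            "cleavage": {
                "accept_dibasic": sorted(self.cleavage.accept_dibasic),
                "allow_multibasic_runs": self.cleavage.allow_multibasic_runs,
                "allow_monobasic_R": self.cleavage.allow_monobasic_R,
                "min_peptide_len": self.cleavage.min_peptide_len,
            },
            "ptm": dataclasses.asdict(self.ptm),
            "signal_threshold": self.signal_threshold,
            "signal_bonus": self.signal_bonus,
            "min_orf_aa": self.min_orf_aa,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "search" in data:
            kwargs["search"] = SearchParams(**data["search"])
        if "cleavage" in data:
            cl = dict(data["cleavage"])
            if "accept_dibasic" in cl:
                cl["accept_dibasic"] = frozenset(cl["accept_dibasic"])
            kwargs["cleavage"] = CleavageRuleSet(**cl)
        if "ptm" in data:
            kwargs["ptm"] = PTMOptions(**data["ptm"])
        for key in ("signal_threshold", "signal_bonus", "min_orf_aa", "seed"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PrecursorRow:
    """Everything the pipeline concluded about one candidate precursor."""

    transcript_id: str
    best_hit: AlignmentHit
    orf: OpenReadingFrame
    signal_cleavage_after: int
    signal_score: float
    sites: list[CleavageSite]
    peptides: list[MaturePeptide]
    family_call: FamilyCall


@dataclass
class PipelineReport:
    """Ordered precursor rows plus summary counts."""

    rows: list[PrecursorRow] = field(default_factory=list)
    n_transcripts: int = 0
    n_queries: int = 0
    n_hits: int = 0
    n_candidate_transcripts: int = 0

    def summary(self) -> dict:
        families: dict[str, int] = {}
        for row in self.rows:
            families[row.family_call.family] = (
                families.get(row.family_call.family, 0) + 1
            )
        return {
            "n_transcripts": self.n_transcripts,
            "n_queries": self.n_queries,
            "n_hits": self.n_hits,
            "n_candidate_transcripts": self.n_candidate_transcripts,
            "n_reported_precursors": len(self.rows),
            "families": dict(sorted(families.items())),
        }


def _choose_orf(
    orfs: list[OpenReadingFrame], hit: AlignmentHit
) -> OpenReadingFrame | None:
    """Prefer the longest ORF in the hit's frame whose translated-frame
    span overlaps the hit; fall back to the longest ORF overall."""
    in_frame = [
        o
        for o in orfs
        if o.frame == hit.frame
        and o.aa_start < hit.target_span[1]
        and o.aa_start + len(o.protein) > hit.target_span[0]
    ]
    if in_frame:
        return in_frame[0]  # find_orfs sorts longest-first
    return orfs[0] if orfs else None


def annotate_candidate(
    transcript: Transcript, hit: AlignmentHit, config: PipelineConfig
) -> PrecursorRow | None:
    """ORF choice, signal prediction, cleavage, maturation and family call
    for one candidate transcript. Returns None when no suitable ORF exists
    or no signal peptide is found (precursor hallmarks absent)."""
    orfs = find_orfs(transcript, min_aa=config.min_orf_aa)
    orf = _choose_orf(orfs, hit)
    if orf is None:
        logger.info("%s: no ORF of >= %d aa", transcript.id, config.min_orf_aa)
        return None
    signal = predict_signal_peptide(
        orf.protein, threshold=config.signal_threshold, small_bonus=config.signal_bonus
    )
    if not signal.present:
        logger.info("%s: no signal peptide (%s)", transcript.id, signal.reason)
        return None
    mature = orf.protein[signal.cleavage_after :]
    sites = find_cleavage_sites(mature, config.cleavage)
    segments = excise_peptides(orf.protein, signal, sites, config.cleavage)
    peptides = [
        apply_terminal_ptms(s.peptide, s.flank, config.ptm, s.span)
        for s in segments
        if s.kept
    ]
    (call,) = classify_family(
        [
            PrecursorPeptides(
                subject_id=transcript.id,
                peptides=peptides,
                n_cleavage_sites=len(sites),
            )
        ],
        config.profiles,
    )
    return PrecursorRow(
        transcript_id=transcript.id,
        best_hit=hit,
        orf=orf,
        signal_cleavage_after=signal.cleavage_after,
        signal_score=signal.score,
        sites=sites,
        peptides=peptides,
        family_call=call,
    )


def run_pipeline(
    transcripts: list[Transcript] | str | Path,
    queries: QuerySet | str | Path,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """Run the full discovery pipeline; inputs may be in-memory objects or
    FASTA paths. An empty query set or candidate set yields an empty report
    (not an error)."""
    config = config or PipelineConfig()
    if not isinstance(transcripts, list):
        transcripts = [
            Transcript(id=r.id, sequence=r.sequence)
            for r in read_fasta(transcripts, "nucleotide")
        ]
    if not isinstance(queries, QuerySet):
        queries = read_query_fasta(queries)
    report = PipelineReport(
        n_transcripts=len(transcripts), n_queries=len(queries.records)
    )
    if not queries.records or not transcripts:
        return report
    hits = run_search(transcripts, queries, config.search)
    report.n_hits = len(hits)
    candidates = select_candidates(hits, config.search)
    report.n_candidate_transcripts = len(candidates.transcripts)
    tx_by_id = {t.id: t for t in transcripts}
    for tid in sorted(candidates.transcripts):
        row = annotate_candidate(tx_by_id[tid], candidates.transcripts[tid], config)
        if row is not None:
            report.rows.append(row)
    return report


# --- serialization ---------------------------------------------------------


def hits_to_tsv(hits: list[AlignmentHit], path: str | Path) -> None:
    """BLAST outfmt-6-like hit table; spans 1-based inclusive."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(HIT_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.transcript_id}\t{h.frame:+d}\t{h.raw_score:g}"
                f"\t{h.bit_score:.2f}\t{h.evalue:.3g}"
                f"\t{h.query_span[0] + 1}\t{h.query_span[1]}"
                f"\t{h.target_span[0] + 1}\t{h.target_span[1]}\n"
            )


def hits_from_tsv(path: str | Path) -> list[dict]:
    """Read a hit table back as dicts (numeric fields parsed, spans kept
    1-based inclusive as written)."""
    lines = Path(path).read_text().splitlines()
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        out.append(
            {
                "query_id": f[0],
                "transcript_id": f[1],
                "frame": int(f[2]),
                "raw_score": float(f[3]),
                "bit_score": float(f[4]),
                "evalue": float(f[5]),
                "q_start": int(f[6]),
                "q_end": int(f[7]),
                "t_start": int(f[8]),
                "t_end": int(f[9]),
            }
        )
    return out


def report_to_dict(report: PipelineReport) -> dict:
    """JSON-ready report; all coordinates 1-based inclusive."""
    precursors = []
    for row in report.rows:
        precursors.append(
            {
                "transcript_id": row.transcript_id,
                "best_query": row.best_hit.query_id,
                "evalue": row.best_hit.evalue,
                "bit_score": round(row.best_hit.bit_score, 2),
                "frame": row.best_hit.frame,
                "orf_span": [row.orf.nt_span[0] + 1, row.orf.nt_span[1]],
                "protein_length": len(row.orf.protein),
                "signal_cleavage_after": row.signal_cleavage_after,
                "signal_score": round(row.signal_score, 3),
                "cleavage_sites": [
                    {"after": s.position, "motif": s.motif, "class": s.cls}
                    for s in row.sites
                ],
                "peptides": [
                    {
                        "sequence": p.sequence,
                        "pre_amidation": p.pre_amidation,
                        "span": [p.source_span[0] + 1, p.source_span[1]],
                        "flank": p.flank_removed,
                        "amidated": p.amidated,
                        "pyroglutamate": p.pyroglutamate,
                        "sulfated_tyr": list(p.sulfated_tyr),
                    }
                    for p in row.peptides
                ],
                "family": row.family_call.family,
                "confidence": row.family_call.confidence,
                "evidence": list(row.family_call.evidence),
            }
        )
    return {"summary": report.summary(), "precursors": precursors}


def validate_report_dict(data: dict) -> None:
    """Structural check of a report dict against the packaged schema
    (required keys and container types only)."""
    schema = json.loads(
        resources.files("npmine.data").joinpath("report_schema.json").read_text()
    )
    for key in schema["required"]:
        if key not in data:
            raise ValidationError(f"report missing key {key!r}")
    for key in schema["properties"]["summary"]["required"]:
        if key not in data["summary"]:
            raise ValidationError(f"report summary missing {key!r}")
    item_req = schema["properties"]["precursors"]["items"]["required"]
    pep_req = schema["properties"]["precursors"]["items"]["properties"]["peptides"][
        "items"
    ]["required"]
    for row in data["precursors"]:
        for key in item_req:
            if key not in row:
                raise ValidationError(f"precursor row missing {key!r}")
        for pep in row["peptides"]:
            for key in pep_req:
                if key not in pep:
                    raise ValidationError(f"peptide entry missing {key!r}")


REPORT_TSV_COLUMNS = (
    "row_type",
    "transcript_id",
    "family",
    "confidence",
    "best_query",
    "evalue",
    "frame",
    "orf_start",
    "orf_end",
    "signal_cleavage_after",
    "n_sites",
    "peptide_seq",
    "pep_start",
    "pep_end",
    "flank",
    "amidated",
    "pyroglu",
    "sulfo_positions",
)


def write_report(
    report: PipelineReport,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("tsv", "json"),
) -> dict[str, Path]:
    """Write the report in the requested formats into *out_dir*.

    ``tsv`` and ``json`` are always sensible; ``fasta`` adds a mature
    peptide FASTA with PTM annotations in the headers and ``gff`` a
    GFF3-like transcript-relative annotation table. Returns the mapping of
    format name to file path. Unknown format keys raise.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    known = {"tsv", "json", "fasta", "gff"}
    unknown = set(formats) - known
    if unknown:
        raise ConfigurationError(f"unknown report format(s) {sorted(unknown)}")
    data = report_to_dict(report)
    written: dict[str, Path] = {}
    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        written["json"] = path
    if "tsv" in formats:
        path = out_dir / "report.tsv"
        with path.open("w") as fh:
            fh.write("\t".join(REPORT_TSV_COLUMNS) + "\n")
            for row in data["precursors"]:
                base = (
                    "precursor",
                    row["transcript_id"],
                    row["family"],
                    row["confidence"],
                    row["best_query"],
                    f"{row['evalue']:.3g}",
                    f"{row['frame']:+d}",
                    str(row["orf_span"][0]),
                    str(row["orf_span"][1]),
                    str(row["signal_cleavage_after"]),
                    str(len(row["cleavage_sites"])),
                )
                fh.write("\t".join(base + ("", "", "", "", "", "", "")) + "\n")
                for pep in row["peptides"]:
                    fh.write(
                        "\t".join(
                            (
                                "peptide",
                                row["transcript_id"],
                                row["family"],
                                "",
                                "",
                                "",
                                "",
                                "",
                                "",
                                "",
                                "",
                                pep["sequence"],
                                str(pep["span"][0]),
                                str(pep["span"][1]),
                                pep["flank"],
                                str(int(pep["amidated"])),
                                str(int(pep["pyroglutamate"])),
                                ",".join(map(str, pep["sulfated_tyr"])),
                            )
                        )
                        + "\n"
                    )
        written["tsv"] = path
    if "fasta" in formats:
        path = out_dir / "peptides.fasta"
        records = []
        for row in data["precursors"]:
            for k, pep in enumerate(row["peptides"], start=1):
                tags = []
                if pep["amidated"]:
                    tags.append("amidated")
                if pep["pyroglutamate"]:
                    tags.append("pyroGlu")
                if pep["sulfated_tyr"]:
                    tags.append(
                        "sulfoY=" + ",".join(map(str, pep["sulfated_tyr"]))
                    )
                desc = f"family={row['family']} " + (";".join(tags) if tags else "-")
                records.append(
                    (f"{row['transcript_id']}_pep{k}", desc, pep["sequence"])
                )
        write_fasta(records, path)
        written["fasta"] = path
    if "gff" in formats:
        path = out_dir / "annotation.gff3"
        with path.open("w") as fh:
            fh.write("##gff-version 3\n")
            for row in data["precursors"]:
                strand = "+" if row["frame"] > 0 else "-"
                fh.write(
                    f"{row['transcript_id']}\tnpmine\tCDS\t{row['orf_span'][0]}"
                    f"\t{row['orf_span'][1]}\t.\t{strand}\t0"
                    f"\tID={row['transcript_id']}.orf;family={row['family']}\n"
                )
        written["gff"] = path
    return written


def read_report_json(path: str | Path) -> dict:
    """Read back a JSON report and validate its structure."""
    data = json.loads(Path(path).read_text())
    validate_report_dict(data)
    return data


def read_report_tsv(path: str | Path) -> list[dict]:
    """Read back the TSV report as a list of row dicts."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]
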