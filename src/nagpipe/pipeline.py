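"""End-to-end orchestration of the annotation and NAG-discovery stages.

homology annotation → transcript classification (excluding loci already
covered by homology) → NAG consolidation, triage and presence matrix.
Also holds the TSV readers for the exon-chain mapping tables that connect
the stages when run from files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .homology import (
    GeneCall,
    MappedLocus,
    TemplateGene,
    annotate_genome,
    call_gene,
    classify_cds,
    verify_support,
    reconstruct_cds,
    INTACT,
)
from .io import AnnotationRecord, CoverageTrack, GenomeAssembly, log_stage
from .nags import (
    Cluster,
    HitRecord,
    NagRecord,
    build_presence_matrix,
    classify_nag,
    deduplicate,
    family_size,
)
from .rnaseq import CODING_NAG, MappedTranscript, TranscriptCall, annotate_transcripts
from .simulate import Cohort, REFERENCE_TAGS

__all__ = [
    "PipelineResult",
    "read_mappings_tsv",
    "read_templates_tsv",
    "read_transcripts",
    "homology_calls_to_annotations",
    "nag_status",
    "consolidate",
    "run_cohort",
]


@dataclass
class PipelineResult:
    homology_calls: Dict[str, Dict[str, GeneCall]]  # genome -> template -> call
    transcript_calls: Dict[str, List[TranscriptCall]]
    clusters: List[Cluster]
    nag_records: List[NagRecord]
    presence: pd.DataFrame


def read_mappings_tsv(path: str | Path) -> List[MappedLocus]:
    """Exon-chain mapping table: template_id, isoform_id, seq_id,
    exons ("s-e,s-e" 0-based half-open), strand, identity."""
    df = pd.read_csv(path, sep="\t", dtype={"template_id": str, "isoform_id": str})
    out: List[MappedLocus] = []
    for row in df.itertuples(index=False):
        exons = tuple(
            (int(p.split("-")[0]), int(p.split("-")[1])) for p in str(row.exons).split(",")
        )
        out.append(
            MappedLocus(
                template_id=str(row.template_id),
                seq_id=str(row.seq_id),
                exons=exons,
                strand=str(row.strand),
                identity=float(row.identity),
                isoform_id=str(row.isoform_id),
            )
        )
    return out


def read_templates_tsv(path: str | Path) -> List[TemplateGene]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: List[TemplateGene] = []
    for row in df.itertuples(index=False):
        sec = frozenset(int(k) for k in row.sec_codons.split(",") if k)
        out.append(TemplateGene(row.id, row.source_kind, sec))
    return out


def read_transcripts(fasta: Mapping[str, str], exon_records: Sequence[AnnotationRecord]) -> List[MappedTranscript]:
    """Assemble MappedTranscript objects from a sequence dict plus GFF3 exon
    rows grouped by their Parent attribute."""
    chains: Dict[str, List[AnnotationRecord]] = {}
    for rec in exon_records:
        parent = rec.attributes.get("Parent")
        if parent:
            chains.setdefault(parent, []).append(rec)
    out: List[MappedTranscript] = []
    for tid, seq in fasta.items():
        recs = sorted(chains.get(tid, []), key=lambda r: r.start)
        if not recs:
            raise ValueError(f"transcript {tid!r} has no exon records")
        out.append(
            MappedTranscript(
                tid,
                recs[0].seq_id,
                tuple((r.start, r.end) for r in recs),
                recs[0].strand,
                seq,
            )
        )
    return out


def homology_calls_to_annotations(calls: Mapping[str, GeneCall]) -> List[AnnotationRecord]:
    """Gene-span annotation records from homology calls (for overlap tests)."""
    out: List[AnnotationRecord] = []
    for call in calls.values():
        if call.locus is None:
            continue
        out.append(
            AnnotationRecord(
                call.locus.seq_id,
                "gene",
                call.locus.start,
                call.locus.end,
                call.locus.strand,
                {"ID": call.template_id, "status": call.status},
            )
        )
    return out


def nag_status(
    genome: GenomeAssembly,
    mappings: Sequence[MappedLocus],
    coverage: CoverageTrack,
    min_cov: int = 10,
) -> str:
    """Status of one NAG in one genome from its cross-mapped locus.

    No mapping → absent; intact reconstructed CDS → present; a supported
    loss-of-function mutation → pseudogenized; an unsupported one → present
    (the apparent mutation is attributed to assembly error).
    """
    if not mappings:
        return "absent"
    best = min(mappings, key=lambda m: (-m.identity, m.seq_id, m.start))
    diagnosis = classify_cds(reconstruct_cds(genome, best))
    if diagnosis.status == INTACT:
        return "intact"
    support = verify_support(best, coverage, min_cov)
    return call_gene(diagnosis, support, "gene")


def consolidate(
    candidates: Mapping[str, str],
    hits: Sequence[HitRecord],
    genomes: Mapping[str, GenomeAssembly],
    nag_mappings: Mapping[str, Sequence[MappedLocus]],
    coverage: Mapping[str, CoverageTrack],
    threshold: float = 0.985,
    min_cov: int = 10,
    reference_tags=REFERENCE_TAGS,
) -> Tuple[List[Cluster], List[NagRecord], pd.DataFrame]:
    """Collapse per-genome NAG candidates and build the presence matrix.

    ``candidates`` maps candidate transcript id → spliced sequence across
    all genomes; ``nag_mappings`` holds per-genome cross-mappings keyed by
    candidate id. Rows of the matrix are cluster representatives.
    """
    clusters = deduplicate(candidates, threshold=threshold)
    hits_by_query: Dict[str, List[HitRecord]] = {}
    for h in hits:
        hits_by_query.setdefault(h.query, []).append(h)
    records: List[NagRecord] = []
    calls: List[Tuple[str, str, str]] = []
    for cluster in clusters:
        rep = cluster.representative
        rep_hits = hits_by_query.get(rep, [])
        records.append(
            NagRecord(
                id=rep,
                sequence=candidates[rep],
                members=list(cluster.members),
                nag_class=classify_nag(rep_hits, reference_tags),
                family_size=family_size(rep_hits),
            )
        )
        for g, genome in genomes.items():
            maps = [m for m in nag_mappings.get(g, []) if m.template_id == rep]
            calls.append((rep, g, nag_status(genome, maps, coverage[g], min_cov)))
    matrix = build_presence_matrix(
        calls,
        nag_ids=[c.representative for c in clusters],
        genome_ids=list(genomes),
    )
    log_stage("consolidate", len(candidates), len(clusters))
    return clusters, records, matrix


def run_cohort(cohort: Cohort, min_cov: Optional[int] = None) -> PipelineResult:
    """Run the full pipeline over an in-memory cohort."""
    min_cov = cohort.config.min_cov if min_cov is None else min_cov
    homology_calls: Dict[str, Dict[str, GeneCall]] = {}
    transcript_calls: Dict[str, List[TranscriptCall]] = {}
    candidates: Dict[str, str] = {}
    for g, genome in cohort.genomes.items():
        calls = annotate_genome(
            genome,
            cohort.templates,
            cohort.template_mappings[g],
            cohort.coverage[g],
            min_cov=min_cov,
        )
        homology_calls[g] = calls
        annotations = homology_calls_to_annotations(calls)
        t_calls = annotate_transcripts(cohort.transcripts[g], annotations)
        transcript_calls[g] = t_calls
        by_id = {t.id: t for t in cohort.transcripts[g]}
        for c in t_calls:
            if c.verdict == CODING_NAG:
                candidates[c.transcript_id] = by_id[c.transcript_id].sequence
    clusters, records, matrix = consolidate(
        candidates,
        cohort.hits,
        cohort.genomes,
        cohort.nag_mappings,
        cohort.coverage,
        min_cov=min_cov,
    )
    return PipelineResult(homology_calls, transcript_calls, clusters, records, matrix)
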