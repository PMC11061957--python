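"""Homology-projected gene annotation.

Template CDS models (genes and pseudogenes from reference annotations) are
projected onto a target genome as mapped exon chains. The mapped CDS is
reconstructed and diagnosed: intact if its length is a multiple of three, it
ends in a stop codon and carries no internal stop (after selenocysteine
recoding); otherwise it carries a nonsense or ORF-shift (frameshift)
mutation. An apparent loss-of-function mutation counts only when every base
of the locus is covered by at least ``min_cov`` perfectly matching short
reads — otherwise it is attributed to uncorrected long-read error and the
gene is called partially supported. Pseudogene templates that project to an
intact, fully read-supported ORF are resurrected as genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .io import CoverageTrack, GenomeAssembly, log_stage
from .seq import STOP_CODONS, reverse_complement

__all__ = [
    "TemplateGene",
    "MappedLocus",
    "CdsDiagnosis",
    "GeneCall",
    "TemplateUnmapped",
    "select_best_locus",
    "reconstruct_cds",
    "classify_cds",
    "verify_support",
    "call_gene",
    "frameshift_impact",
    "annotate_genome",
]

INTACT = "intact"
NONSENSE = "nonsense"
ORF_SHIFT = "orf_shift"

READ_SUPPORTED = "read_supported"
UNSUPPORTED = "unsupported"
NOT_APPLICABLE = "not_applicable"

INTACT_GENE = "intact_gene"
PARTIAL_GENE = "partially_supported_gene"
PSEUDOGENE = "pseudogene"
GENE_FROM_PSEUDO = "gene_from_pseudogene"


class TemplateUnmapped(LookupError):
    """Raised when a template has no mapped locus in a genome (gene absent)."""


@dataclass(frozen=True)
class TemplateGene:
    """A reference gene or pseudogene model used as a projection template."""

    id: str
    source_kind: str  # "gene" | "pseudogene"
    sec_codon_indices: FrozenSet[int] = frozenset()  # 1-based codon ordinals

    def __post_init__(self) -> None:
        if self.source_kind not in ("gene", "pseudogene"):
            raise ValueError(f"invalid source_kind {self.source_kind!r}")


@dataclass(frozen=True)
class MappedLocus:
    """One projection of a template isoform onto the target genome.

    ``exons`` are 0-based half-open intervals in ascending genomic order;
    for minus-strand loci the reconstructed CDS is the reverse complement of
    their concatenation.
    """

    template_id: str
    seq_id: str
    exons: Tuple[Tuple[int, int], ...]
    strand: str
    identity: float
    isoform_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")
        prev = -1
        for s, e in self.exons:
            if s >= e or s < prev:
                raise ValueError("exon chain must be ordered and non-overlapping")
            prev = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class CdsDiagnosis:
    """Outcome of the intact-ORF test on a reconstructed CDS.

    ``detail`` is the 1-based ordinal of the first offending codon for
    nonsense calls, or the length-mod-3 residue for ORF shifts.
    """

    status: str  # intact | nonsense | orf_shift
    detail: int = 0


@dataclass(frozen=True)
class GeneCall:
    template_id: str
    locus: Optional[MappedLocus]
    diagnosis: Optional[CdsDiagnosis]
    support: str
    status: str  # intact_gene | partially_supported_gene | pseudogene | gene_from_pseudogene


def select_best_locus(mappings: Sequence[MappedLocus]) -> MappedLocus:
    """The locus with the highest mapping identity; ties go to the leftmost
    (lexicographic chromosome, then start)."""
    if not mappings:
        raise TemplateUnmapped("template unmapped")
    return min(mappings, key=lambda m: (-m.identity, m.seq_id, m.start))


def reconstruct_cds(genome: GenomeAssembly, locus: MappedLocus) -> str:
    """Concatenate the mapped exons into a putative full-length CDS."""
    chrom = genome[locus.seq_id]
    length = len(chrom)
    parts: List[str] = []
    for s, e in locus.exons:
        if s < 0 or e > length:
            raise ValueError(
                f"exon [{s}, {e}) outside {locus.seq_id} (length {length})"
            )
        parts.append(chrom[s:e])
    cds = "".join(parts)
    if locus.strand == "-":
        cds = reverse_complement(cds)
    return cds


def classify_cds(cds: str, sec_codon_indices: Iterable[int] = ()) -> CdsDiagnosis:
    """Diagnose a reconstructed CDS as intact / nonsense / orf_shift.

    TGA codons at the given 1-based selenocysteine ordinals are recoded
    before the internal-stop test. A CDS whose final codon is not a stop is
    grouped with the nonsense class (stop-loss), detail = final codon ordinal.
    """
    if not cds:
        raise ValueError("empty CDS")
    cds = cds.upper()
    if len(cds) % 3 != 0:
        return CdsDiagnosis(ORF_SHIFT, detail=len(cds) % 3)
    sec = set(sec_codon_indices)
    n_codons = len(cds) // 3
    for k in range(n_codons - 1):
        codon = cds[3 * k : 3 * k + 3]
        if codon in STOP_CODONS and not (codon == "TGA" and (k + 1) in sec):
            return CdsDiagnosis(NONSENSE, detail=k + 1)
    if cds[-3:] not in STOP_CODONS:
        return CdsDiagnosis(NONSENSE, detail=n_codons)
    return CdsDiagnosis(INTACT)


def verify_support(
    locus: MappedLocus, coverage: CoverageTrack, min_cov: int = 10
) -> str:
    """Read-support verdict: supported iff every exon base has depth >= min_cov.

    A chromosome missing from the track reads as depth zero (unsupported):
    absence of evidence is not support.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    for s, e in locus.exons:
        if coverage.min_depth(locus.seq_id, s, e) < min_cov:
            return UNSUPPORTED
    return READ_SUPPORTED


def call_gene(diagnosis: CdsDiagnosis, support: str, source_kind: str) -> str:
    """Final gene status from the decision table.

    ===========  ==============  ==========  ========================
    diagnosis    support         template    call
    ===========  ==============  ==========  ========================
    intact       not_applicable  gene        intact_gene
    intact       read_supported  pseudogene  gene_from_pseudogene
    intact       unsupported     pseudogene  pseudogene (stays)
    LOF          read_supported  either      pseudogene
    LOF          unsupported     gene        partially_supported_gene
    LOF          unsupported     pseudogene  pseudogene (stays)
    ===========  ==============  ==========  ========================

    A pseudogene template is only resurrected when its intact ORF is fully
    read-supported.
    """
    if source_kind not in ("gene", "pseudogene"):
        raise ValueError(f"invalid source_kind {source_kind!r}")
    if diagnosis.status == INTACT:
        if source_kind == "gene":
            if support != NOT_APPLICABLE:
                raise ValueError("intact gene-template call takes no support flag")
            return INTACT_GENE
        if support == READ_SUPPORTED:
            return GENE_FROM_PSEUDO
        if support == UNSUPPORTED:
            return PSEUDOGENE
        raise ValueError("intact pseudogene-template call requires a support flag")
    # loss-of-function diagnosis
    if support == READ_SUPPORTED:
        return PSEUDOGENE
    if support == UNSUPPORTED:
        return PARTIAL_GENE if source_kind == "gene" else PSEUDOGENE
    raise ValueError("loss-of-function diagnosis requires a support flag")


def frameshift_impact(cds_len: int, del_start: int, del_end: int) -> int:
    """Codons affected by a frameshifting deletion at 1-based CDS positions.

    Counts from the codon containing the first deleted base through the
    final codon of the original CDS: ``cds_len/3 - ceil(del_start/3) + 1``.
    """
    if cds_len % 3 != 0:
        raise ValueError("cds_len must be a multiple of 3")
    if not (1 <= del_start <= del_end <= cds_len):
        raise ValueError("deletion interval outside the CDS")
    return cds_len // 3 - math.ceil(del_start / 3) + 1


def annotate_genome(
    genome: GenomeAssembly,
    templates: Sequence[TemplateGene],
    mappings: Sequence[MappedLocus],
    coverage: CoverageTrack,
    min_cov: int = 10,
    min_map_identity: float = 0.0,
) -> Dict[str, GeneCall]:
    """Run the full homology-annotation pass over one genome.

    Each isoform of each template is resolved to its best locus; a template
    is intact if any isoform reconstructs an intact CDS (the permissive
    any-isoform aggregation). Unmapped templates are absent from the result.
    """
    by_template: Dict[str, Dict[str, List[MappedLocus]]] = {}
    for m in mappings:
        if m.identity < min_map_identity:
            continue
        by_template.setdefault(m.template_id, {}).setdefault(m.isoform_id, []).append(m)

    calls: Dict[str, GeneCall] = {}
    for template in templates:
        isoform_maps = by_template.get(template.id)
        if not isoform_maps:
            continue
        per_isoform: List[Tuple[MappedLocus, CdsDiagnosis]] = []
        for maps in isoform_maps.values():
            locus = select_best_locus(maps)
            cds = reconstruct_cds(genome, locus)
            per_isoform.append((locus, classify_cds(cds, template.sec_codon_indices)))
        intact = [(l, d) for l, d in per_isoform if d.status == INTACT]
        if intact:
            locus, diagnosis = intact[0]
            if template.source_kind == "gene":
                support = NOT_APPLICABLE
            else:
                support = verify_support(locus, coverage, min_cov)
        else:
            locus, diagnosis = max(per_isoform, key=lambda ld: ld[0].identity)
            support = verify_support(locus, coverage, min_cov)
        status = call_gene(diagnosis, support, template.source_kind)
        calls[template.id] = GeneCall(template.id, locus, diagnosis, support, status)
    log_stage("annotate_genome", len(templates), len(calls))
    return calls
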