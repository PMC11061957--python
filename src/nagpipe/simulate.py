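"""Synthetic cohorts with planted truth.

Generates multi-genome chicken-like test data with the statistical
structure the analyses assume: chromosomes with class-dependent G/C
(macro ≈ 0.40, middle ≈ 0.42, micro ≈ 0.53) and subtelomeric G/C
elevation, multi-exon template genes whose orthologs carry planted
nonsense or frameshift mutations with or without short-read support,
NAG loci with coding transcripts, decoy transcripts (overlapping, lncRNA,
short), taxon-labelled hit tables, coverage tracks and expression
matrices. Every planted object's true status is recorded so pipeline
recall and precision can be measured exactly.

All randomness flows from the single config seed; two runs with equal
configs produce identical objects and identical emitted files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .context import WindowStat, chromosome_class, MACRO, MIDDLE, MICRO, UNPLACED
from .homology import (
    GENE_FROM_PSEUDO,
    INTACT_GENE,
    PARTIAL_GENE,
    PSEUDOGENE,
    MappedLocus,
    TemplateGene,
)
from .io import CoverageTrack, GenomeAssembly
from .nags import GNAG, NOVEL, ONAG, HitRecord
from .rnaseq import CODING_NAG, LNCRNA, OVERLAPS_EXISTING, UNCLASSIFIED, MappedTranscript
from .seq import STOP_CODONS, reverse_complement

__all__ = [
    "SimConfig",
    "TruthSet",
    "Cohort",
    "simulate_genome",
    "simulate_cohort",
    "simulate_window_stats",
    "simulate_gene_context",
    "random_sequence",
    "plant_g4",
    "write_cohort",
]

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

G4_INSERT = "GGGTTAGGGTTAGGGTTAGGG"  # one canonical quadruplex

REFERENCE_TAGS = frozenset({"GRCg6a", "GRCg7b", "GRCg7w"})

_OTHER_SPECIES = (
    "Meleagris gallopavo",
    "Coturnix japonica",
    "Numida meleagris",
    "Anas platyrhynchos",
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the chicken-genome setting at desk scale: four genomes,
    one chromosome per size class plus an unplaced contig (~2.5 Mbp per
    genome), 300 projection templates, 100 unique NAGs.
    """

    seed: int
    genome_names: Tuple[str, ...] = ("Daweishan", "Hu", "Piao", "Wuding")
    chromosomes: Tuple[Tuple[str, int], ...] = (
        ("chr1", 1_200_000),
        ("chr8", 700_000),
        ("chr20", 400_000),
        ("contig_1", 200_000),
    )
    gc_by_class: Tuple[Tuple[str, float], ...] = (
        (MACRO, 0.40),
        (MIDDLE, 0.42),
        (MICRO, 0.53),
        (UNPLACED, 0.45),
    )
    ramp_amplitude: float = 0.10  # subtelomeric G/C elevation at the very end
    ramp_fraction: float = 0.10  # outer fraction of the chromosome it spans
    n_templates: int = 300
    pseudo_template_frac: float = 0.04  # templates that are pseudogene models
    frac_nonsense: float = 0.10  # per (genome, gene-template): planted nonsense
    frac_frameshift: float = 0.10  # planted frameshift
    supported_frac: float = 0.8  # planted mutations with full read support
    coverage_depth: int = 30
    min_cov: int = 10
    cds_codon_range: Tuple[int, int] = (110, 360)
    exon_range: Tuple[int, int] = (2, 5)
    n_nags: int = 100
    nag_class_mix: Tuple[float, float, float] = (0.6, 0.3, 0.1)  # gNAG/oNAG/novel
    p_nag_present: float = 0.7
    p_nag_pseudo: float = 0.1  # remainder absent
    gc_enrichment: bool = True  # NAG chromosome choice biased towards high G/C
    n_decoy_overlap: int = 10
    n_decoy_lncrna: int = 10
    n_decoy_short: int = 10
    n_tissues: int = 10
    expressed_frac: float = 0.9
    genome_groups: Optional[Tuple[Tuple[str, ...], Tuple[str, ...]]] = None


@dataclass
class TruthSet:
    """Planted truth for every emitted object."""

    gene_status: Dict[Tuple[str, str], str] = field(default_factory=dict)
    nag_class: Dict[str, str] = field(default_factory=dict)
    nag_family_size: Dict[str, int] = field(default_factory=dict)
    presence: Optional[pd.DataFrame] = None  # NAG x genome, {1, 0, -1}
    transcript_nag: Dict[str, str] = field(default_factory=dict)
    transcript_verdict: Dict[Tuple[str, str], str] = field(default_factory=dict)
    expressed: Dict[str, bool] = field(default_factory=dict)


@dataclass
class Cohort:
    """Everything a full pipeline run consumes, plus the planted truth."""

    config: SimConfig
    genomes: Dict[str, GenomeAssembly]
    templates: List[TemplateGene]
    template_mappings: Dict[str, List[MappedLocus]]
    coverage: Dict[str, CoverageTrack]
    transcripts: Dict[str, List[MappedTranscript]]
    nag_mappings: Dict[str, List[MappedLocus]]  # keyed per genome; query = transcript id
    hits: List[HitRecord]
    expression: pd.DataFrame
    truth: TruthSet


# ---------------------------------------------------------------------------
# low-level generators


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence with independent per-base G/C probability ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _gc_profile(length: int, base: float, amplitude: float, fraction: float) -> np.ndarray:
    """Per-base G/C probability: flat centre, linear subtelomeric ramps."""
    pos = np.arange(length)
    dist_to_end = np.minimum(pos, length - 1 - pos)
    extent = max(int(length * fraction), 1)
    ramp = np.clip(1.0 - dist_to_end / extent, 0.0, 1.0)
    return np.clip(base + amplitude * ramp, 0.0, 1.0)


def _draw_bases(rng: np.random.Generator, p_gc: np.ndarray) -> str:
    u = rng.random(p_gc.size)
    bases = np.empty(p_gc.size, dtype="<U1")
    half = p_gc / 2
    bases[u < half] = "G"
    bases[(u >= half) & (u < p_gc)] = "C"
    at = u >= p_gc
    bases[at & (u < p_gc + (1 - p_gc) / 2)] = "A"
    bases[at & (u >= p_gc + (1 - p_gc) / 2)] = "T"
    return "".join(bases)


def simulate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GenomeAssembly:
    """One genome with class-dependent G/C and subtelomeric elevation."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gc_map = dict(config.gc_by_class)
    sequences: Dict[str, str] = {}
    for name, length in config.chromosomes:
        base = gc_map[chromosome_class(name)]
        p = _gc_profile(length, base, config.ramp_amplitude, config.ramp_fraction)
        sequences[name] = _draw_bases(rng, p)
    return GenomeAssembly(sequences)


def _random_cds(rng: np.random.Generator, n_codons: int, sec_ordinals: Sequence[int] = ()) -> str:
    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 1)]
    codons[0] = "ATG"
    for k in sec_ordinals:
        codons[k - 1] = "TGA"
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


def _strip_atg(seq: str) -> str:
    """Remove every ATG so the sequence cannot contain an ORF."""
    while "ATG" in seq:
        seq = seq.replace("ATG", "ACG")
    return seq


def plant_g4(seq: str, n_motifs: int, rng: np.random.Generator) -> str:
    """Overwrite ``n_motifs`` random non-overlapping slots with a G4 motif."""
    if n_motifs <= 0 or len(seq) < len(G4_INSERT):
        return seq
    out = bytearray(seq.encode())
    step = len(seq) // max(n_motifs, 1)
    for i in range(n_motifs):
        lo = i * step
        hi = min((i + 1) * step, len(seq)) - len(G4_INSERT)
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        out[pos : pos + len(G4_INSERT)] = G4_INSERT.encode()
    return out.decode()


# ---------------------------------------------------------------------------
# mutation machinery


def _apply_nonsense(cds: str, rng: np.random.Generator) -> str:
    n_codons = len(cds) // 3
    k = int(rng.integers(2, n_codons))  # codon ordinal 2 .. n_codons-1 (1-based)
    return cds[: 3 * (k - 1)] + "TAA" + cds[3 * k :]


def _apply_frameshift(cds: str, rng: np.random.Generator) -> str:
    del_len = int(rng.choice([1, 2, 4, 5]))
    pos = int(rng.integers(3, len(cds) - 6 - del_len))
    return cds[:pos] + cds[pos + del_len :]


def _split_exons(seq: str, n_exons: int, rng: np.random.Generator) -> List[str]:
    if n_exons <= 1 or len(seq) < 2 * n_exons:
        return [seq]
    cuts = sorted(rng.choice(np.arange(1, len(seq)), size=n_exons - 1, replace=False))
    pieces, prev = [], 0
    for c in cuts:
        pieces.append(seq[prev:c])
        prev = int(c)
    pieces.append(seq[prev:])
    return pieces


def _genomic_exons(pieces: List[str], strand: str) -> List[str]:
    """Exon contents in ascending genomic order for a spliced sequence."""
    if strand == "+":
        return pieces
    return [reverse_complement(p) for p in reversed(pieces)]


# ---------------------------------------------------------------------------
# cohort assembly


class _Placer:
    """Sequential non-overlapping placement of loci along chromosomes."""

    def __init__(self, chromosomes: Sequence[Tuple[str, int]], rng: np.random.Generator):
        self.rng = rng
        self.names = [n for n, _ in chromosomes]
        self.lengths = {n: l for n, l in chromosomes}
        self.cursor = {n: 2000 for n in self.names}

    def place(self, total_len: int, weights: Optional[Dict[str, float]] = None) -> Tuple[str, int]:
        candidates = [
            n
            for n in self.names
            if self.cursor[n] + total_len + 2000 < self.lengths[n] - 2000
        ]
        if not candidates:
            raise ValueError("infeasible plan: loci do not fit on the chromosomes")
        if weights:
            w = np.array([weights.get(n, 1.0) for n in candidates])
            name = candidates[int(self.rng.choice(len(candidates), p=w / w.sum()))]
        else:
            name = candidates[int(self.rng.integers(0, len(candidates)))]
        start = self.cursor[name] + int(self.rng.integers(200, 800))
        self.cursor[name] = start + total_len
        return name, start


def _plant_spliced(
    patches: Dict[str, List[Tuple[int, str]]],
    placer: _Placer,
    pieces: List[str],
    strand: str,
    rng: np.random.Generator,
    weights: Optional[Dict[str, float]] = None,
) -> Tuple[str, Tuple[Tuple[int, int], ...]]:
    """Write spliced pieces (transcription order) with random introns; return
    (chromosome, ascending genomic exon intervals)."""
    genomic = _genomic_exons(pieces, strand)
    introns = [int(rng.integers(60, 300)) for _ in range(len(genomic) - 1)]
    total = sum(len(p) for p in genomic) + sum(introns)
    chrom, start = placer.place(total, weights)
    exons: List[Tuple[int, int]] = []
    pos = start
    for i, piece in enumerate(genomic):
        patches[chrom].append((pos, piece))
        exons.append((pos, pos + len(piece)))
        pos += len(piece)
        if i < len(introns):
            pos += introns[i]
    return chrom, tuple(exons)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full multi-genome cohort with planted truth."""
    rng = np.random.default_rng(config.seed)
    gc_map = dict(config.gc_by_class)

    # ---- shared design: templates --------------------------------------
    n_pseudo = max(1, int(round(config.n_templates * config.pseudo_template_frac)))
    templates: List[TemplateGene] = []
    template_cds: Dict[str, str] = {}
    template_exon_counts: Dict[str, int] = {}
    for i in range(config.n_templates):
        source = "pseudogene" if i < n_pseudo else "gene"
        n_codons = int(rng.integers(*config.cds_codon_range))
        sec: Tuple[int, ...] = ()
        if source == "gene" and i % 97 == 5:  # a few selenoprotein templates
            sec = (int(rng.integers(2, n_codons - 1)),)
        tid = f"T{i:04d}"
        templates.append(TemplateGene(tid, source, frozenset(sec)))
        template_cds[tid] = _random_cds(rng, n_codons, sec)
        template_exon_counts[tid] = int(rng.integers(config.exon_range[0], config.exon_range[1] + 1))

    # per-(genome, template) mutation plan
    plan: Dict[Tuple[str, str], Tuple[str, bool]] = {}
    for g in config.genome_names:
        for t in templates:
            if t.source_kind == "pseudogene":
                # half resurrected as supported intact genes, half stay broken
                resurrected = rng.random() < 0.5
                plan[(g, t.id)] = ("none", True) if resurrected else ("frameshift", True)
                continue
            u = rng.random()
            if u < config.frac_nonsense:
                mutation = "nonsense"
            elif u < config.frac_nonsense + config.frac_frameshift:
                mutation = "frameshift"
            else:
                mutation = "none"
            supported = bool(rng.random() < config.supported_frac)
            plan[(g, t.id)] = (mutation, supported)

    # ---- shared design: NAGs -------------------------------------------
    nag_ids = [f"NAG{j:04d}" for j in range(config.n_nags)]
    nag_class = {
        nid: [GNAG, ONAG, NOVEL][int(rng.choice(3, p=np.array(config.nag_class_mix)))]
        for nid in nag_ids
    }
    nag_cds = {nid: _random_cds(rng, int(rng.integers(111, 260))) for nid in nag_ids}
    nag_utr5 = {nid: _strip_atg(random_sequence(rng, int(rng.integers(50, 150)), 0.5)) for nid in nag_ids}
    nag_utr3 = {nid: _strip_atg(random_sequence(rng, int(rng.integers(50, 150)), 0.5)) for nid in nag_ids}

    home = {nid: config.genome_names[int(rng.integers(0, len(config.genome_names)))] for nid in nag_ids}
    presence = pd.DataFrame(0, index=nag_ids, columns=list(config.genome_names), dtype=np.int8)
    if config.genome_groups is not None:
        group_a, group_b = config.genome_groups
        nag_group = {nid: ("A" if rng.random() < 0.5 else "B") for nid in nag_ids}
    for nid in nag_ids:
        for g in config.genome_names:
            if config.genome_groups is not None:
                own = g in (group_a if nag_group[nid] == "A" else group_b)
                p_present = 0.95 if own else 0.05
                u = rng.random()
                code = 1 if u < p_present else (0 if rng.random() < 0.7 else -1)
            else:
                u = rng.random()
                if u < config.p_nag_present:
                    code = 1
                elif u < config.p_nag_present + config.p_nag_pseudo:
                    code = -1
                else:
                    code = 0
            presence.loc[nid, g] = code
        if not (presence.loc[nid] == 1).any():
            presence.loc[nid, home[nid]] = 1

    # hit tables keyed later by transcript id; design per unique NAG first
    nag_hits: Dict[str, List[Tuple[str, str]]] = {}
    for nid in nag_ids:
        rows: List[Tuple[str, str]] = []
        cls = nag_class[nid]
        if cls == GNAG:
            for _ in range(1 + int(rng.poisson(4))):
                rows.append(("Gallus gallus", f"breed_{int(rng.integers(1, 20))}"))
            for _ in range(int(rng.poisson(1))):
                rows.append((_OTHER_SPECIES[int(rng.integers(0, len(_OTHER_SPECIES)))], ""))
        elif cls == ONAG:
            for _ in range(1 + int(rng.poisson(3))):
                rows.append((_OTHER_SPECIES[int(rng.integers(0, len(_OTHER_SPECIES)))], ""))
        nag_hits[nid] = rows

    # ---- per-genome realization ----------------------------------------
    truth = TruthSet()
    truth.nag_class = dict(nag_class)
    truth.presence = presence
    genomes: Dict[str, GenomeAssembly] = {}
    template_mappings: Dict[str, List[MappedLocus]] = {}
    nag_mappings: Dict[str, List[MappedLocus]] = {g: [] for g in config.genome_names}
    coverage: Dict[str, CoverageTrack] = {}
    transcripts: Dict[str, List[MappedTranscript]] = {}
    nag_weights = (
        {name: float(np.exp(8.0 * gc_map[chromosome_class(name)])) for name, _ in config.chromosomes}
        if config.gc_enrichment
        else None
    )
    nag_transcript_ids: Dict[str, List[str]] = {nid: [] for nid in nag_ids}
    nag_loci: Dict[Tuple[str, str], Tuple[str, Tuple[Tuple[int, int], ...]]] = {}

    for g in config.genome_names:
        background = simulate_genome(config, rng)
        patches: Dict[str, List[Tuple[int, str]]] = {n: [] for n, _ in config.chromosomes}
        placer = _Placer(config.chromosomes, rng)
        mappings: List[MappedLocus] = []
        cov_spans: List[Tuple[str, int, int]] = []  # fully covered spans
        cov_holes: List[Tuple[str, int]] = []  # one sub-threshold base each
        genome_transcripts: List[MappedTranscript] = []

        # template orthologs
        for t in templates:
            mutation, supported = plan[(g, t.id)]
            cds = template_cds[t.id]
            if mutation == "nonsense":
                cds = _apply_nonsense(cds, rng)
            elif mutation == "frameshift":
                cds = _apply_frameshift(cds, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            pieces = _split_exons(cds, template_exon_counts[t.id], rng)
            chrom, exons = _plant_spliced(patches, placer, pieces, strand, rng)
            mappings.append(MappedLocus(t.id, chrom, exons, strand, identity=1.0, isoform_id="i1"))
            cov_spans.append((chrom, exons[0][0] - 50, exons[-1][1] + 50))
            if mutation != "none" and not supported:
                hole = int(rng.integers(exons[0][0], exons[0][1]))
                cov_holes.append((chrom, hole))
            # truth status
            if t.source_kind == "pseudogene":
                status = GENE_FROM_PSEUDO if mutation == "none" else PSEUDOGENE
            elif mutation == "none":
                status = INTACT_GENE
            elif supported:
                status = PSEUDOGENE
            else:
                status = PARTIAL_GENE
            truth.gene_status[(g, t.id)] = status

        # NAG loci and transcripts
        for nid in nag_ids:
            code = int(presence.loc[nid, g])
            if code == 0:
                continue
            cds = nag_cds[nid]
            if code == -1:
                cds = _apply_frameshift(cds, rng) if rng.random() < 0.5 else _apply_nonsense(cds, rng)
            spliced = nag_utr5[nid] + cds + nag_utr3[nid]
            n_exons = int(rng.integers(1, 4))
            pieces = _split_exons(spliced, n_exons, rng)
            chrom, exons = _plant_spliced(patches, placer, pieces, "+", rng, nag_weights)
            cov_spans.append((chrom, exons[0][0] - 50, exons[-1][1] + 50))
            # CDS-only genomic intervals (transcript is on +, exons ascending)
            t_cds_start, t_cds_end = len(nag_utr5[nid]), len(nag_utr5[nid]) + len(cds)
            cds_exons: List[Tuple[int, int]] = []
            offset = 0
            for s, e in exons:
                ex_len = e - s
                lo = max(t_cds_start, offset)
                hi = min(t_cds_end, offset + ex_len)
                if hi > lo:
                    cds_exons.append((s + (lo - offset), s + (hi - offset)))
                offset += ex_len
            tid = f"{nid}|{g}"
            nag_loci[(nid, g)] = (chrom, tuple(cds_exons))
            if code == 1:
                genome_transcripts.append(MappedTranscript(tid, chrom, exons, "+", spliced))
                truth.transcript_nag[tid] = nid
                truth.transcript_verdict[(g, tid)] = CODING_NAG
                nag_transcript_ids[nid].append(tid)

        # decoy transcripts
        for k in range(config.n_decoy_lncrna):
            seq = _strip_atg(random_sequence(rng, int(rng.integers(1100, 2000)), 0.5))
            chrom, exons = _plant_spliced(patches, placer, [seq], "+", rng)
            tid = f"lnc{k}|{g}"
            genome_transcripts.append(MappedTranscript(tid, chrom, exons, "+", seq))
            truth.transcript_verdict[(g, tid)] = LNCRNA
        for k in range(config.n_decoy_short):
            seq = _strip_atg(random_sequence(rng, int(rng.integers(400, 900)), 0.5))
            chrom, exons = _plant_spliced(patches, placer, [seq], "+", rng)
            tid = f"short{k}|{g}"
            genome_transcripts.append(MappedTranscript(tid, chrom, exons, "+", seq))
            truth.transcript_verdict[(g, tid)] = UNCLASSIFIED

        # apply patches to the background, then carve overlap decoys out of
        # planted template loci so they overlap homology annotations
        chrom_arrays = {n: bytearray(background[n].encode()) for n, _ in config.chromosomes}
        for n, plist in patches.items():
            arr = chrom_arrays[n]
            for pos, piece in plist:
                arr[pos : pos + len(piece)] = piece.encode()
        genome = GenomeAssembly({n: chrom_arrays[n].decode() for n, _ in config.chromosomes})
        genomes[g] = genome

        decoy_sources = rng.choice(len(mappings), size=config.n_decoy_overlap, replace=False)
        for k, mi in enumerate(decoy_sources):
            locus = mappings[int(mi)]
            s, e = locus.exons[0]
            seq = genome[locus.seq_id][s:e]
            tid = f"ovl{k}|{g}"
            genome_transcripts.append(MappedTranscript(tid, locus.seq_id, ((s, e),), "+", seq))
            truth.transcript_verdict[(g, tid)] = OVERLAPS_EXISTING

        # coverage track: merge covered spans, punch sub-threshold holes
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e in cov_spans:
            by_chrom.setdefault(chrom, []).append((max(0, s), e))
        holes_by_chrom: Dict[str, List[int]] = {}
        for chrom, pos in cov_holes:
            holes_by_chrom.setdefault(chrom, []).append(pos)
        intervals: Dict[str, List[Tuple[int, int, int]]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            merged: List[Tuple[int, int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            rows: List[Tuple[int, int, int]] = []
            holes = sorted(holes_by_chrom.get(chrom, []))
            for s, e in merged:
                inside = [h for h in holes if s <= h < e]
                pos = s
                for h in inside:
                    if h > pos:
                        rows.append((pos, h, config.coverage_depth))
                    rows.append((h, h + 1, config.min_cov - 1))
                    pos = h + 1
                if pos < e:
                    rows.append((pos, e, config.coverage_depth))
            intervals[chrom] = rows
        coverage[g] = CoverageTrack(intervals)
        template_mappings[g] = mappings
        transcripts[g] = genome_transcripts

    # cross-mappings keyed by candidate transcript id: each emitted NAG
    # transcript maps onto every genome where its NAG has a planted locus
    for nid in nag_ids:
        for g in config.genome_names:
            locus = nag_loci.get((nid, g))
            if locus is None:
                continue
            chrom, cds_exons = locus
            for tid in nag_transcript_ids[nid]:
                nag_mappings[g].append(
                    MappedLocus(tid, chrom, cds_exons, "+", identity=1.0, isoform_id="i1")
                )

    # hit table rows per emitted NAG transcript id
    hits: List[HitRecord] = []
    for nid in nag_ids:
        truth.nag_family_size[nid] = len(nag_hits[nid])
        for tid in nag_transcript_ids[nid]:
            for taxon, tag in nag_hits[nid]:
                hits.append(HitRecord(tid, taxon, tag, identity=float(rng.uniform(0.9, 1.0))))

    # expression matrix over template + NAG ids
    tissues = [f"tissue_{k + 1}" for k in range(config.n_tissues)]
    gene_rows = [t.id for t in templates] + nag_ids
    values = np.zeros((len(gene_rows), config.n_tissues))
    for i, gene in enumerate(gene_rows):
        expressed = bool(rng.random() < config.expressed_frac)
        truth.expressed[gene] = expressed
        if expressed:
            k = int(rng.integers(1, 4))
            cols = rng.choice(config.n_tissues, size=k, replace=False)
            values[i, cols] = rng.lognormal(2.0, 1.0, size=k)
    expression = pd.DataFrame(values, index=gene_rows, columns=tissues)

    return Cohort(
        config=config,
        genomes=genomes,
        templates=templates,
        template_mappings=template_mappings,
        coverage=coverage,
        transcripts=transcripts,
        nag_mappings=nag_mappings,
        hits=hits,
        expression=expression,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# light-weight generators for the context statistics


def simulate_window_stats(
    n_windows: int,
    rng: np.random.Generator,
    enrichment: bool = True,
    gc_mean: float = 0.45,
    gc_sd: float = 0.05,
    base_rate: float = 2.0,
    slope: float = 20.0,
) -> List[WindowStat]:
    """Window-level NAG placement model: G/C per window is Gaussian, NAG
    counts are Poisson with rate increasing in G/C when enrichment is on."""
    gc = np.clip(rng.normal(gc_mean, gc_sd, size=n_windows), 0.25, 0.75)
    if enrichment:
        rate = base_rate * np.exp(slope * (gc - gc_mean))
    else:
        rate = np.full(n_windows, base_rate)
    counts = rng.poisson(rate)
    return [
        WindowStat("chrSim", i * 1_000_000, (i + 1) * 1_000_000, float(gc[i]), int(counts[i]), 0)
        for i in range(n_windows)
    ]


def simulate_gene_context(
    n_genes: int,
    rng: np.random.Generator,
    body_len: int = 1500,
    flank_len: int = 5000,
    base_gc: float = 0.42,
    nag_flank_gc: float = 0.48,
    g4_existing_per_kb: float = 0.05,
    g4_nag_body_per_kb: float = 1.0,
    g4_nag_flank_per_kb: float = 1.0,
) -> Dict[str, List[str]]:
    """Gene-body and flank sequences for NAGs versus existing genes.

    NAG bodies carry planted G4 enrichment; NAG flanks carry both elevated
    G/C and planted G4s, emulating the sequencing-refractory neighbourhoods
    the context comparisons are designed to detect.
    """
    out: Dict[str, List[str]] = {
        "nag_body": [],
        "nag_flank": [],
        "existing_body": [],
        "existing_flank": [],
    }
    for _ in range(n_genes):
        body = random_sequence(rng, body_len, base_gc)
        out["existing_body"].append(
            plant_g4(body, int(rng.poisson(g4_existing_per_kb * body_len / 1000)), rng)
        )
        flank = random_sequence(rng, flank_len, base_gc)
        out["existing_flank"].append(
            plant_g4(flank, int(rng.poisson(g4_existing_per_kb * flank_len / 1000)), rng)
        )
        nag_body = random_sequence(rng, body_len, base_gc)
        out["nag_body"].append(
            plant_g4(nag_body, int(rng.poisson(g4_nag_body_per_kb * body_len / 1000)), rng)
        )
        nag_flank = random_sequence(rng, flank_len, nag_flank_gc)
        out["nag_flank"].append(
            plant_g4(nag_flank, int(rng.poisson(g4_nag_flank_per_kb * flank_len / 1000)), rng)
        )
    return out


# ---------------------------------------------------------------------------
# file emission


def _mappings_frame(mappings: List[MappedLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "template_id": [m.template_id for m in mappings],
            "isoform_id": [m.isoform_id for m in mappings],
            "seq_id": [m.seq_id for m in mappings],
            "exons": [",".join(f"{s}-{e}" for s, e in m.exons) for m in mappings],
            "strand": [m.strand for m in mappings],
            "identity": [m.identity for m in mappings],
        }
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Emit the cohort as the plain-text formats the pipeline consumes."""
    from .io import write_coverage, write_fasta_dict, write_features, write_genome
    from .io import AnnotationRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": [t.id for t in cohort.templates],
            "source_kind": [t.source_kind for t in cohort.templates],
            "sec_codons": [
                ",".join(str(k) for k in sorted(t.sec_codon_indices))
                for t in cohort.templates
            ],
        }
    ).to_csv(outdir / "templates.tsv", sep="\t", index=False)
    for g, genome in cohort.genomes.items():
        write_genome(genome, outdir / f"{g}.fa")
        _mappings_frame(cohort.template_mappings[g]).to_csv(
            outdir / f"{g}.template_mappings.tsv", sep="\t", index=False
        )
        _mappings_frame(cohort.nag_mappings[g]).to_csv(
            outdir / f"{g}.nag_mappings.tsv", sep="\t", index=False
        )
        track = cohort.coverage[g]
        intervals = {
            seq_id: [
                (int(s), int(e), int(d))
                for s, e, d in zip(
                    track._starts[seq_id], track._ends[seq_id], track._depths[seq_id]
                )
            ]
            for seq_id in track.seq_ids
        }
        write_coverage(intervals, outdir / f"{g}.coverage.bedgraph")
        write_fasta_dict(
            {t.id: t.sequence for t in cohort.transcripts[g]},
            outdir / f"{g}.transcripts.fa",
        )
        exon_records = [
            AnnotationRecord(t.seq_id, "exon", s, e, t.strand, {"Parent": t.id})
            for t in cohort.transcripts[g]
            for s, e in t.exons
        ]
        write_features(exon_records, outdir / f"{g}.transcripts.gff3")
    pd.DataFrame(
        {
            "query": [h.query for h in cohort.hits],
            "taxon": [h.taxon for h in cohort.hits],
            "tag": [h.tag for h in cohort.hits],
            "identity": [h.identity for h in cohort.hits],
        }
    ).to_csv(outdir / "hits.tsv", sep="\t", index=False)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")
    cohort.truth.presence.to_csv(outdir / "truth_presence.tsv", sep="\t")
    pd.DataFrame(
        {
            "genome": [k[0] for k in cohort.truth.gene_status],
            "template_id": [k[1] for k in cohort.truth.gene_status],
            "status": list(cohort.truth.gene_status.values()),
        }
    ).to_csv(outdir / "truth_gene_status.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "nag_id": list(cohort.truth.nag_class),
            "class": list(cohort.truth.nag_class.values()),
            "family_size": [cohort.truth.nag_family_size[n] for n in cohort.truth.nag_class],
        }
    ).to_csv(outdir / "truth_nag_class.tsv", sep="\t", index=False)
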