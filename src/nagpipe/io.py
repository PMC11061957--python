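"""Readers and writers for the plain-text formats the pipeline touches.

Internally every coordinate is 0-based half-open; GFF3 output is 1-based
inclusive. The shift happens in exactly one place per direction
(:func:`read_features` / :func:`write_features`), so it is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("nagpipe")

_VALID_BASES = frozenset("ACGTN")

DEFAULT_CONFIG: Dict[str, object] = {
    "min_coverage": 10,
    "min_orf": 300,
    "lncrna_min_len": 1000,
    "identity_dedup": 0.985,
    "window": 1_000_000,
    "bins": 100,
    "flank": 1_000_000,
    "min_map_identity": 0.0,
    "overlap_stranded": False,
    "overlap_span_level": False,
}


@dataclass
class GenomeAssembly:
    """Named chromosome sequences, upper-cased, alphabet A/C/G/T/N."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"record {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    @property
    def names(self) -> List[str]:
        return list(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class AnnotationRecord:
    """One genomic feature: the carrier type for every annotated span.

    ``start``/``end`` are internal 0-based half-open; they are converted to
    1-based inclusive only on GFF3 output.
    """

    seq_id: str
    kind: str  # gene, CDS, exon, transcript
    start: int
    end: int
    strand: str
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def id(self) -> Optional[str]:
        return self.attributes.get("ID")


class CoverageTrack:
    """Per-base short-read depth, stored as sorted non-overlapping intervals.

    Positions absent from the underlying bedGraph have depth zero; a
    chromosome absent altogether reads as depth zero everywhere (absence of
    evidence, per the read-support rule).
    """

    def __init__(self, intervals: Mapping[str, List[Tuple[int, int, int]]]):
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._depths: Dict[str, np.ndarray] = {}
        for seq_id, ivs in intervals.items():
            ivs = sorted(ivs)
            prev_end = -1
            for s, e, d in ivs:
                if d < 0:
                    raise ValueError(f"negative depth {d} on {seq_id}")
                if s < prev_end:
                    raise ValueError(f"overlapping bedGraph intervals on {seq_id}")
                prev_end = e
            self._starts[seq_id] = np.array([s for s, _, _ in ivs], dtype=np.int64)
            self._ends[seq_id] = np.array([e for _, e, _ in ivs], dtype=np.int64)
            self._depths[seq_id] = np.array([d for _, _, d in ivs], dtype=np.int64)

    @property
    def seq_ids(self) -> List[str]:
        return list(self._starts)

    def depths(self, seq_id: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end); zeros where no interval covers."""
        out = np.zeros(end - start, dtype=np.int64)
        if seq_id not in self._starts or end <= start:
            return out
        starts, ends, depths = (
            self._starts[seq_id],
            self._ends[seq_id],
            self._depths[seq_id],
        )
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if s < e:
                out[s - start : e - start] = depths[i]
        return out

    def min_depth(self, seq_id: str, start: int, end: int) -> int:
        if end <= start:
            raise ValueError("empty interval")
        d = self.depths(seq_id, start, end)
        return int(d.min())


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | Path) -> GenomeAssembly:
    """Read a genome FASTA into a :class:`GenomeAssembly`.

    Sequences are upper-cased; duplicate record names and non-IUPAC
    characters are hard errors; an empty file is an error.
    """
    sequences: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate record name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no records in {path}")
    return GenomeAssembly(sequences)


def write_genome(genome: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta_dict(path: str | Path) -> Dict[str, str]:
    """Plain id -> sequence mapping (CDS/transcript FASTA)."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate record name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no records in {path}")
    return out


def write_fasta_dict(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


def _format_attributes(attrs: Mapping[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_features(path: str | Path) -> List[AnnotationRecord]:
    """Read a 9-column GFF3 file; coordinates become 0-based half-open.

    ``##`` pragmas and comment lines are tolerated. ``end < start`` is a hard
    error reported with its line number.
    """
    records: List[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            seq_id, _source, kind, start_s, end_s, _score, strand, _phase, attrs = fields
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            records.append(
                AnnotationRecord(
                    seq_id=seq_id,
                    kind=kind,
                    start=start - 1,  # the single 1-based -> 0-based shift
                    end=end,
                    strand=strand if strand in ("+", "-") else "+",
                    attributes=_parse_attributes(attrs),
                )
            )
    return records


def write_features(
    records: Iterable[AnnotationRecord], path: str | Path, source: str = "nagpipe"
) -> None:
    """Write GFF3; the single 0-based -> 1-based inclusive conversion point."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.seq_id,
                        source,
                        rec.kind,
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        _format_attributes(rec.attributes),
                    ]
                )
                + "\n"
            )


def group_cds_by_parent(
    records: Iterable[AnnotationRecord],
) -> Dict[str, List[AnnotationRecord]]:
    """Group CDS/exon records by their Parent attribute, preserving order."""
    groups: Dict[str, List[AnnotationRecord]] = {}
    for rec in records:
        parent = rec.attributes.get("Parent")
        if parent is None:
            continue
        groups.setdefault(parent, []).append(rec)
    return groups


# ---------------------------------------------------------------------------
# bedGraph


def read_coverage(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a coverage track."""
    intervals: Dict[str, List[Tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            seq_id, start_s, end_s, depth_s = fields
            depth = int(depth_s)
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {depth}")
            intervals.setdefault(seq_id, []).append((int(start_s), int(end_s), depth))
    return CoverageTrack(intervals)


def write_coverage(
    intervals: Mapping[str, List[Tuple[int, int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for seq_id in intervals:
            for s, e, d in sorted(intervals[seq_id]):
                fh.write(f"{seq_id}\t{s}\t{e}\t{d}\n")


# ---------------------------------------------------------------------------
# flat config


def read_config(path: str | Path) -> Dict[str, object]:
    """Flat ``key = value`` text config; unknown keys pass through as strings."""
    cfg = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            default = DEFAULT_CONFIG.get(key)
            if isinstance(default, bool):
                cfg[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                cfg[key] = int(value)
            elif isinstance(default, float):
                cfg[key] = float(value)
            else:
                cfg[key] = value
    return cfg


def write_config(cfg: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")


# ---------------------------------------------------------------------------
# report helpers


def percent(numerator: float, denominator: float, decimals: int = 1) -> str:
    """Format a count ratio as a percentage string, half-up rounding.

    This is the rule every summary table uses: ``percent(1277, 1420)`` →
    ``"89.9"``, ``percent(39, 42, 2)`` → ``"92.86"``.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total")
    value = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return str(value.quantize(quantum, rounding=ROUND_HALF_UP))


def log_stage(stage: str, n_in: int, n_out: int, **extra: object) -> None:
    """Record in/out counts for a pipeline stage (summary tables come from these)."""
    detail = "".join(f" {k}={v}" for k, v in extra.items())
    logger.info("%s: in=%d out=%d%s", stage, n_in, n_out, detail)
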