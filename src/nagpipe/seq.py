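"""Primitive sequence computations shared by every pipeline stage.

G/C content, ORF discovery, translation with selenoprotein recoding,
canonical G-quadruplex scanning and pairwise identity. All coordinates are
0-based half-open on the given string; ambiguous bases (``N``) never count
towards G/C, never extend a G-run and never match inside a quadruplex loop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Set

import edlib

__all__ = [
    "Orf",
    "G4Motif",
    "InternalStopError",
    "reverse_complement",
    "gc_content",
    "find_orfs",
    "translate",
    "scan_g4",
    "g4_frequency",
    "pairwise_identity",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# four runs of >=3 G separated by 1-7 nt loops; N is excluded everywhere
G4_PATTERN = re.compile(r"G{3,}(?:[ACGT]{1,7}G{3,}){3}")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class InternalStopError(ValueError):
    """A stop codon occurred before the final codon of a CDS.

    ``codon_ordinal`` is the 1-based ordinal of the offending codon.
    """

    def __init__(self, codon_ordinal: int):
        self.codon_ordinal = codon_ordinal
        super().__init__(f"internal stop codon at codon {codon_ordinal}")


@dataclass(frozen=True, order=True)
class Orf:
    """An ATG-initiated, stop-terminated open reading frame on a transcript.

    ``start``/``end`` are 0-based half-open positions on the sense strand of
    the transcript; the span includes the stop codon, so the length is always
    a multiple of three and at least six.
    """

    start: int
    end: int
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class G4Motif:
    """A canonical quadruplex match: interval on the forward sequence, strand."""

    start: int
    end: int
    strand: str


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T), ignoring N.

    Raises ``ValueError`` if the sequence is empty or all-N: the quantity is
    undefined there and must not silently read as zero.
    """
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("gc_content undefined for empty or all-N sequence")
    return gc / denom


def find_orfs(seq: str, min_len: int = 300) -> List[Orf]:
    """All ORFs of length >= ``min_len`` nt on the sense strand.

    An ORF runs from an ATG to the first in-frame stop, stop included, with no
    internal stop. All three frames are scanned. Results are sorted by length
    descending, ties by leftmost start.
    """
    if min_len < 6 or min_len % 3 != 0:
        raise ValueError("min_len must be >= 6 and a multiple of 3")
    seq = seq.upper()
    n = len(seq)
    orfs: List[Orf] = []
    for frame in range(3):
        pending: List[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == START_CODON:
                pending.append(i)
            if codon in STOP_CODONS:
                for s in pending:
                    if i + 3 - s >= min_len:
                        orfs.append(Orf(s, i + 3, frame))
                pending = []
    orfs.sort(key=lambda o: (-o.length, o.start))
    return orfs


def translate(cds: str, sec_codon_indices: Iterable[int] = ()) -> str:
    """Translate a CDS with the standard code, dropping a terminal stop.

    ``sec_codon_indices`` are 1-based codon ordinals at which a TGA codon is
    read as selenocysteine (``U``) instead of stop. Any other stop codon
    before the final codon raises :class:`InternalStopError` carrying the
    codon ordinal.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    sec: Set[int] = set(sec_codon_indices)
    n_codons = len(cds) // 3
    protein: List[str] = []
    for k in range(n_codons):
        codon = cds[3 * k : 3 * k + 3]
        ordinal = k + 1
        aa = _CODON_TABLE.get(codon, "X")
        if codon == "TGA" and ordinal in sec:
            aa = "U"
        if aa == "*":
            if ordinal == n_codons:
                break  # terminal stop dropped
            raise InternalStopError(ordinal)
        protein.append(aa)
    return "".join(protein)


def scan_g4(seq: str) -> List[G4Motif]:
    """Non-overlapping leftmost-greedy canonical G4 motifs on both strands.

    Minus-strand motifs are found by scanning the reverse complement and
    mapping the intervals back onto the forward coordinate system. Results
    are sorted by start position.
    """
    seq = seq.upper()
    motifs = [G4Motif(m.start(), m.end(), "+") for m in G4_PATTERN.finditer(seq)]
    n = len(seq)
    rc = reverse_complement(seq)
    motifs.extend(
        G4Motif(n - m.end(), n - m.start(), "-") for m in G4_PATTERN.finditer(rc)
    )
    motifs.sort(key=lambda g: (g.start, g.strand))
    return motifs


def g4_frequency(seq: str) -> float:
    """Quadruplex motifs per kbp of scanned sequence (both strands)."""
    if not seq:
        raise ValueError("empty sequence")
    return len(scan_g4(seq)) / (len(seq) / 1000.0)


def pairwise_identity(a: str, b: str) -> float:
    """Global identity between two sequences under unit edit costs.

    Defined as ``1 - d(a, b) / max(|a|, |b|)`` where ``d`` is the Levenshtein
    distance (substitutions and single-base gaps each cost one). Symmetric,
    lies in [0, 1], and equals 1 exactly when the sequences are identical.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))
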