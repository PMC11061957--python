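"""Genomic-context statistics around NAGs.

Chromosome size classes of the chicken karyotype, 1-Mbp G/C windows versus
NAG density with Pearson correlation, 100-bin per-chromosome-group
profiles (the subtelomere view), flanking-region extraction, and
two-sample comparisons (Wilcoxon rank-sum by default, Welch t optional).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io import AnnotationRecord, GenomeAssembly
from .seq import gc_content

__all__ = [
    "MACRO",
    "MIDDLE",
    "MICRO",
    "UNPLACED",
    "WindowStat",
    "BinProfile",
    "CorrelationResult",
    "CompareResult",
    "chromosome_class",
    "window_stats",
    "density_gc_correlation",
    "percent_bin_profile",
    "flank_intervals",
    "compare_groups",
]

MACRO = "macro"
MIDDLE = "middle"
MICRO = "micro"
UNPLACED = "unplaced"

_CHR_RE = re.compile(r"^chr(\d+|[ZW])$", re.IGNORECASE)


@dataclass(frozen=True)
class WindowStat:
    seq_id: str
    start: int
    end: int
    gc: float  # nan when the window is all-N
    nag_count: int
    gene_count: int


@dataclass
class BinProfile:
    group: str
    gc: np.ndarray  # per-bin mean G/C across chromosomes
    nag_density: np.ndarray  # per-bin mean NAGs per Mbp
    n_chromosomes: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


@dataclass(frozen=True)
class CompareResult:
    statistic: float
    pvalue: float
    test: str
    degenerate: bool = False


def chromosome_class(name: str) -> str:
    """Size class of a chicken chromosome name.

    chr1–chr5 and chrZ are macro-chromosomes, chr6–chr13 and chrW middle,
    chr14–chr39 micro; anything else (unplaced contigs, scaffolds, higher
    numbers) is unplaced. The ``chr`` prefix is case-insensitive.
    """
    m = _CHR_RE.match(name.strip())
    if not m:
        return UNPLACED
    token = m.group(1).upper()
    if token == "Z":
        return MACRO
    if token == "W":
        return MIDDLE
    num = int(token)
    if 1 <= num <= 5:
        return MACRO
    if 6 <= num <= 13:
        return MIDDLE
    if 14 <= num <= 39:
        return MICRO
    return UNPLACED


def _starts_by_chrom(features: Iterable[AnnotationRecord]) -> Dict[str, List[int]]:
    out: Dict[str, List[int]] = {}
    for f in features:
        out.setdefault(f.seq_id, []).append(f.start)
    return out


def window_stats(
    genome: GenomeAssembly,
    annotations: Iterable[AnnotationRecord] = (),
    nags: Iterable[AnnotationRecord] = (),
    window: int = 1_000_000,
) -> List[WindowStat]:
    """Tile each chromosome into fixed windows (the last one shorter) and
    record per-window G/C, NAG count and existing-gene count.

    A feature is counted in the window containing its start, so window
    counts sum exactly to the number of features placed on the genome.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    gene_starts = _starts_by_chrom(annotations)
    nag_starts = _starts_by_chrom(nags)
    out: List[WindowStat] = []
    for name in genome.names:
        seq = genome[name]
        length = len(seq)
        genes = np.sort(np.array(gene_starts.get(name, []), dtype=np.int64))
        nag_pos = np.sort(np.array(nag_starts.get(name, []), dtype=np.int64))
        for w_start in range(0, length, window):
            w_end = min(w_start + window, length)
            try:
                gc = gc_content(seq[w_start:w_end])
            except ValueError:
                gc = math.nan
            n_nag = int(
                np.searchsorted(nag_pos, w_end, "left")
                - np.searchsorted(nag_pos, w_start, "left")
            )
            n_gene = int(
                np.searchsorted(genes, w_end, "left")
                - np.searchsorted(genes, w_start, "left")
            )
            out.append(WindowStat(name, w_start, w_end, gc, n_nag, n_gene))
    return out


def density_gc_correlation(windows: Sequence[WindowStat]) -> CorrelationResult:
    """Pearson correlation between window G/C and window NAG count."""
    pairs = [(w.gc, w.nag_count) for w in windows if not math.isnan(w.gc)]
    if len(pairs) < 3:
        raise ValueError("need >= 3 windows with defined G/C")
    gc = np.array([p[0] for p in pairs])
    counts = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(gc) == 0 or np.ptp(counts) == 0:
        raise ValueError("degenerate correlation: zero variance")
    r, _ = stats.pearsonr(gc, counts)
    return CorrelationResult(float(r), len(pairs))


def percent_bin_profile(
    genomes: Sequence[GenomeAssembly],
    nags: Iterable[AnnotationRecord],
    group: str,
    bins: int = 100,
) -> BinProfile:
    """Average G/C and NAG density over ``bins`` equal portions of every
    chromosome of a size class, across all genomes.

    Each chromosome is cut into ``bins`` equal-length portions (the last
    absorbs the remainder); NAG counts are normalized to per-Mbp densities
    before averaging so chromosomes of different lengths are comparable.
    """
    nag_starts = _starts_by_chrom(nags)
    gc_sum = np.zeros(bins)
    gc_n = np.zeros(bins)
    dens_sum = np.zeros(bins)
    n_chroms = 0
    for genome in genomes:
        for name in genome.names:
            if chromosome_class(name) != group:
                continue
            seq = genome[name]
            length = len(seq)
            if length < bins:
                raise ValueError(
                    f"chromosome {name} (length {length}) shorter than {bins} bins"
                )
            n_chroms += 1
            size = length // bins
            starts = np.sort(np.array(nag_starts.get(name, []), dtype=np.int64))
            for b in range(bins):
                s = b * size
                e = (b + 1) * size if b < bins - 1 else length
                try:
                    gc_sum[b] += gc_content(seq[s:e])
                    gc_n[b] += 1
                except ValueError:
                    pass
                count = int(
                    np.searchsorted(starts, e, "left")
                    - np.searchsorted(starts, s, "left")
                )
                dens_sum[b] += count / ((e - s) / 1e6)
    if n_chroms == 0:
        raise ValueError(f"no chromosome of class {group!r}")
    with np.errstate(invalid="ignore"):
        gc_mean = np.where(gc_n > 0, gc_sum / np.maximum(gc_n, 1), np.nan)
    return BinProfile(group, gc_mean, dens_sum / n_chroms, n_chroms)


def flank_intervals(
    start: int, end: int, chrom_len: int, flank: int = 1_000_000
) -> List[Tuple[int, int]]:
    """Up to two flanking intervals of width ``flank`` around a gene span,
    clipped to the chromosome; empty intervals are dropped."""
    if not (0 <= start <= end <= chrom_len):
        raise ValueError("gene span outside chromosome")
    out = []
    left = (max(0, start - flank), start)
    right = (end, min(chrom_len, end + flank))
    for s, e in (left, right):
        if e > s:
            out.append((s, e))
    return out


def compare_groups(
    a: Sequence[float], b: Sequence[float], test: str = "ranksum"
) -> CompareResult:
    """Two-sided two-sample comparison: Wilcoxon rank-sum or Welch t.

    The rank-sum test uses the exact null distribution at small sample
    sizes without ties (scipy's Mann–Whitney machinery), the normal
    approximation otherwise. Two identical all-equal groups have nothing to
    compare; p is 1 by convention and the result is flagged degenerate.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if np.ptp(a_arr) == 0 and np.ptp(b_arr) == 0 and a_arr[0] == b_arr[0]:
        return CompareResult(0.0, 1.0, test, degenerate=True)
    if test == "ranksum":
        res = stats.mannwhitneyu(a_arr, b_arr, alternative="two-sided", method="auto")
        return CompareResult(float(res.statistic), float(res.pvalue), test)
    if test == "t":
        res = stats.ttest_ind(a_arr, b_arr, equal_var=False)
        return CompareResult(float(res.statistic), float(res.pvalue), test)
    raise ValueError(f"unknown test {test!r}")
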