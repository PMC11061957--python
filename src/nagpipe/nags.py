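"""NAG consolidation, triage and presence/absence clustering.

Per-genome NAG candidates are collapsed into a non-redundant set (greedy
clustering at >98.5% identity), triaged by the taxonomy of their database
hits — gNAG (hits in other chicken breeds), oNAG (hits only in other
species) or novel (no hits) — sized by hit count, and cross-tabulated into
a NAG × genome matrix over {1, 0, −1} (present / absent / pseudogenized)
that is clustered two-way with Ward linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .io import log_stage
from .seq import pairwise_identity

__all__ = [
    "HitRecord",
    "NagRecord",
    "Cluster",
    "BiclusterResult",
    "GNAG",
    "ONAG",
    "NOVEL",
    "deduplicate",
    "classify_nag",
    "family_size",
    "build_presence_matrix",
    "bicluster",
]

GNAG = "gNAG"
ONAG = "oNAG"
NOVEL = "novel"

CHICKEN_TAXON = "Gallus gallus"

PRESENT = 1
ABSENT = 0
PSEUDOGENIZED = -1

_STATUS_CODE = {
    "intact": PRESENT,
    "intact_gene": PRESENT,
    "gene_from_pseudogene": PRESENT,
    "partially_supported_gene": PRESENT,
    "present": PRESENT,
    "absent": ABSENT,
    "unmapped": ABSENT,
    "pseudogene": PSEUDOGENIZED,
    "pseudogenized": PSEUDOGENIZED,
}


@dataclass(frozen=True)
class HitRecord:
    """One database hit of a NAG query: subject taxon plus assembly tag."""

    query: str
    taxon: str
    tag: str = ""
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError("hit taxon must be non-empty")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")


@dataclass
class Cluster:
    representative: str
    members: List[str]


@dataclass
class NagRecord:
    id: str
    sequence: str
    members: List[str] = field(default_factory=list)
    nag_class: str = NOVEL
    family_size: int = 0


@dataclass
class BiclusterResult:
    row_order: List[str]
    col_order: List[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def deduplicate(
    sequences: Mapping[str, str], threshold: float = 0.985
) -> List[Cluster]:
    """Greedy redundancy removal at identity strictly above ``threshold``.

    Sequences are visited longest-first (ties by id); each joins the first
    representative it exceeds the threshold with, otherwise founds a new
    cluster. Representatives are therefore the longest members, and two
    sequences at exactly the threshold stay separate ("> 98.5%" is strict).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: List[Cluster] = []
    for name in order:
        seq = sequences[name]
        for cluster in clusters:
            if pairwise_identity(seq, sequences[cluster.representative]) > threshold:
                cluster.members.append(name)
                break
        else:
            clusters.append(Cluster(representative=name, members=[name]))
    log_stage("deduplicate", len(sequences), len(clusters))
    return clusters


def classify_nag(
    hits: Sequence[HitRecord], reference_tags: Set[str] = frozenset()
) -> str:
    """Triage a NAG by its hit taxonomy.

    gNAG if any hit is *Gallus gallus* outside the reference assemblies
    (``reference_tags``), else oNAG if any other-species hit exists, else
    novel. Invariant to hit order.
    """
    has_other_species = False
    for hit in hits:
        if hit.taxon == CHICKEN_TAXON:
            if hit.tag not in reference_tags:
                return GNAG
        else:
            has_other_species = True
    return ONAG if has_other_species else NOVEL


def family_size(hits: Sequence[HitRecord]) -> int:
    """Estimated family size: the number of database hits of the query."""
    return len(hits)


def build_presence_matrix(
    calls: Iterable[Tuple[str, str, str]],
    nag_ids: Optional[Sequence[str]] = None,
    genome_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """NAG × genome matrix over {1, 0, −1}.

    ``calls`` yields (nag_id, genome_id, status) triples; intact-class
    statuses code 1, pseudogene-class −1, and pairs never mentioned (or
    explicitly absent/unmapped) code 0. Duplicate pairs are a hard error.
    """
    seen: Set[Tuple[str, str]] = set()
    entries: Dict[Tuple[str, str], int] = {}
    rows: List[str] = list(nag_ids) if nag_ids is not None else []
    cols: List[str] = list(genome_ids) if genome_ids is not None else []
    for nag_id, genome_id, status in calls:
        key = (nag_id, genome_id)
        if key in seen:
            raise ValueError(f"duplicate call for NAG {nag_id!r} in {genome_id!r}")
        seen.add(key)
        if status not in _STATUS_CODE:
            raise ValueError(f"unknown status {status!r}")
        entries[key] = _STATUS_CODE[status]
        if nag_ids is None and nag_id not in rows:
            rows.append(nag_id)
        if genome_ids is None and genome_id not in cols:
            cols.append(genome_id)
    matrix = pd.DataFrame(ABSENT, index=rows, columns=cols, dtype=np.int8)
    for (nag_id, genome_id), code in entries.items():
        matrix.loc[nag_id, genome_id] = code
    return matrix


def bicluster(
    matrix: pd.DataFrame, method: str = "ward", metric: str = "euclidean"
) -> BiclusterResult:
    """Two-way hierarchical clustering of a presence matrix.

    Rows (NAGs) and columns (genomes) are clustered independently with the
    given linkage on their {−1, 0, 1} vectors; leaf orders and merge trees
    are returned. Deterministic given the inputs; a constant matrix has no
    variation to cluster and is an error.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("bicluster needs at least 2 rows and 2 columns")
    values = matrix.to_numpy(dtype=float)
    if np.all(values == values.flat[0]):
        raise ValueError("no variation to cluster")
    row_linkage = linkage(values, method=method, metric=metric)
    col_linkage = linkage(values.T, method=method, metric=metric)
    row_order = [matrix.index[i] for i in leaves_list(row_linkage)]
    col_order = [matrix.columns[i] for i in leaves_list(col_linkage)]
    return BiclusterResult(row_order, col_order, row_linkage, col_linkage)
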