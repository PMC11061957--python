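"""NAG consolidation, triage, presence matrix and biclustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from nagpipe.nags import (
    GNAG,
    NOVEL,
    ONAG,
    HitRecord,
    bicluster,
    build_presence_matrix,
    classify_nag,
    deduplicate,
    family_size,
)
from nagpipe.seq import pairwise_identity

REF_TAGS = {"GRCg6a", "GRCg7b", "GRCg7w"}


# ---------------------------------------------------------------------------
# deduplicate


def greedy_oracle(sequences, threshold):
    """Independent re-implementation of the longest-first greedy clustering."""
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps, members = [], {}
    for name in order:
        for rep in reps:
            if pairwise_identity(sequences[name], sequences[rep]) > threshold:
                members[rep].append(name)
                break
        else:
            reps.append(name)
            members[name] = [name]
    return [(r, members[r]) for r in reps]


def single_linkage_components(sequences, threshold):
    names = list(sequences)
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in itertools.combinations(names, 2):
        if pairwise_identity(sequences[a], sequences[b]) > threshold:
            parent[find(a)] = find(b)
    return len({find(n) for n in names})


def test_identical_sequences_form_one_cluster():
    clusters = deduplicate({"a": "ACGT" * 50, "b": "ACGT" * 50})
    assert len(clusters) == 1
    assert sorted(clusters[0].members) == ["a", "b"]


def test_dedup_threshold_is_strict():
    base = "A" * 200
    variant = "A" * 197 + "TTT"  # identity exactly 0.985
    assert pairwise_identity(base, variant) == pytest.approx(0.985)
    assert len(deduplicate({"a": base, "b": variant}, 0.985)) == 2
    just_above = "A" * 198 + "TT"  # identity 0.99
    assert len(deduplicate({"a": base, "b": just_above}, 0.985)) == 1


def test_dedup_matches_greedy_oracle_and_single_linkage_bound(rng):
    for _ in range(20):
        n = int(rng.integers(3, 9))
        base = "".join(rng.choice(list("ACGT"), size=120))
        seqs = {}
        for i in range(n):
            s = list(base)
            for _ in range(int(rng.integers(0, 8))):
                s[int(rng.integers(0, len(s)))] = str(rng.choice(list("ACGT")))
            seqs[f"s{i}"] = "".join(s)
        got = deduplicate(seqs, 0.985)
        expected = greedy_oracle(seqs, 0.985)
        assert [(c.representative, c.members) for c in got] == expected
        # greedy can only split a single-linkage component, never merge two
        assert len(got) >= single_linkage_components(seqs, 0.985)


def test_dedup_representative_properties(rng):
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=100)) for i in range(10)}
    clusters = deduplicate(seqs, 0.985)
    reps = [c.representative for c in clusters]
    for a, b in itertools.combinations(reps, 2):
        assert pairwise_identity(seqs[a], seqs[b]) <= 0.985
    for c in clusters:
        for m in c.members:
            if m != c.representative:
                assert pairwise_identity(seqs[m], seqs[c.representative]) > 0.985


# ---------------------------------------------------------------------------
# classify_nag / family_size


def test_classify_by_hit_taxonomy():
    gg = HitRecord("q", "Gallus gallus", "breed_X")
    turkey = HitRecord("q", "Meleagris gallopavo")
    ref_only = HitRecord("q", "Gallus gallus", "GRCg6a")
    assert classify_nag([gg], REF_TAGS) == GNAG
    assert classify_nag([turkey], REF_TAGS) == ONAG
    assert classify_nag([], REF_TAGS) == NOVEL
    assert classify_nag([ref_only], REF_TAGS) == NOVEL  # reference hits ignored
    assert classify_nag([ref_only, turkey], REF_TAGS) == ONAG


def test_classify_invariant_to_hit_order(rng):
    hits = [
        HitRecord("q", "Gallus gallus", "breed_1"),
        HitRecord("q", "Meleagris gallopavo"),
        HitRecord("q", "Anas platyrhynchos"),
    ]
    for perm in itertools.permutations(hits):
        assert classify_nag(list(perm), REF_TAGS) == GNAG


def test_family_size_is_hit_count(rng):
    assert family_size([]) == 0
    multiplicities = {f"q{i}": int(rng.integers(0, 12)) for i in range(20)}
    hits = [
        HitRecord(q, "Gallus gallus", "b") for q, k in multiplicities.items() for _ in range(k)
    ]
    by_query = {}
    for h in hits:
        by_query.setdefault(h.query, []).append(h)
    for q, k in multiplicities.items():
        assert family_size(by_query.get(q, [])) == k


# ---------------------------------------------------------------------------
# presence matrix


def test_presence_matrix_encoding():
    matrix = build_presence_matrix(
        [("n1", "A", "intact"), ("n1", "B", "absent"), ("n1", "C", "pseudogene")],
        genome_ids=["A", "B", "C"],
    )
    assert list(matrix.loc["n1"]) == [1, 0, -1]


def test_presence_matrix_missing_pairs_default_absent():
    matrix = build_presence_matrix(
        [("n1", "A", "intact")], nag_ids=["n1", "n2"], genome_ids=["A", "B"]
    )
    assert matrix.loc["n1", "B"] == 0
    assert list(matrix.loc["n2"]) == [0, 0]


def test_presence_matrix_duplicate_pair_is_error():
    with pytest.raises(ValueError, match="duplicate"):
        build_presence_matrix([("n1", "A", "intact"), ("n1", "A", "absent")])


# ---------------------------------------------------------------------------
# bicluster


def block_matrix():
    rows = {}
    for i in range(6):
        rows[f"up{i}"] = [1, 1, 1, 0, 0]
        rows[f"down{i}"] = [-1, -1, -1, 1, 1]
    return pd.DataFrame(rows, index=["gA", "gB", "gC", "gD", "gE"]).T


def test_bicluster_recovers_planted_blocks():
    result = bicluster(block_matrix())
    row_cut = fcluster(result.row_linkage, 2, criterion="maxclust")
    labels = dict(zip(block_matrix().index, row_cut))
    assert len({labels[f"up{i}"] for i in range(6)}) == 1
    assert len({labels[f"down{i}"] for i in range(6)}) == 1
    col_cut = fcluster(result.col_linkage, 2, criterion="maxclust")
    col_labels = dict(zip(block_matrix().columns, col_cut))
    assert col_labels["gA"] == col_labels["gB"] == col_labels["gC"]
    assert col_labels["gD"] == col_labels["gE"]
    assert col_labels["gA"] != col_labels["gD"]


def test_bicluster_invariant_to_row_permutation(rng):
    m = block_matrix()
    shuffled = m.sample(frac=1.0, random_state=3)
    a = bicluster(m)
    b = bicluster(shuffled)
    cut_a = dict(zip(m.index, fcluster(a.row_linkage, 2, criterion="maxclust")))
    cut_b = dict(zip(shuffled.index, fcluster(b.row_linkage, 2, criterion="maxclust")))
    # same partition of row labels either way
    part_a = {frozenset(k for k, v in cut_a.items() if v == c) for c in set(cut_a.values())}
    part_b = {frozenset(k for k, v in cut_b.items() if v == c) for c in set(cut_b.values())}
    assert part_a == part_b


def test_bicluster_constant_matrix_is_error():
    flat = pd.DataFrame(np.ones((4, 3)), index=list("abcd"), columns=list("xyz"))
    with pytest.raises(ValueError, match="no variation"):
        bicluster(flat)


def test_bicluster_matches_stepwise_agglomerative_trace():
    """Ward merges on a small matrix equal a hand-rolled agglomerative run."""
    base = np.array(
        [[1, 1, 0, 0], [1, 1, 0, -1], [-1, 0, 1, 1], [-1, -1, 1, 1], [0, 0, 1, 1], [1, 1, 1, 1]],
        dtype=float,
    )
    # deterministic jitter so no two pairwise distances tie
    base += np.random.default_rng(0).normal(0, 0.01, base.shape)
    from scipy.spatial.distance import pdist

    assert len(set(np.round(pdist(base), 12))) == 15
    m = pd.DataFrame(base, index=[f"n{i}" for i in range(6)], columns=list("ABCD"))
    result = bicluster(m, method="average")
    # hand agglomeration with average linkage on euclidean distances
    points = {i: [i] for i in range(6)}
    dist = {
        (i, j): float(np.linalg.norm(base[i] - base[j]))
        for i in range(6)
        for j in range(i + 1, 6)
    }

    def cluster_dist(ci, cj):
        return np.mean([dist[tuple(sorted((a, b)))] for a in points[ci] for b in points[cj]])

    merges = []
    active = list(range(6))
    next_id = 6
    while len(active) > 1:
        best = min(
            ((ci, cj) for i, ci in enumerate(active) for cj in active[i + 1 :]),
            key=lambda p: (cluster_dist(*p), p),
        )
        merges.append((set(points[best[0]]), set(points[best[1]])))
        points[next_id] = points[best[0]] + points[best[1]]
        active = [c for c in active if c not in best] + [next_id]
        next_id += 1
    scipy_merges = []
    scipy_points = {i: {i} for i in range(6)}
    for k, (a, b, _, _) in enumerate(result.row_linkage):
        sa, sb = scipy_points[int(a)], scipy_points[int(b)]
        scipy_merges.append((sa, sb))
        scipy_points[6 + k] = sa | sb
    got = [frozenset(frozenset(x) for x in pair) for pair in scipy_merges]
    expected = [frozenset(frozenset(x) for x in pair) for pair in merges]
    assert got == expected
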