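"""Genomic-context statistics: windows, profiles, flanks, comparisons."""

import itertools
import math

import numpy as np
import pytest

from nagpipe.context import (
    MACRO,
    MICRO,
    MIDDLE,
    UNPLACED,
    chromosome_class,
    compare_groups,
    density_gc_correlation,
    flank_intervals,
    percent_bin_profile,
    window_stats,
    WindowStat,
)
from nagpipe.io import AnnotationRecord, GenomeAssembly
from nagpipe.seq import gc_content
from nagpipe.simulate import SimConfig, simulate_genome


def feature(seq_id, start, kind="gene"):
    return AnnotationRecord(seq_id, kind, start, start + 100, "+", {})


# ---------------------------------------------------------------------------
# chromosome classes


@pytest.mark.parametrize(
    "name,expected",
    [
        ("chr1", MACRO),
        ("chr3", MACRO),
        ("chr5", MACRO),
        ("chrZ", MACRO),
        ("chr6", MIDDLE),
        ("chr10", MIDDLE),
        ("chr13", MIDDLE),
        ("chrW", MIDDLE),
        ("chr14", MICRO),
        ("chr20", MICRO),
        ("chr39", MICRO),
        ("chr40", UNPLACED),
        ("contig_517", UNPLACED),
        ("CHRz", MACRO),
    ],
)
def test_chromosome_class_table(name, expected):
    assert chromosome_class(name) == expected


# ---------------------------------------------------------------------------
# window stats


def test_window_tiling_last_window_shorter(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2_500_000))
    genome = GenomeAssembly({"chr1": seq})
    windows = window_stats(genome, window=1_000_000)
    assert [(w.start, w.end) for w in windows] == [
        (0, 1_000_000),
        (1_000_000, 2_000_000),
        (2_000_000, 2_500_000),
    ]
    for w in windows:
        assert w.gc == pytest.approx(gc_content(seq[w.start : w.end]))


def test_feature_counted_in_window_of_its_start():
    genome = GenomeAssembly({"chr1": "ACGT" * 500_000})
    nag = feature("chr1", 999_999)  # spans into window 2
    windows = window_stats(genome, nags=[nag], window=1_000_000)
    assert [w.nag_count for w in windows] == [1, 0]


def test_window_counts_sum_to_total(rng):
    genome = GenomeAssembly({"chr1": "ACGT" * 100_000, "chr2": "ACGT" * 50_000})
    nags = [
        feature(str(rng.choice(["chr1", "chr2"])), int(rng.integers(0, 150_000)))
        for _ in range(200)
    ]
    windows = window_stats(genome, nags=nags, window=37_000)
    assert sum(w.nag_count for w in windows) == len(nags)


def test_length_weighted_window_gc_equals_genome_gc(rng):
    seq = "".join(rng.choice(list("ACGTN"), p=[0.2, 0.3, 0.3, 0.15, 0.05], size=90_000))
    genome = GenomeAssembly({"chr1": seq})
    windows = window_stats(genome, window=7_000)
    num = sum(
        w.gc * len([c for c in seq[w.start : w.end] if c != "N"])
        for w in windows
        if not math.isnan(w.gc)
    )
    den = sum(1 for c in seq if c != "N")
    assert num / den == pytest.approx(gc_content(seq), abs=1e-12)


def test_all_n_window_has_undefined_gc():
    genome = GenomeAssembly({"chr1": "N" * 10 + "ACGT" * 5})
    windows = window_stats(genome, window=10)
    assert math.isnan(windows[0].gc)
    assert not math.isnan(windows[1].gc)


# ---------------------------------------------------------------------------
# correlation


def test_perfectly_linear_counts_give_r_one():
    windows = [
        WindowStat("c", i, i + 1, 0.3 + 0.01 * i, 10 + 2 * i, 0) for i in range(20)
    ]
    assert density_gc_correlation(windows).r == pytest.approx(1.0)


def test_permuted_counts_give_small_r(rng):
    gc = 0.3 + 0.4 * rng.random(2000)
    counts = rng.permutation(np.arange(2000))
    windows = [
        WindowStat("c", i, i + 1, float(gc[i]), int(counts[i]), 0) for i in range(2000)
    ]
    assert abs(density_gc_correlation(windows).r) < 0.08


def test_degenerate_correlation_is_error():
    flat = [WindowStat("c", i, i + 1, 0.4, 5, 0) for i in range(10)]
    with pytest.raises(ValueError, match="degenerate|variance"):
        density_gc_correlation(flat)


# ---------------------------------------------------------------------------
# bin profiles


def test_bin_assignment_and_short_chromosome_error():
    genome = GenomeAssembly({"chr14": "ACGT" * 250})  # 1000 bp
    nag = AnnotationRecord("chr14", "gene", 5, 20, "+", {})
    profile = percent_bin_profile([genome], [nag], MICRO, bins=100)
    assert profile.nag_density[0] > 0
    assert np.count_nonzero(profile.nag_density) == 1
    short = GenomeAssembly({"chr14": "ACGT" * 10})
    with pytest.raises(ValueError, match="shorter"):
        percent_bin_profile([short], [], MICRO, bins=100)


def test_profile_recovers_planted_subtelomeric_ramp():
    config = SimConfig(
        seed=11,
        chromosomes=(("chr2", 1_000_000),),
        ramp_amplitude=0.10,
        ramp_fraction=0.10,
    )
    genome = simulate_genome(config)
    profile = percent_bin_profile([genome], [], MACRO, bins=100)
    central = profile.gc[40:60].mean()
    outer = (profile.gc[0] + profile.gc[-1]) / 2
    # outermost bins span the last 1%: ramp mean there is ~0.95 x amplitude
    assert outer - central == pytest.approx(0.10, abs=0.02)


def test_uniform_genome_profile_is_flat(rng):
    seq = "".join(rng.choice(list("ACGT"), size=500_000))
    genome = GenomeAssembly({"chr7": seq})
    profile = percent_bin_profile([genome], [], MIDDLE, bins=100)
    assert profile.gc.max() - profile.gc.min() < 0.05


# ---------------------------------------------------------------------------
# flanks


def test_flank_clipping_cases():
    assert flank_intervals(0, 500, 10_000, flank=1000) == [(500, 1500)]
    assert flank_intervals(5000, 6000, 100_000, flank=1000) == [
        (4000, 5000),
        (6000, 7000),
    ]
    assert flank_intervals(0, 10_000, 10_000, flank=1000) == []


def test_flank_lengths_match_arithmetic_oracle(rng):
    for _ in range(200):
        chrom_len = int(rng.integers(1000, 100_000))
        start = int(rng.integers(0, chrom_len))
        end = int(rng.integers(start, chrom_len))
        flank = int(rng.integers(1, 5000))
        intervals = flank_intervals(start, end, chrom_len, flank)
        lengths = {"left": 0, "right": 0}
        for s, e in intervals:
            side = "left" if e <= start else "right"
            lengths[side] = e - s
        assert lengths["left"] == min(flank, start)
        assert lengths["right"] == min(flank, chrom_len - end)


# ---------------------------------------------------------------------------
# compare_groups


def ranksum_exact_oracle(a, b):
    """Exact two-sided p by enumerating every assignment of pooled ranks."""
    n, m = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == n + m, "oracle requires no ties"
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank_of[x] for x in a) - n * (n + 1) / 2
    nulls = []
    for combo in itertools.combinations(range(1, n + m + 1), n):
        nulls.append(sum(combo) - n * (n + 1) / 2)
    nulls = np.array(nulls)
    u_lo = min(u_obs, n * m - u_obs)
    p = (np.sum(nulls <= u_lo) + np.sum(nulls >= n * m - u_lo)) / len(nulls)
    return min(1.0, p)


def test_ranksum_exact_small_case():
    res = compare_groups([1, 2, 3], [4, 5, 6])
    assert res.pvalue == pytest.approx(0.1)
    assert res.pvalue == pytest.approx(ranksum_exact_oracle([1, 2, 3], [4, 5, 6]))


def test_identical_groups_degenerate():
    res = compare_groups([2.0, 2.0], [2.0, 2.0])
    assert res.pvalue == 1.0
    assert res.degenerate


def test_large_shift_is_significant(rng):
    a = rng.normal(0, 1, 200)
    b = rng.normal(2, 1, 200)
    assert compare_groups(a, b).pvalue < 1e-20
    assert compare_groups(a, b, test="t").pvalue < 1e-20


def test_welch_t_direction(rng):
    a = rng.normal(0, 1, 50)
    b = rng.normal(1, 2, 50)
    res = compare_groups(a, b, test="t")
    assert res.statistic < 0 and res.pvalue < 0.05
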