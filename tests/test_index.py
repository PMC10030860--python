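"""Merging and clustering against independent brute-force oracles."""

import numpy as np
import pytest

from pgii.index import (
    build_presence_matrix,
    cluster_inversions,
    merge_calls,
    per_genome_counts,
)
from pgii.model import InversionCall, NonredundantInversion

from conftest import random_calls, random_index


def brute_force_merge_partition(calls, max_dist):
    """O(n^2) transitive closure over the linking relation, as index sets."""
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i], calls[j]
            if (
                a.chrom == b.chrom
                and abs(a.ref_start - b.ref_start) <= max_dist
                and abs(a.ref_end - b.ref_end) <= max_dist
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {
        frozenset((calls[i].chrom, calls[i].ref_start, calls[i].ref_end,
                   calls[i].query_genome) for i in members)
        for members in groups.values()
    }


def brute_force_cluster_partition(index, frac):
    n = len(index)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = index[i], index[j]
            if a.chrom != b.chrom:
                continue
            ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start) + 1
            if ov > 0 and ov >= frac * a.length and ov >= frac * b.length:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(index[i].inv_id)
    return {frozenset(m) for m in groups.values()}


@pytest.mark.parametrize("seed", [0, 1, 2, 7])
@pytest.mark.parametrize("max_dist", [0, 10, 50])
def test_merge_matches_brute_force_oracle(seed, max_dist):
    rng = np.random.default_rng(seed)
    calls = random_calls(rng, 200)
    index = merge_calls(calls, max_dist=max_dist)
    got = {
        frozenset(
            (c.chrom, c.ref_start, c.ref_end, c.query_genome)
            for c in v.member_calls
        )
        for v in index
    }
    assert got == brute_force_merge_partition(calls, max_dist)


def test_merge_carriers_are_union_of_member_genomes():
    calls = [
        InversionCall("gA", "Chr01", 100, 200),
        InversionCall("gB", "Chr01", 105, 195),
        InversionCall("gA", "Chr01", 108, 198),
    ]
    (inv,) = merge_calls(calls, max_dist=10)
    assert inv.carriers == frozenset({"gA", "gB"})


def test_merge_is_transitive_closure_chain():
    # starts 0/8/16 apart: ends also within 10 pairwise-adjacent, so the
    # chain collapses even though the extremes differ by 16 > 10
    calls = [
        InversionCall("g1", "Chr01", 100, 200),
        InversionCall("g2", "Chr01", 108, 208),
        InversionCall("g3", "Chr01", 116, 216),
    ]
    assert len(merge_calls(calls, max_dist=10)) == 1
    assert len(merge_calls(calls, max_dist=7)) == 3


def test_merge_requires_both_breakpoints_close():
    calls = [
        InversionCall("g1", "Chr01", 100, 200),
        InversionCall("g2", "Chr01", 105, 500),  # start close, end far
    ]
    assert len(merge_calls(calls, max_dist=10)) == 2


def test_medoid_representative_and_tie_break():
    # medoid of {100, 110, 200} starts is 110 (cost 110 vs 120/190)
    calls = [
        InversionCall("g1", "Chr01", 100, 1000),
        InversionCall("g2", "Chr01", 110, 1005),
        InversionCall("g3", "Chr01", 120, 1010),
    ]
    (inv,) = merge_calls(calls, max_dist=20)
    assert (inv.ref_start, inv.ref_end) == (110, 1005)
    # perfect tie between two calls: smallest start wins
    calls = [
        InversionCall("g1", "Chr01", 100, 1000),
        InversionCall("g2", "Chr01", 110, 1010),
    ]
    (inv,) = merge_calls(calls, max_dist=20)
    assert (inv.ref_start, inv.ref_end) == (100, 1000)


def test_merge_ids_follow_chromosome_and_start_order():
    calls = [
        InversionCall("g1", "Chr02", 500, 700),
        InversionCall("g1", "Chr01", 900, 1000),
        InversionCall("g1", "Chr01", 100, 200),
    ]
    index = merge_calls(calls)
    assert [v.inv_id for v in index] == ["INV010001", "INV010002", "INV020001"]
    assert merge_calls([], max_dist=10) == []


def test_merge_unknown_chromosome_rejected():
    with pytest.raises(ValueError, match="unknown chromosomes"):
        merge_calls(
            [InversionCall("g", "ChrX", 1, 100)], known_chroms={"Chr01"}
        )


@pytest.mark.parametrize("seed", [0, 3, 11])
@pytest.mark.parametrize("frac", [0.5, 0.8, 1.0])
def test_cluster_matches_brute_force_oracle(seed, frac):
    rng = np.random.default_rng(seed)
    index = random_index(rng, 150)
    clusters = cluster_inversions(index, min_reciprocal_overlap=frac)
    got = {frozenset(c.members) for c in clusters}
    assert got == brute_force_cluster_partition(index, frac)


def test_cluster_span_and_carriers_union():
    index = [
        NonredundantInversion("a", "Chr01", 100, 199, frozenset({"g1"})),
        NonredundantInversion("b", "Chr01", 110, 215, frozenset({"g2"})),
        NonredundantInversion("c", "Chr01", 5000, 6000, frozenset({"g3"})),
    ]
    clusters = cluster_inversions(index, min_reciprocal_overlap=0.8)
    two = next(c for c in clusters if len(c.members) == 2)
    assert (two.span_start, two.span_end) == (100, 215)
    assert two.carriers_union == frozenset({"g1", "g2"})
    assert two.cluster_id.startswith("Clu-INV01")


def test_non_reciprocal_mode_uses_shorter_length():
    index = [
        NonredundantInversion("a", "Chr01", 100, 199, frozenset({"g1"})),
        NonredundantInversion("b", "Chr01", 100, 999, frozenset({"g2"})),
    ]
    # overlap 100 covers all of a but only 11% of b
    assert len(cluster_inversions(index, 0.8, reciprocal=True)) == 2
    assert len(cluster_inversions(index, 0.8, reciprocal=False)) == 1


def test_presence_matrix_reference_column_zero(small_panel):
    index = [
        NonredundantInversion("a", "Chr01", 100, 300, frozenset({"gj1", "xi1"}))
    ]
    clusters = cluster_inversions(index)
    m = build_presence_matrix(clusters, small_panel, reference_genome="ref")
    assert m["ref"].sum() == 0
    assert m.loc[clusters[0].cluster_id, "gj1"] == 1.0
    assert m.loc[clusters[0].cluster_id, "gj2"] == 0.0
    assert per_genome_counts(m)["xi1"] == 1.0


def test_presence_matrix_rejects_bad_carriers(small_panel):
    index = [
        NonredundantInversion("a", "Chr01", 100, 300, frozenset({"nobody"}))
    ]
    with pytest.raises(ValueError, match="not in panel"):
        build_presence_matrix(cluster_inversions(index), small_panel)
    index = [NonredundantInversion("a", "Chr01", 100, 300, frozenset({"ref"}))]
    with pytest.raises(ValueError, match="reference as a carrier"):
        build_presence_matrix(
            cluster_inversions(index), small_panel, reference_genome="ref"
        )
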