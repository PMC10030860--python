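"""Building the pan-genome inversion index.

Per-genome inversion calls against a single reference are merged into
non-redundant inversions (start and end coordinates each within a maximum
breakpoint distance, 10 bp by default, closed under transitivity), and the
non-redundant index is then clustered by reciprocal overlap (>= 80% of each
member's length by default).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .model import (
    GenomeRecord,
    InversionCall,
    InversionCluster,
    NonredundantInversion,
)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)

    def components(self) -> Dict[int, List[int]]:
        comps: Dict[int, List[int]] = defaultdict(list)
        for i in range(len(self.parent)):
            comps[self.find(i)].append(i)
        return comps


def _chrom_sort_key(chrom: str):
    digits = "".join(ch for ch in chrom if ch.isdigit())
    return (int(digits) if digits else 10**9, chrom)


def _medoid(calls: Sequence[InversionCall]) -> InversionCall:
    """Member call minimizing summed |dstart| + |dend| to all members.

    Ties break to the smallest start, then smallest end.
    """
    starts = np.array([c.ref_start for c in calls])
    ends = np.array([c.ref_end for c in calls])
    cost = (
        np.abs(starts[:, None] - starts[None, :]).sum(axis=1)
        + np.abs(ends[:, None] - ends[None, :]).sum(axis=1)
    )
    order = np.lexsort((ends, starts, cost))
    return calls[order[0]]


def merge_calls(
    calls: Sequence[InversionCall],
    max_dist: int = 10,
    known_chroms: Optional[Iterable[str]] = None,
) -> List[NonredundantInversion]:
    """Collapse near-identical calls across genomes into one record each.

    Two calls are linked iff they share a chromosome and both their start
    and end coordinates differ by at most ``max_dist`` bp. Connected
    components of this relation (transitive closure, so chains longer than
    ``max_dist`` may form) become single non-redundant inversions whose
    representative interval is the component medoid and whose carriers are
    the union of member query genomes. Ids are assigned per chromosome in
    start order (INV{chrom:02d}{serial:04d}).
    """
    if known_chroms is not None:
        known = set(known_chroms)
        bad = {c.chrom for c in calls} - known
        if bad:
            raise ValueError(f"calls on unknown chromosomes: {sorted(bad)}")

    by_chrom: Dict[str, List[InversionCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)

    records: List[NonredundantInversion] = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        group = sorted(by_chrom[chrom], key=lambda c: (c.ref_start, c.ref_end))
        n = len(group)
        uf = _UnionFind(n)
        starts = [c.ref_start for c in group]
        ends = [c.ref_end for c in group]
        for i in range(n):
            j = i + 1
            while j < n and starts[j] - starts[i] <= max_dist:
                if abs(ends[j] - ends[i]) <= max_dist:
                    uf.union(i, j)
                j += 1
        comps = uf.components()
        reps = []
        for members in comps.values():
            comp_calls = [group[i] for i in members]
            rep = _medoid(comp_calls)
            reps.append((rep, comp_calls))
        reps.sort(key=lambda t: (t[0].ref_start, t[0].ref_end))
        chrom_num = _chrom_sort_key(chrom)[0]
        prefix = f"INV{chrom_num:02d}" if chrom_num < 10**9 else f"INV_{chrom}_"
        for serial, (rep, comp_calls) in enumerate(reps, start=1):
            records.append(
                NonredundantInversion(
                    inv_id=f"{prefix}{serial:04d}",
                    chrom=chrom,
                    ref_start=rep.ref_start,
                    ref_end=rep.ref_end,
                    carriers=frozenset(c.query_genome for c in comp_calls),
                    member_calls=comp_calls,
                )
            )
    return records


def _reciprocal_overlap(
    s1: int, e1: int, s2: int, e2: int, min_fraction: float, reciprocal: bool
) -> bool:
    ov = min(e1, e2) - max(s1, s2) + 1
    if ov <= 0:
        return False
    l1 = e1 - s1 + 1
    l2 = e2 - s2 + 1
    if reciprocal:
        return ov >= min_fraction * l1 and ov >= min_fraction * l2
    return ov >= min_fraction * min(l1, l2)


def cluster_inversions(
    index: Sequence[NonredundantInversion],
    min_reciprocal_overlap: float = 0.8,
    reciprocal: bool = True,
) -> List[InversionCluster]:
    """Cluster the non-redundant index by reciprocal overlap.

    Two inversions are linked iff their overlap covers at least
    ``min_reciprocal_overlap`` of each inversion's length (or of the shorter
    one only, with ``reciprocal=False``); connected components become
    clusters spanning min start to max end. Cluster ids follow
    Clu-INV{chrom:02d}{serial:04d} in span order per chromosome.
    """
    by_chrom: Dict[str, List[NonredundantInversion]] = defaultdict(list)
    for inv in index:
        by_chrom[inv.chrom].append(inv)

    clusters: List[InversionCluster] = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        group = sorted(by_chrom[chrom], key=lambda v: (v.ref_start, v.ref_end))
        n = len(group)
        uf = _UnionFind(n)
        # sweep: only pairs whose intervals intersect can satisfy the overlap
        for i in range(n):
            for j in range(i + 1, n):
                if group[j].ref_start > group[i].ref_end:
                    break
                if _reciprocal_overlap(
                    group[i].ref_start,
                    group[i].ref_end,
                    group[j].ref_start,
                    group[j].ref_end,
                    min_reciprocal_overlap,
                    reciprocal,
                ):
                    uf.union(i, j)
        spans = []
        for members in uf.components().values():
            mem = [group[i] for i in members]
            spans.append(
                (
                    min(v.ref_start for v in mem),
                    max(v.ref_end for v in mem),
                    frozenset(v.inv_id for v in mem),
                    frozenset().union(*(v.carriers for v in mem)),
                )
            )
        spans.sort(key=lambda t: (t[0], t[1]))
        chrom_num = _chrom_sort_key(chrom)[0]
        prefix = (
            f"Clu-INV{chrom_num:02d}" if chrom_num < 10**9 else f"Clu-INV_{chrom}_"
        )
        for serial, (s, e, members, carriers) in enumerate(spans, start=1):
            clusters.append(
                InversionCluster(
                    cluster_id=f"{prefix}{serial:04d}",
                    chrom=chrom,
                    span_start=s,
                    span_end=e,
                    members=members,
                    carriers_union=carriers,
                )
            )
    return clusters


def build_presence_matrix(
    clusters: Sequence[InversionCluster],
    panel: Sequence[GenomeRecord],
    reference_genome: Optional[str] = None,
) -> pd.DataFrame:
    """Clusters x genomes presence matrix (1 carrier, 0 absent, NaN missing).

    Presence is defined relative to the reference, whose column (if it is a
    panel member) is all zeros by construction.
    """
    genome_ids = [g.genome_id for g in panel]
    known = set(genome_ids)
    for clu in clusters:
        unknown = clu.carriers_union - known
        if unknown:
            raise ValueError(
                f"cluster {clu.cluster_id} carriers not in panel: {sorted(unknown)}"
            )
        if reference_genome is not None and reference_genome in clu.carriers_union:
            raise ValueError(
                f"cluster {clu.cluster_id} lists the reference as a carrier"
            )
    data = np.zeros((len(clusters), len(genome_ids)), dtype=float)
    col = {g: j for j, g in enumerate(genome_ids)}
    for i, clu in enumerate(clusters):
        for g in clu.carriers_union:
            data[i, col[g]] = 1.0
    return pd.DataFrame(
        data, index=[c.cluster_id for c in clusters], columns=genome_ids
    )


def per_genome_counts(matrix: pd.DataFrame) -> pd.Series:
    """Number of index entries carried by each genome (column sums)."""
    return matrix.sum(axis=0, skipna=True)
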