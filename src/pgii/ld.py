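"""Linkage disequilibrium around inversions.

r-squared is the squared composite (genotype-dosage) correlation, suitable
for unphased panels. LD blocks are maximal cliques of the r² > 0.8 graph
found greedily from the highest-degree sites; block membership may skip
intervening SNPs, which is exactly the disrupted-block signature an
inversion leaves in reference coordinates: a block connecting one flank to
the distal half of the inversion while containing no SNP in the proximal
half (SNP order inside the inversion is reversed in carrier haplotypes, so
recombination in carriers links the flank to what the reference displays as
the far end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


def pairwise_r2(genotypes: pd.DataFrame, site_i: str, site_j: str) -> float:
    """Squared composite correlation of two dosage rows (NaN = missing).

    Computed over jointly non-missing samples; monomorphic sites give NaN.
    """
    gi = genotypes.loc[site_i].to_numpy(dtype=float)
    gj = genotypes.loc[site_j].to_numpy(dtype=float)
    both = ~np.isnan(gi) & ~np.isnan(gj)
    if both.sum() < 2:
        raise ValueError("need >=2 samples with both sites observed")
    gi, gj = gi[both], gj[both]
    if gi.std() == 0 or gj.std() == 0:
        return float("nan")
    return float(np.corrcoef(gi, gj)[0, 1] ** 2)


def r2_matrix(genotypes: pd.DataFrame) -> np.ndarray:
    """All-pairs r² over variant rows (pairwise-complete, NaN where undefined)."""
    X = genotypes.to_numpy(dtype=float)
    if not np.isnan(X).any():
        sd = X.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X)
        r2 = r**2
        r2[sd == 0, :] = np.nan
        r2[:, sd == 0] = np.nan
        return r2
    n = X.shape[0]
    r2 = np.full((n, n), np.nan)
    for i in range(n):
        r2[i, i] = 1.0
        for j in range(i + 1, n):
            gi, gj = X[i], X[j]
            both = ~np.isnan(gi) & ~np.isnan(gj)
            if both.sum() < 2:
                continue
            a, b = gi[both], gj[both]
            if a.std() == 0 or b.std() == 0:
                continue
            r2[i, j] = r2[j, i] = np.corrcoef(a, b)[0, 1] ** 2
    return r2


@dataclass
class LDBlock:
    positions: List[int]
    min_r2: float


@dataclass
class DisruptionCall:
    inversion_id: str
    signature_present: Optional[bool]
    flank_side: str = ""
    n_flank: int = 0
    n_distal: int = 0
    n_proximal: int = 0
    supporting_block: Optional[LDBlock] = None


def find_blocks(
    genotypes: pd.DataFrame,
    positions: Sequence[int],
    r2_threshold: float = 0.8,
    max_span: Optional[int] = None,
) -> List[LDBlock]:
    """Greedy maximal-clique LD blocks on the r² > threshold graph.

    Sites are processed from highest degree (deterministic ties by
    position); each unassigned seed grows a clique by adding, in position
    order, sites adjacent to every current member (and within ``max_span``
    of the seed when given). Each site belongs to at most one block; blocks
    need >= 2 sites.
    """
    pos = np.asarray(positions)
    r2 = r2_matrix(genotypes)
    adj = np.nan_to_num(r2, nan=0.0) > r2_threshold
    np.fill_diagonal(adj, False)
    n = len(pos)
    degree = adj.sum(axis=1)
    order = np.lexsort((pos, -degree))
    assigned = np.zeros(n, dtype=bool)
    blocks: List[LDBlock] = []
    for seed in order:
        if assigned[seed] or degree[seed] == 0:
            continue
        members = [seed]
        for cand in np.argsort(pos, kind="stable"):
            if cand == seed or assigned[cand]:
                continue
            if max_span is not None and abs(pos[cand] - pos[seed]) > max_span:
                continue
            if all(adj[cand, m] for m in members):
                members.append(int(cand))
        if len(members) >= 2:
            members_sorted = sorted(members, key=lambda k: pos[k])
            assigned[members_sorted] = True
            min_r2 = min(
                r2[a, b]
                for ai, a in enumerate(members_sorted)
                for b in members_sorted[ai + 1 :]
            )
            blocks.append(
                LDBlock(
                    positions=[int(pos[k]) for k in members_sorted],
                    min_r2=float(min_r2),
                )
            )
    return blocks


def detect_signature(
    blocks: Sequence[LDBlock],
    inv_start: int,
    inv_end: int,
    flank: int = 100_000,
    min_snps: int = 3,
    inversion_id: str = "",
) -> DisruptionCall:
    """Disrupted-block signature of an inversion, from its LD blocks.

    With midpoint m, the left test splits the region into flank
    L = [s-F, s), proximal P = [s, m) and distal D = [m, e]: the signature
    is present on the left iff some block has >= min_snps SNPs in L,
    >= min_snps in D and none in P. The right side mirrors this
    (flank (e, e+F], proximal (m, e], distal [s, m]). The overall call is
    left OR right.
    """
    if inv_end - inv_start < 2:
        return DisruptionCall(inversion_id=inversion_id, signature_present=None)
    m = inv_start + (inv_end - inv_start) / 2.0

    def side(block: LDBlock, which: str) -> Tuple[int, int, int]:
        p = np.asarray(block.positions)
        if which == "left":
            fl = ((p >= inv_start - flank) & (p < inv_start)).sum()
            prox = ((p >= inv_start) & (p < m)).sum()
            dist = ((p >= m) & (p <= inv_end)).sum()
        else:
            fl = ((p > inv_end) & (p <= inv_end + flank)).sum()
            prox = ((p > m) & (p <= inv_end)).sum()
            dist = ((p >= inv_start) & (p <= m)).sum()
        return int(fl), int(dist), int(prox)

    for which in ("left", "right"):
        for block in blocks:
            fl, dist, prox = side(block, which)
            if fl >= min_snps and dist >= min_snps and prox == 0:
                return DisruptionCall(
                    inversion_id=inversion_id,
                    signature_present=True,
                    flank_side=which,
                    n_flank=fl,
                    n_distal=dist,
                    n_proximal=prox,
                    supporting_block=block,
                )
    return DisruptionCall(inversion_id=inversion_id, signature_present=False)


def scan_inversion(
    genotypes: pd.DataFrame,
    positions: Sequence[int],
    inv_start: int,
    inv_end: int,
    flank: int = 100_000,
    r2_threshold: float = 0.8,
    min_snps: int = 3,
    inversion_id: str = "",
) -> DisruptionCall:
    """Blocks + signature detection over the inversion and its flanks."""
    pos = np.asarray(positions)
    keep = (pos >= inv_start - flank) & (pos <= inv_end + flank)
    sub = genotypes.loc[genotypes.index[keep]]
    blocks = find_blocks(sub, pos[keep], r2_threshold=r2_threshold)
    return detect_signature(
        blocks,
        inv_start,
        inv_end,
        flank=flank,
        min_snps=min_snps,
        inversion_id=inversion_id,
    )
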