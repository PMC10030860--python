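"""Inversion-rate estimation.

The rate is the number of inversion polymorphisms separating two lineages
divided by twice their time to the most recent common ancestor:
IR = N / (2 * TMRCA), in inversions per million years. For within-Geng/
japonica (GJ) estimates, clusters possibly introgressed from other groups
are removed first: only clusters segregating in GJ but in no non-GJ
subpopulation are kept, and regions whose SNP background lies closer to the
Xian/indica (XI) panel than to the GJ panel are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import GenomeRecord, Group

#: population divergence of temperate japonica from proto-japonica plus the
#: expected within-population coalescence time, in million years
GJ_PAIR_TMRCA_MY = 0.0142


@dataclass(frozen=True)
class RateEstimate:
    comparison: str
    tmrca_my: float
    n_inversions: float
    rate: float

    @property
    def reported(self) -> float:
        """Rate rounded the way the result tables print it.

        Rates below 100 print with one decimal; larger ones as integers.
        The stored ``rate`` is never rounded.
        """
        if self.rate < 100:
            return round(self.rate, 1)
        return float(round(self.rate))


def estimate_rate(
    n_inversions: float, tmrca_my: float, comparison: str = ""
) -> RateEstimate:
    """IR = N / (2 * TMRCA)."""
    if tmrca_my <= 0:
        raise ValueError("TMRCA must be positive")
    if n_inversions < 0:
        raise ValueError("inversion count must be non-negative")
    return RateEstimate(
        comparison=comparison,
        tmrca_my=tmrca_my,
        n_inversions=n_inversions,
        rate=n_inversions / (2.0 * tmrca_my),
    )


def gj_private_clusters(
    matrix: pd.DataFrame, panel: Sequence[GenomeRecord]
) -> Set[str]:
    """Clusters segregating within GJ genomes and carried by no non-GJ genome.

    Outgroup species and admixed accessions count as non-GJ: a carrier there
    disqualifies the cluster.
    """
    group_of = {g.genome_id: g.group for g in panel}
    unknown = set(matrix.columns) - set(group_of)
    if unknown:
        raise ValueError(f"genomes without panel metadata: {sorted(unknown)}")
    gj_cols = [g for g in matrix.columns if group_of[g] == Group.GJ]
    non_gj_cols = [g for g in matrix.columns if group_of[g] != Group.GJ]
    present = matrix.fillna(0) > 0
    in_gj = present[gj_cols].any(axis=1)
    in_non_gj = (
        present[non_gj_cols].any(axis=1)
        if non_gj_cols
        else pd.Series(False, index=matrix.index)
    )
    return set(matrix.index[in_gj & ~in_non_gj])


def snp_proximity_filter(
    clusters: Set[str],
    region_distances: Dict[str, Tuple[Optional[float], Optional[float]]],
) -> Set[str]:
    """Drop clusters whose region is closer to the XI panel than to the GJ panel.

    ``region_distances`` maps cluster id to (d_XI, d_GJ), the mean per-site
    SNP distance of the region to each group panel. A cluster is dropped iff
    d_XI < d_GJ (strict); clusters with a missing distance are retained
    conservatively.
    """
    survivors = set()
    for cid in clusters:
        d_xi, d_gj = region_distances.get(cid, (None, None))
        if d_xi is None or d_gj is None:
            survivors.add(cid)
            continue
        if d_xi < d_gj:
            continue
        survivors.add(cid)
    return survivors


def region_snp_distances(
    genotypes: pd.DataFrame,
    regions: Dict[str, Tuple[str, int, int]],
    snp_positions: pd.DataFrame,
    xi_samples: Sequence[str],
    gj_samples: Sequence[str],
) -> Dict[str, Tuple[Optional[float], Optional[float]]]:
    """Mean per-site distance of each region's consensus to two group panels.

    ``regions`` maps cluster id to (chrom, start, end) in 1-based inclusive
    coordinates; ``snp_positions`` has columns chrom and pos indexed like the
    genotype matrix. For each region the across-all-samples consensus dosage
    at each contained SNP is compared to the mean dosage in each panel; the
    returned value per panel is the mean absolute difference over sites.
    Regions without SNPs map to (None, None).
    """
    out: Dict[str, Tuple[Optional[float], Optional[float]]] = {}
    for cid, (chrom, start, end) in regions.items():
        mask = (
            (snp_positions["chrom"] == chrom)
            & (snp_positions["pos"] >= start)
            & (snp_positions["pos"] <= end)
        )
        sub = genotypes.loc[mask.to_numpy()]
        if sub.empty:
            out[cid] = (None, None)
            continue
        consensus = sub.mean(axis=1, skipna=True)
        d_xi = float((sub[list(xi_samples)].mean(axis=1) - consensus).abs().mean())
        d_gj = float((sub[list(gj_samples)].mean(axis=1) - consensus).abs().mean())
        out[cid] = (d_xi, d_gj)
    return out


def pairwise_rate_summary(
    matrix: pd.DataFrame,
    genomes: Sequence[str],
    tmrca_my: float,
    comparison: str = "",
    clusters: Optional[Set[str]] = None,
) -> Tuple[float, RateEstimate]:
    """Mean pairwise differing-cluster count over a genome subset, and its rate.

    For every unordered pair the number of clusters (optionally restricted
    to ``clusters``) whose presence states differ is counted; the mean count
    feeds IR = N / (2 * TMRCA).
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    sub = matrix if clusters is None else matrix.loc[sorted(clusters)]
    sub = sub[list(genomes)].fillna(0) > 0
    counts = [
        int((sub[a] != sub[b]).sum()) for a, b in combinations(genomes, 2)
    ]
    mean_count = float(np.mean(counts))
    return mean_count, estimate_rate(mean_count, tmrca_my, comparison=comparison)


def rate_table(estimates: Sequence[RateEstimate]) -> pd.DataFrame:
    """Summary table mirroring the headline rate comparisons."""
    return pd.DataFrame(
        {
            "comparison": [e.comparison for e in estimates],
            "tmrca_my": [e.tmrca_my for e in estimates],
            "n_inversions": [e.n_inversions for e in estimates],
            "rate_per_my": [e.rate for e in estimates],
            "rate_reported": [e.reported for e in estimates],
        }
    )
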