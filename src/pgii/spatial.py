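"""Spatial statistics over the inversion index.

Covers the discovery-saturation permutation analysis, Monte-Carlo
Kolmogorov-Smirnov tests for uniformity of inversion positions along each
chromosome (with Benjamini-Hochberg correction across length classes), and
fixed-window hotspot detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import NonredundantInversion

logger = logging.getLogger(__name__)

#: closed-open length bins used when stratifying uniformity tests
LENGTH_CLASSES: Dict[str, Tuple[float, float]] = {
    "<1Kb": (100, 1_000),
    "1-5Kb": (1_000, 5_000),
    "5-10Kb": (5_000, 10_000),
    ">10Kb": (10_000, float("inf")),
}


@dataclass
class SaturationCurve:
    """Mean/sd/quantiles of discovered-inversion counts per panel subset size."""

    subset_sizes: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    q05: np.ndarray
    q95: np.ndarray
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset_size": self.subset_sizes,
                "mean": self.mean,
                "sd": self.sd,
                "q05": self.q05,
                "q95": self.q95,
            }
        )


@dataclass
class UniformityResult:
    chrom: str
    length_class: str
    ks_statistic: float
    mc_p: float
    n_positions: int
    n_sim: int
    bh_adjusted_p: Optional[float] = None


def saturation_curve(
    matrix: pd.DataFrame,
    n_perm: int = 1000,
    mode: str = "all",
    min_carriers_for_shared: int = 2,
    seed: int = 0,
    subset_sizes: Optional[Sequence[int]] = None,
) -> SaturationCurve:
    """Resampling curve: inversions discovered in random k-genome subsets.

    For each k the panel columns are subsampled ``n_perm`` times and rows
    present in at least one subset member are counted. ``mode='shared'``
    restricts to rows whose full-panel carrier count is at least
    ``min_carriers_for_shared`` (non-genome-specific inversions).
    """
    if matrix.isna().any().any():
        logger.warning("presence matrix contains missing values; treated as absent")
    present = matrix.fillna(0).to_numpy() > 0
    if mode == "shared":
        present = present[present.sum(axis=1) >= min_carriers_for_shared]
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")
    n_genomes = present.shape[1]
    if subset_sizes is None:
        subset_sizes = range(1, n_genomes + 1)
    subset_sizes = np.asarray(list(subset_sizes), dtype=int)
    if subset_sizes.max(initial=0) > n_genomes:
        raise ValueError("subset size exceeds panel size")

    rng = np.random.default_rng(seed)
    presence = present.astype(np.float32)
    means, sds, q05, q95 = [], [], [], []
    for k in subset_sizes:
        sel = np.zeros((n_genomes, n_perm), dtype=np.float32)
        for p in range(n_perm):
            sel[rng.choice(n_genomes, size=k, replace=False), p] = 1.0
        counts = ((presence @ sel) > 0).sum(axis=0)
        means.append(counts.mean())
        sds.append(counts.std(ddof=0))
        q05.append(np.quantile(counts, 0.05))
        q95.append(np.quantile(counts, 0.95))
    return SaturationCurve(
        subset_sizes=subset_sizes,
        mean=np.array(means),
        sd=np.array(sds),
        q05=np.array(q05),
        q95=np.array(q95),
        mode=mode,
    )


def _ks_statistic_sorted(u: np.ndarray) -> np.ndarray:
    """Sup-norm distance to the uniform CDF for rows of sorted values in [0,1]."""
    n = u.shape[-1]
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    return np.maximum((grid_hi - u).max(axis=-1), (u - grid_lo).max(axis=-1))


def ks_uniformity(
    positions: Sequence[float],
    chrom_length: int,
    n_sim: int = 10_000,
    seed: int = 0,
    chrom: str = "",
    length_class: str = "all",
) -> UniformityResult:
    """Monte-Carlo KS test of positional uniformity along a chromosome.

    The statistic is the sup-norm distance between the empirical CDF of
    positions/chrom_length and the uniform CDF; its null distribution is
    simulated with ``n_sim`` draws of the same number of uniform positions,
    and the p-value uses the add-one estimator
    (1 + #{D_sim >= D_obs}) / (n_sim + 1), so it is never zero.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("need at least one position")
    if (pos < 1).any() or (pos > chrom_length).any():
        raise ValueError("positions outside [1, chrom_length]")
    observed = _ks_statistic_sorted(np.sort(pos / chrom_length))
    rng = np.random.default_rng(seed)
    sims = np.sort(rng.random((n_sim, pos.size)), axis=1)
    d_sim = _ks_statistic_sorted(sims)
    mc_p = (1 + int((d_sim >= observed).sum())) / (n_sim + 1)
    return UniformityResult(
        chrom=chrom,
        length_class=length_class,
        ks_statistic=float(observed),
        mc_p=float(mc_p),
        n_positions=int(pos.size),
        n_sim=n_sim,
    )


def adjust_bh(results: Sequence[UniformityResult]) -> List[UniformityResult]:
    """Benjamini-Hochberg adjustment within each chromosome's set of tests."""
    by_chrom: Dict[str, List[UniformityResult]] = {}
    for r in results:
        by_chrom.setdefault(r.chrom, []).append(r)
    for group in by_chrom.values():
        pvals = [r.mc_p for r in group]
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        for r, p in zip(group, adjusted):
            r.bh_adjusted_p = float(p)
    return list(results)


def uniformity_scan(
    index: Sequence[NonredundantInversion],
    chrom_lengths: Dict[str, int],
    n_sim: int = 10_000,
    seed: int = 0,
    by_length_class: bool = False,
) -> List[UniformityResult]:
    """Run the MC-KS uniformity test per chromosome (optionally per length class)."""
    results: List[UniformityResult] = []
    classes = LENGTH_CLASSES if by_length_class else {"all": (0, float("inf"))}
    rng = np.random.default_rng(seed)
    for chrom in sorted(chrom_lengths):
        on_chrom = [v for v in index if v.chrom == chrom]
        for name, (lo, hi) in classes.items():
            positions = [v.ref_start for v in on_chrom if lo <= v.length < hi]
            if not positions:
                continue
            results.append(
                ks_uniformity(
                    positions,
                    chrom_lengths[chrom],
                    n_sim=n_sim,
                    seed=int(rng.integers(2**31 - 1)),
                    chrom=chrom,
                    length_class=name,
                )
            )
    return adjust_bh(results)


def detect_hotspots(
    index: Sequence[NonredundantInversion],
    chrom_lengths: Dict[str, int],
    window: int = 200_000,
    top_fraction: float = 0.02,
    centromeres: Optional[pd.DataFrame] = None,
    telomeres: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Fixed-window hotspot scan over inversion start coordinates.

    Chromosomes are tiled with non-overlapping windows; a window is a
    hotspot iff its start-coordinate count strictly exceeds the genome-wide
    (1 - top_fraction) quantile of window counts and is at least 1.
    Returns one row per window with hotspot and centromere/telomere
    overlap flags.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom in sorted(chrom_lengths, key=lambda c: (len(c), c)):
        length = chrom_lengths[chrom]
        starts = np.array(
            [v.ref_start for v in index if v.chrom == chrom], dtype=float
        )
        edges = np.arange(0, length + window, window)
        edges[-1] = max(edges[-1], length)
        counts, _ = np.histogram(starts, bins=edges)
        for i, c in enumerate(counts):
            rows.append((chrom, int(edges[i]), int(min(edges[i + 1], length)), int(c)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "start_count"])
    threshold = np.quantile(df["start_count"], 1 - top_fraction)
    df["is_hotspot"] = (df["start_count"] > threshold) & (df["start_count"] >= 1)

    def _overlaps(track: Optional[pd.DataFrame]) -> np.ndarray:
        flags = np.zeros(len(df), dtype=bool)
        if track is None or track.empty:
            return flags
        for i, row in enumerate(df.itertuples(index=False)):
            sub = track[track["chrom"] == row.chrom]
            flags[i] = bool(
                ((sub["start"] < row.end) & (sub["end"] > row.start)).any()
            )
        return flags

    df["centromere_overlap"] = _overlaps(centromeres)
    df["telomere_overlap"] = _overlaps(telomeres)
    return df


def merge_hotspot_regions(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent hotspot windows into hotspot regions."""
    hot = windows[windows["is_hotspot"]].sort_values(["chrom", "start"])
    regions = []
    for _, row in hot.iterrows():
        if (
            regions
            and regions[-1][0] == row["chrom"]
            and regions[-1][2] == row["start"]
        ):
            regions[-1][2] = row["end"]
            regions[-1][3] += row["start_count"]
        else:
            regions.append([row["chrom"], row["start"], row["end"], row["start_count"]])
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_inversions"])
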