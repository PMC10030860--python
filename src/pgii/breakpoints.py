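"""Transposable elements and genes at inversions and their breakpoints.

TE content is the union-of-overlaps base fraction of inversion intervals
covered by TE annotation; breakpoint enrichment compares per-family TE
presence in +/-100 bp windows around observed breakpoints with windows
around randomly resampled genomic positions (ten replicates of ten times
the breakpoint count by default, one-sample t-test of the replicate
frequencies against the observed frequency). Direct/inverted repeats at
breakpoints are sought as exact shared substrings of at least 10 bp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from scipy import stats

from .model import NonredundantInversion

logger = logging.getLogger(__name__)


def _merged(intervals: pd.DataFrame, chrom: str) -> List[Tuple[int, int]]:
    sub = intervals[intervals["chrom"] == chrom].sort_values("start")
    merged: List[Tuple[int, int]] = []
    for row in sub.itertuples(index=False):
        if merged and row.start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], row.end))
        else:
            merged.append((row.start, row.end))
    return merged


def te_content(intervals: pd.DataFrame, te_annotation: pd.DataFrame) -> float:
    """Fraction of interval bases covered by TE annotation (both 0-based

    half-open interval frames on the same reference). Overlapping TE copies
    are counted once (union of overlaps).
    """
    total = 0
    covered = 0
    merged_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for row in intervals.itertuples(index=False):
        total += row.end - row.start
        if row.chrom not in merged_by_chrom:
            merged_by_chrom[row.chrom] = _merged(te_annotation, row.chrom)
        for s, e in merged_by_chrom[row.chrom]:
            if s >= row.end:
                break
            covered += max(0, min(e, row.end) - max(s, row.start))
    return 0.0 if total == 0 else covered / total


@dataclass
class EnrichmentResult:
    family: str
    observed_frequency: float
    resampled_mean: float
    resampled_sd: float
    t_statistic: float
    p_value: float
    n_replicates: int


def _window_family_hits(
    positions: np.ndarray,
    chroms: np.ndarray,
    te_annotation: pd.DataFrame,
    window: int,
    families: Sequence[str],
) -> pd.DataFrame:
    """Per-window boolean presence of each TE family within +/- window bp."""
    hits = np.zeros((len(positions), len(families)), dtype=bool)
    fam_idx = {f: k for k, f in enumerate(families)}
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        pos = positions[mask]
        idx = np.flatnonzero(mask)
        sub = te_annotation[te_annotation["chrom"] == chrom]
        # a TE [s,e) hits window around 1-based p iff s < p+window and e > p-1-window
        for row in sub.itertuples(index=False):
            lo = row.start + 1 - window  # smallest breakpoint coordinate hit
            hi = row.end + window  # largest
            sel = idx[(pos >= lo) & (pos <= hi)]
            hits[sel, fam_idx[row.label]] = True
    return pd.DataFrame(hits, columns=list(families))


def breakpoint_te_enrichment(
    breakpoints: Sequence[Tuple[str, int]],
    te_annotation: pd.DataFrame,
    chrom_lengths: Dict[str, int],
    window: int = 100,
    n_replicates: int = 10,
    resample_multiplier: int = 10,
    excluded: Optional[pd.DataFrame] = None,
    seed: int = 0,
) -> List[EnrichmentResult]:
    """Per-family TE enrichment at breakpoints versus random positions.

    ``breakpoints`` are (chrom, 1-based position) pairs. The observed
    per-family frequency is the share of breakpoint windows containing at
    least one copy of the family. Each replicate draws
    ``resample_multiplier * n_breakpoints / n_replicates`` uniform random
    positions and measures the same frequency; a two-sided one-sample
    t-test compares the replicate frequencies to the observed value.
    """
    if te_annotation.empty or not breakpoints:
        return []
    chroms = np.array([b[0] for b in breakpoints])
    positions = np.array([b[1] for b in breakpoints], dtype=np.int64)
    for chrom, pos in zip(chroms, positions):
        if pos - window < 1 or pos + window > chrom_lengths[chrom]:
            logger.warning(
                "breakpoint window at %s:%d truncated by chromosome bounds",
                chrom,
                pos,
            )
    families = sorted(te_annotation["label"].unique())
    observed = _window_family_hits(
        positions, chroms, te_annotation, window, families
    ).mean(axis=0)

    rng = np.random.default_rng(seed)
    n_per_rep = max(1, round(resample_multiplier * len(positions) / n_replicates))
    chrom_names = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    weights = lengths / lengths.sum()
    rep_freqs = np.zeros((n_replicates, len(families)))
    for rep in range(n_replicates):
        draws_c = rng.choice(len(chrom_names), size=n_per_rep, p=weights)
        draws_p = np.array(
            [rng.integers(1, lengths[c] + 1) for c in draws_c], dtype=np.int64
        )
        if excluded is not None and not excluded.empty:
            keep = np.ones(n_per_rep, dtype=bool)
            for k in range(n_per_rep):
                chrom = chrom_names[draws_c[k]]
                sub = excluded[excluded["chrom"] == chrom]
                if ((sub["start"] < draws_p[k]) & (sub["end"] >= draws_p[k])).any():
                    keep[k] = False
            draws_c, draws_p = draws_c[keep], draws_p[keep]
        rep_chroms = np.array([chrom_names[c] for c in draws_c])
        rep_freqs[rep] = _window_family_hits(
            draws_p, rep_chroms, te_annotation, window, families
        ).mean(axis=0)

    results = []
    for k, fam in enumerate(families):
        col = rep_freqs[:, k]
        if np.ptp(col) == 0:
            # zero replicate variance: the t-test is undefined, so report
            # certainty directly from whether the constant matches
            same = col[0] == observed[fam]
            t_stat = 0.0 if same else math.inf * np.sign(col[0] - observed[fam])
            p = 1.0 if same else 0.0
        else:
            t_stat, p = stats.ttest_1samp(col, observed[fam])
        results.append(
            EnrichmentResult(
                family=fam,
                observed_frequency=float(observed[fam]),
                resampled_mean=float(rep_freqs[:, k].mean()),
                resampled_sd=float(rep_freqs[:, k].std(ddof=1)),
                t_statistic=float(t_stat),
                p_value=float(p),
                n_replicates=n_replicates,
            )
        )
    return results


def te_content_comparison(
    index_fractions: Sequence[float], genome_fractions: Sequence[float]
) -> Tuple[float, float]:
    """Welch t-test comparing per-genome TE content inside the inversion

    index against genome-wide TE content. Returns (t, p)."""
    t, p = stats.ttest_ind(index_fractions, genome_fractions, equal_var=False)
    return float(t), float(p)


def _longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact shared substring (dynamic programming)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def find_breakpoint_repeats(
    left_seq: str, right_seq: str, min_len: int = 10
) -> Dict[str, object]:
    """Search two breakpoint-flanking sequences for direct/inverted repeats.

    A direct repeat is an exact shared substring of at least ``min_len``
    between the two windows on the same strand; an inverted repeat is a
    shared substring between one window and the reverse complement of the
    other, or between a window and its own reverse complement. The longer
    verdict wins ('inverted' on ties); returns
    {'kind': 'direct'|'inverted'|'none', 'length': int}.
    """
    left = left_seq.upper()
    right = right_seq.upper()
    if min(len(left), len(right)) < min_len:
        return {"kind": "none", "length": 0}
    direct = _longest_common_substring(left, right)
    inverted = max(
        _longest_common_substring(left, reverse_complement(right)),
        _longest_common_substring(left, reverse_complement(left)),
        _longest_common_substring(right, reverse_complement(right)),
    )
    if max(direct, inverted) < min_len:
        return {"kind": "none", "length": 0}
    if inverted >= direct:
        return {"kind": "inverted", "length": inverted}
    return {"kind": "direct", "length": direct}


def genes_at_inversions(
    index: Sequence[NonredundantInversion], gene_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Count genes within inversions and genes spanning breakpoints.

    A gene (0-based half-open) is 'within' if its span is contained in an
    inversion; 'at a breakpoint' if its span strictly contains a breakpoint
    coordinate. Returns one row per inversion with both counts and the
    gene labels involved.
    """
    rows = []
    for inv in index:
        s0, e0 = inv.ref_start - 1, inv.ref_end  # inversion, 0-based half-open
        genes = gene_annotation[gene_annotation["chrom"] == inv.chrom]
        within = genes[(genes["start"] >= s0) & (genes["end"] <= e0)]
        at_bp = genes[
            (
                (genes["start"] < inv.ref_start - 1)
                & (genes["end"] > inv.ref_start)
            )
            | ((genes["start"] < inv.ref_end - 1) & (genes["end"] > inv.ref_end))
        ]
        rows.append(
            {
                "inv_id": inv.inv_id,
                "n_within": len(within),
                "n_at_breakpoint": len(at_bp),
                "within": ",".join(within["label"]),
                "at_breakpoint": ",".join(at_bp["label"]),
            }
        )
    return pd.DataFrame(rows).set_index("inv_id")
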