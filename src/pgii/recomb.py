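"""Recombination rate from a RIL bin map, and suppression inside inversions.

Rates are cM/Mb between neighboring bin midpoints; an inter-bin interval is
attributed to an inversion if its midpoint lies inside one (a minimum
overlap fraction is available instead), and inverted vs genome-wide rates
are compared with a two-sample Welch t-test.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def interbin_rates(binmap: pd.DataFrame) -> pd.DataFrame:
    """Per-interval recombination rates between neighboring bins.

    ``binmap`` columns: bin_id, chrom, cm, phys_start, phys_end. The rate of
    the interval between two neighboring bins is their genetic distance
    divided by the physical distance between bin midpoints, in cM/Mb.
    Zero-physical-distance intervals are skipped with a warning; negative
    genetic distances are an error.
    """
    rows = []
    for chrom, grp in binmap.groupby("chrom", sort=True):
        grp = grp.sort_values("phys_start")
        if len(grp) < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 bins")
        mid = (grp["phys_start"].to_numpy() + grp["phys_end"].to_numpy()) / 2.0
        cm = grp["cm"].to_numpy(dtype=float)
        d_cm = np.diff(cm)
        if (d_cm < 0).any():
            raise ValueError(f"genetic positions decrease on {chrom}")
        d_mb = np.diff(mid) / 1e6
        for k in range(len(d_cm)):
            if d_mb[k] <= 0:
                logger.warning(
                    "zero physical distance between bins on %s; interval skipped",
                    chrom,
                )
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": mid[k],
                    "end": mid[k + 1],
                    "d_cm": d_cm[k],
                    "rate_cm_per_mb": d_cm[k] / d_mb[k],
                }
            )
    return pd.DataFrame(rows)


def compare_inverted_rates(
    rates: pd.DataFrame,
    inversions: Sequence[Tuple[str, int, int]],
    min_overlap_fraction: Optional[float] = None,
) -> Dict[str, float]:
    """Mean recombination rate in inverted intervals vs genome-wide.

    ``inversions`` are (chrom, start, end) in 1-based inclusive
    coordinates. By default an interval is inverted if its midpoint falls
    inside an inversion; with ``min_overlap_fraction`` set, the overlap must
    cover at least that fraction of the interval instead. The genome-wide
    mean includes the inverted intervals. Returns mean_inverted,
    mean_genomewide, t_statistic and p_value (two-sided Welch); a degenerate
    comparison (no rate variance) reports t = 0, p = 1.
    """
    inverted_mask = np.zeros(len(rates), dtype=bool)
    mid = (rates["start"].to_numpy() + rates["end"].to_numpy()) / 2.0
    for chrom, s, e in inversions:
        on = (rates["chrom"] == chrom).to_numpy()
        if min_overlap_fraction is None:
            inverted_mask |= on & (mid >= s) & (mid <= e)
        else:
            ov = np.minimum(rates["end"].to_numpy(), e) - np.maximum(
                rates["start"].to_numpy(), s - 1
            )
            span = rates["end"].to_numpy() - rates["start"].to_numpy()
            inverted_mask |= on & (ov / np.maximum(span, 1) >= min_overlap_fraction)
    if inverted_mask.sum() == 0:
        raise ValueError("no inter-bin intervals overlap the inversions")
    inv_rates = rates.loc[inverted_mask, "rate_cm_per_mb"].to_numpy()
    all_rates = rates["rate_cm_per_mb"].to_numpy()
    out = {
        "mean_inverted": float(inv_rates.mean()),
        "mean_genomewide": float(all_rates.mean()),
        "n_inverted": int(inverted_mask.sum()),
        "n_total": len(all_rates),
    }
    non_inv = rates.loc[~inverted_mask, "rate_cm_per_mb"].to_numpy()
    if (
        len(inv_rates) < 2
        or len(non_inv) < 2
        or (inv_rates.std() == 0 and non_inv.std() == 0)
    ):
        out["t_statistic"], out["p_value"] = 0.0, 1.0
        return out
    t, p = stats.ttest_ind(inv_rates, non_inv, equal_var=False)
    if np.isnan(t):
        t, p = 0.0, 1.0
    out["t_statistic"], out["p_value"] = float(t), float(p)
    return out
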