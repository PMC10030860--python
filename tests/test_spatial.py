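from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pgii.model import NonredundantInversion
from pgii.spatial import (
    LENGTH_CLASSES,
    UniformityResult,
    adjust_bh,
    detect_hotspots,
    ks_uniformity,
    merge_hotspot_regions,
    saturation_curve,
    uniformity_scan,
)


def _matrix():
    # 5 clusters x 4 genomes, known subset coverage
    data = np.array(
        [
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 0],
            [0, 1, 1, 1],
            [0, 0, 0, 0],  # carried by nobody (reference-only orientation)
        ],
        dtype=float,
    )
    return pd.DataFrame(
        data, index=[f"c{k}" for k in range(5)], columns=list("ABCD")
    )


def exhaustive_mean(present, k):
    """Exact expected discovery count over all k-genome subsets."""
    n = present.shape[1]
    counts = [
        int((present[:, list(sub)].any(axis=1)).sum())
        for sub in combinations(range(n), k)
    ]
    return np.mean(counts)


def test_saturation_matches_exhaustive_enumeration():
    m = _matrix()
    present = m.to_numpy() > 0
    curve = saturation_curve(m, n_perm=4000, seed=1)
    assert list(curve.subset_sizes) == [1, 2, 3, 4]
    # k = n is deterministic: every non-empty row is discovered
    assert curve.mean[-1] == 4 and curve.sd[-1] == 0
    for idx, k in enumerate([1, 2, 3]):
        exact = exhaustive_mean(present, k)
        se = curve.sd[idx] / np.sqrt(4000)
        assert abs(curve.mean[idx] - exact) < max(4 * se, 0.05)


def test_saturation_shared_mode_restricts_rows():
    m = _matrix()
    curve = saturation_curve(m, n_perm=100, mode="shared", seed=0)
    # only rows with >= 2 carriers qualify: c1 and c3
    assert curve.mean[-1] == 2
    with pytest.raises(ValueError, match="unknown mode"):
        saturation_curve(m, mode="nope")
    with pytest.raises(ValueError, match="exceeds panel size"):
        saturation_curve(m, subset_sizes=[9])


def test_saturation_curve_is_monotone_in_subset_size():
    m = _matrix()
    curve = saturation_curve(m, n_perm=500, seed=3)
    assert (np.diff(curve.mean) >= 0).all()


def test_ks_statistic_matches_scipy():
    rng = np.random.default_rng(0)
    for n in (3, 10, 57):
        pos = rng.integers(1, 1_000_000, size=n)
        res = ks_uniformity(pos, 1_000_000, n_sim=10, seed=0)
        expected = stats.kstest(pos / 1_000_000, "uniform").statistic
        assert res.ks_statistic == pytest.approx(expected, abs=1e-12)


def test_ks_uniformity_add_one_estimator_bounds():
    # a perfectly uniform grid should never beat the simulations badly
    grid = np.linspace(1, 1_000_000, 20)
    res = ks_uniformity(grid, 1_000_000, n_sim=199, seed=4)
    assert res.mc_p > 0.5
    # extreme clustering: p bottoms out at the add-one floor 1/(n_sim+1)
    clustered = np.full(20, 1.0)
    res = ks_uniformity(clustered, 1_000_000, n_sim=199, seed=4)
    assert res.mc_p == pytest.approx(1 / 200)
    with pytest.raises(ValueError, match="at least one position"):
        ks_uniformity([], 100, n_sim=10)
    with pytest.raises(ValueError, match="outside"):
        ks_uniformity([0], 100, n_sim=10)


def hand_bh(pvals):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, pvals[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def test_bh_adjustment_matches_hand_computation():
    pvals = [0.01, 0.04, 0.03, 0.20, 0.90]
    results = [
        UniformityResult("Chr01", "all", 0.1, p, 10, 100) for p in pvals
    ]
    adjusted = adjust_bh(results)
    expected = hand_bh(pvals)
    got = [r.bh_adjusted_p for r in adjusted]
    assert got == pytest.approx(list(expected))


def test_bh_adjustment_is_per_chromosome():
    results = [
        UniformityResult("Chr01", "all", 0.1, 0.05, 10, 100),
        UniformityResult("Chr02", "all", 0.1, 0.05, 10, 100),
    ]
    adjusted = adjust_bh(results)
    # alone on its chromosome, each p is unchanged by BH
    assert [r.bh_adjusted_p for r in adjusted] == [0.05, 0.05]


def _index_at(chrom, starts, length=500):
    return [
        NonredundantInversion(
            f"i{k}", chrom, int(s), int(s) + length - 1, frozenset({"g"})
        )
        for k, s in enumerate(starts)
    ]


def test_uniformity_scan_by_length_class():
    index = _index_at("Chr01", [1000, 2000, 3000], length=500) + _index_at(
        "Chr01", [5000, 6000], length=20_000
    )
    results = uniformity_scan(
        index, {"Chr01": 1_000_000}, n_sim=99, seed=0, by_length_class=True
    )
    classes = {r.length_class for r in results}
    assert classes == {"<1Kb", ">10Kb"}
    assert all(r.bh_adjusted_p is not None for r in results)
    assert set(LENGTH_CLASSES) == {"<1Kb", "1-5Kb", "5-10Kb", ">10Kb"}


def test_hotspot_detection_and_strict_threshold():
    # 10 windows of 200 kb on one chromosome; one window holds 5 starts
    starts = [150_000, 150_010, 150_020, 150_030, 150_040]
    starts += [400_001, 900_000, 1_300_000, 1_700_000]
    index = _index_at("Chr01", starts)
    windows = detect_hotspots(
        index, {"Chr01": 2_000_000}, window=200_000, top_fraction=0.02
    )
    assert len(windows) == 10
    hot = windows[windows["is_hotspot"]]
    assert len(hot) == 1
    assert hot.iloc[0]["start"] == 0 and hot.iloc[0]["start_count"] == 5
    # strict inequality: if every window had the same count, none is a hotspot
    flat = _index_at("Chr01", [100_000 + 200_000 * k for k in range(10)])
    windows = detect_hotspots(
        flat, {"Chr01": 2_000_000}, window=200_000, top_fraction=0.02
    )
    assert not windows["is_hotspot"].any()


def test_hotspot_centromere_flag_and_region_merge():
    starts = [50_000] * 5 + [250_000] * 4 + [850_000]
    index = _index_at("Chr01", starts)
    centromeres = pd.DataFrame(
        [("Chr01", 0, 100_000, "cen")],
        columns=["chrom", "start", "end", "label"],
    )
    windows = detect_hotspots(
        index,
        {"Chr01": 2_000_000},
        window=200_000,
        top_fraction=0.15,
        centromeres=centromeres,
    )
    hot = windows[windows["is_hotspot"]]
    assert set(hot["start"]) == {0, 200_000}
    assert windows.loc[windows["start"] == 0, "centromere_overlap"].item()
    regions = merge_hotspot_regions(windows)
    # adjacent hotspot windows merge into one region covering both
    assert len(regions) == 1
    assert regions.iloc[0]["n_inversions"] == 9
    assert (regions.iloc[0]["start"], regions.iloc[0]["end"]) == (0, 400_000)
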