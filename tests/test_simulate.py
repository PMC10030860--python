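import numpy as np
import pandas as pd
import pytest

from pgii.index import merge_calls
from pgii.model import BreakpointState, InversionGenotype, Species
from pgii.simulate import (
    DEFAULT_SUBPOP_SIZES,
    PanelConfig,
    _epoch_integral,
    build_branches,
    build_panel,
    pairwise_tmrca,
    simulate_binmap,
    simulate_breakpoint_read_patterns,
    simulate_inversion_genotypes,
    simulate_panel,
    simulate_te_annotation,
)

SMALL = dict(
    subpop_sizes={"GJ-temp": 2, "GJ-trop1": 2, "XI-1A": 2, "cA1": 2, "cB1": 2}
)


def test_panel_composition_and_reference():
    panel, reference = build_panel(PanelConfig())
    assert len(panel) == sum(DEFAULT_SUBPOP_SIZES.values()) + 2  # 73 + outgroups
    assert reference == "GJ-temp_1"
    by_species = {s: 0 for s in Species}
    for g in panel:
        by_species[g.species] += 1
    assert by_species[Species.SATIVA] == 73
    assert by_species[Species.RUFIPOGON] == 1
    assert by_species[Species.PUNCTATA] == 1


def test_pairwise_tmrca_table():
    cfg = PanelConfig(**SMALL)
    panel, _ = build_panel(cfg)
    by_id = {g.genome_id: g for g in panel}
    cases = [
        ("GJ-temp_1", "GJ-temp_2", cfg.age_subpop),
        ("GJ-temp_1", "GJ-trop1_1", cfg.age_group),
        ("GJ-temp_1", "cB1_1", cfg.age_clade),  # GJ and cB share a clade
        ("GJ-temp_1", "XI-1A_1", cfg.age_sativa),
        ("GJ-temp_1", "cA1_1", cfg.age_sativa),
        ("XI-1A_1", "cA1_1", cfg.age_clade),
        ("GJ-temp_1", "rufipogon_1", cfg.age_aa_split),
        ("XI-1A_1", "punctata_1", cfg.age_bb_split),
        ("rufipogon_1", "punctata_1", cfg.age_bb_split),
    ]
    for a, b, expected in cases:
        assert pairwise_tmrca(cfg, by_id[a], by_id[b]) == expected
        assert pairwise_tmrca(cfg, by_id[b], by_id[a]) == expected
    assert pairwise_tmrca(cfg, by_id[cases[0][0]], by_id[cases[0][0]]) == 0.0


def test_epoch_integral_piecewise():
    cfg = PanelConfig()
    # entirely within the recent epoch
    assert _epoch_integral(cfg, 0, 0.0071) == pytest.approx(0.0071 * 735)
    # spanning recent and AA epochs
    got = _epoch_integral(cfg, 0.0071, 0.25)
    expected = (0.0142 - 0.0071) * 735 + (0.25 - 0.0142) * 215.2
    assert got == pytest.approx(expected)


def test_branch_integrals_cover_headline_expectations():
    cfg = PanelConfig()
    # two genomes from the same group, different subpopulations: their path
    # spans [0, age_group] twice, matching 2 * 0.0142 * 735 = 20.9 events
    path = 2 * _epoch_integral(cfg, 0, cfg.age_group)
    assert path == pytest.approx(2 * 0.0142 * 735, rel=1e-12)
    # O. sativa vs O. rufipogon: 2 * integral(0, 0.5) = 230
    path = 2 * _epoch_integral(cfg, 0, cfg.age_aa_split)
    assert path == pytest.approx(230, rel=1e-3)
    # O. sativa vs O. punctata: 2 * integral(0, 2.5) = 337
    path = 2 * _epoch_integral(cfg, 0, cfg.age_bb_split)
    assert path == pytest.approx(337, rel=1e-3)


def test_simulated_panel_zero_noise_recovers_truth_exactly():
    cfg = PanelConfig(jitter=0, fn_rate=0, **SMALL)
    sim = simulate_panel(cfg, seed=5)
    calls = [
        c
        for g, cs in sim.calls.items()
        if g != sim.reference_genome
        for c in cs
    ]
    index = merge_calls(calls, max_dist=10)
    assert len(index) == len(sim.truth)
    by_coord = {(v.chrom, v.ref_start, v.ref_end): v for v in index}
    for _, ev in sim.truth.iterrows():
        v = by_coord[(ev["chrom"], ev["start"], ev["end"])]
        assert v.carriers == frozenset(ev["observed_carriers"].split(","))


def test_reference_never_emits_calls_and_ascertainment_flips():
    cfg = PanelConfig(jitter=0, fn_rate=0, **SMALL)
    sim = simulate_panel(cfg, seed=1)
    assert sim.calls[sim.reference_genome] == []
    flipped = sim.truth[
        sim.truth["inverted_clade"].str.split(",").map(
            lambda tips: sim.reference_genome in tips
        )
    ]
    assert len(flipped) > 0  # some events arise on the reference's lineage
    all_ids = {g.genome_id for g in sim.panel}
    for _, ev in flipped.iterrows():
        observed = set(ev["observed_carriers"].split(","))
        inverted = set(ev["inverted_clade"].split(","))
        assert observed == all_ids - inverted  # call set is the complement


def test_simulated_panel_is_seed_deterministic():
    cfg = PanelConfig(**SMALL)
    a = simulate_panel(cfg, seed=9)
    b = simulate_panel(cfg, seed=9)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    assert a.calls == b.calls
    c = simulate_panel(cfg, seed=10)
    assert not a.truth.equals(c.truth)


def test_event_count_moments_match_poisson_expectation():
    cfg = PanelConfig(**SMALL)
    expected = sum(
        _epoch_integral(cfg, br.child_age, br.parent_age)
        for br in build_branches(cfg)
    )
    counts = [len(simulate_panel(cfg, seed=s).truth) for s in range(25)]
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expected) < 4 * se


def test_genotype_simulation_shapes_and_carriers():
    sim = simulate_inversion_genotypes(seed=3)
    n_snps = len(sim.positions)
    assert sim.genotypes.shape == (n_snps, 60)
    assert set(np.unique(sim.genotypes.to_numpy())) <= {0.0, 2.0}  # inbred
    assert list(sim.positions) == sorted(sim.positions)
    # carrier fraction tracks inv_freq
    assert sim.carrier_status.mean() == pytest.approx(0.5, abs=0.15)
    assert (sim.inv_start, sim.inv_end) == (100_001, 400_000)
    null = simulate_inversion_genotypes(seed=3, inv_freq=0.0)
    assert not null.carrier_status.any()


def test_genotype_simulation_validation_and_determinism():
    with pytest.raises(ValueError, match="at least 10 SNPs"):
        simulate_inversion_genotypes(n_snps=5)
    with pytest.raises(ValueError, match="inv_freq"):
        simulate_inversion_genotypes(inv_freq=1.0)
    with pytest.raises(ValueError, match="sample more"):
        simulate_inversion_genotypes(n_samples=500)
    a = simulate_inversion_genotypes(seed=11)
    b = simulate_inversion_genotypes(seed=11)
    pd.testing.assert_frame_equal(a.genotypes, b.genotypes)


def test_binmap_simulator_exact_without_noise():
    bm = simulate_binmap(n_bins=10, chrom_length=10_000_000, base_rate=4.0,
                         noise_sd=0.0)
    assert len(bm) == 10
    assert bm["cm"].is_monotonic_increasing
    # each 1 Mb inter-midpoint gap adds exactly 4 cM
    assert np.diff(bm["cm"]) == pytest.approx(np.full(9, 4.0))
    with pytest.raises(ValueError, match="suppression"):
        simulate_binmap(suppression=1.5)


def test_te_annotation_simulator_properties():
    lengths = {"Chr01": 500_000, "Chr02": 300_000}
    te = simulate_te_annotation(lengths, coverage_fraction=0.2, seed=0)
    assert set(te["chrom"]) <= set(lengths)
    for chrom, grp in te.groupby("chrom"):
        grp = grp.sort_values("start")
        assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()
        covered = (grp["end"] - grp["start"]).sum()
        assert 0.15 < covered / lengths[chrom] < 0.25
    bp = [("Chr01", 100_000)]
    enriched = simulate_te_annotation(
        lengths, coverage_fraction=0.05, breakpoints=bp, enrichment=1000.0,
        enriched_family="MULE", seed=1,
    )
    hit = enriched[
        (enriched["chrom"] == "Chr01")
        & (enriched["start"] < 100_100)
        & (enriched["end"] > 99_900)
    ]
    assert (hit["label"] == "MULE").any()


def test_breakpoint_read_patterns_zero_noise_exact():
    truth = pd.DataFrame(
        [[InversionGenotype.INV, InversionGenotype.NO_INV]],
        index=["inv1"],
        columns=["a1", "a2"],
    )
    support, eff = simulate_breakpoint_read_patterns(truth, dropout=0.0, seed=0)
    assert support.loc["inv1", "a1"] == (
        BreakpointState.SUPPORTED,
        BreakpointState.SUPPORTED,
    )
    assert support.loc["inv1", "a2"] == (
        BreakpointState.ABSENT,
        BreakpointState.ABSENT,
    )
    pd.testing.assert_frame_equal(eff, truth)


def test_breakpoint_read_patterns_deletion_conversion():
    truth = pd.DataFrame(
        [[InversionGenotype.INV] * 50],
        index=["inv1"],
        columns=[f"a{k}" for k in range(50)],
    )
    support, eff = simulate_breakpoint_read_patterns(
        truth, deletion_fraction=1.0, seed=0
    )
    assert (eff.loc["inv1"] == InversionGenotype.INV_DEL).all()
    for cell in support.loc["inv1"]:
        assert sorted(s.value for s in cell) == ["absent", "supported"]
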