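"""Synthetic-data generators with known truth for every pipeline input.

The panel generator plants inversion events on a three-species tree
(O. punctata -- (O. rufipogon -- O. sativa)) whose O. sativa crown is
structured into the four varietal groups and fifteen subpopulations, with
per-branch Poisson event counts driven by an epoch-dependent rate schedule,
uniform positions, a log-normal length distribution spanning 100 bp - 5 Mb,
independent breakpoint jitter per observing genome, per-genome false
negatives, and ascertainment against a designated reference genome (events
carried by the reference are re-expressed as calls in all non-carriers).

The genotype generator is a forward haplotype-class simulation: a single
inversion origin, recombination between opposite-karyotype parents allowed
only in the flanks, recombination between inverted parents following the
carrier (reversed) coordinate order, and per-site mutation, which together
reproduce the disrupted-LD-block signature an inversion leaves in reference
coordinates. Further generators emit RIL bin maps with recombination
suppressed inside inversions, TE annotations optionally enriched at planted
breakpoints, and noisy breakpoint-support tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import (
    BreakpointState,
    GenomeRecord,
    Group,
    InversionCall,
    InversionGenotype,
    SUBPOPULATION_GROUP,
    Species,
)

# ---------------------------------------------------------------------------
# species tree and panel configuration
# ---------------------------------------------------------------------------

#: Nipponbare-like chromosome lengths (bp)
DEFAULT_CHROM_LENGTHS: Dict[str, int] = {
    "Chr01": 43_270_000,
    "Chr02": 35_940_000,
    "Chr03": 36_410_000,
    "Chr04": 35_500_000,
    "Chr05": 29_960_000,
    "Chr06": 31_250_000,
    "Chr07": 29_700_000,
    "Chr08": 28_440_000,
    "Chr09": 23_010_000,
    "Chr10": 23_210_000,
    "Chr11": 29_020_000,
    "Chr12": 27_530_000,
}

#: genomes per subpopulation (73 O. sativa assemblies across K = 15 labels)
DEFAULT_SUBPOP_SIZES: Dict[str, int] = {
    "GJ-temp": 6,
    "GJ-trop1": 5,
    "GJ-trop2": 4,
    "GJ-subtrop": 4,
    "XI-1A": 6,
    "XI-1B1": 5,
    "XI-1B2": 5,
    "XI-2": 5,
    "XI-3": 5,
    "XI-adm": 5,
    "cA1": 4,
    "cA2": 4,
    "cA3": 4,
    "cB1": 6,
    "cB2": 5,
}


@dataclass
class PanelConfig:
    """Shape and rates of the simulated genome panel.

    Node ages are in million years before present. The inversion rate is
    epoch-dependent per lineage: ``rate_recent`` applies more recently than
    the within-group coalescence horizon, ``rate_aa`` within the AA lineage
    back to the O. sativa / O. rufipogon split, and ``rate_bb`` beyond it,
    so that the headline pairwise comparisons (outgroup species and
    within-GJ pairs) are matched in expectation. Events per branch are
    Poisson with mean equal to the rate integral over the branch.
    """

    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    subpop_sizes: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBPOP_SIZES)
    )
    reference_subpop: str = "GJ-temp"
    # node ages (MY)
    age_subpop: float = 0.0071
    age_group: float = 0.0142
    age_clade: float = 0.25
    age_sativa: float = 0.38
    age_aa_split: float = 0.5
    age_bb_split: float = 2.5
    # epoch rates (inversions per MY per lineage)
    rate_recent: float = 735.0
    rate_aa: float = 215.2
    rate_bb: float = 26.75
    # event geometry
    length_log_mu: float = 7.3  # ln bp; median ~1.5 kb
    length_log_sigma: float = 1.8
    min_length: int = 100
    max_length: int = 5_000_000
    jitter: int = 5
    fn_rate: float = 0.05
    reject_overlapping: bool = True

    def __post_init__(self) -> None:
        for r in (self.rate_recent, self.rate_aa, self.rate_bb):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if not 0 <= self.fn_rate <= 1:
            raise ValueError("fn_rate must be in [0, 1]")


@dataclass
class Branch:
    """A branch of the species/population tree: spans [child_age, parent_age]."""

    name: str
    child_age: float
    parent_age: float
    tips: Tuple[str, ...]  # genome ids descending from this branch


def _epoch_integral(cfg: PanelConfig, t0: float, t1: float) -> float:
    """Integral of the epoch rate schedule over [t0, t1] MY."""
    horizon1, horizon2 = cfg.age_group, cfg.age_aa_split
    total = 0.0
    total += cfg.rate_recent * max(0.0, min(t1, horizon1) - min(t0, horizon1))
    total += cfg.rate_aa * max(
        0.0, min(t1, horizon2) - max(min(t0, horizon2), horizon1)
    )
    total += cfg.rate_bb * max(0.0, t1 - max(t0, horizon2))
    return total


def build_panel(cfg: PanelConfig) -> Tuple[List[GenomeRecord], str]:
    """Panel member list and the designated reference genome id."""
    panel: List[GenomeRecord] = []
    for subpop, n in cfg.subpop_sizes.items():
        group = SUBPOPULATION_GROUP[subpop]
        for k in range(1, n + 1):
            panel.append(
                GenomeRecord(
                    genome_id=f"{subpop}_{k}",
                    species=Species.SATIVA,
                    group=group,
                    subpopulation=subpop,
                    chrom_lengths=cfg.chrom_lengths,
                )
            )
    panel.append(
        GenomeRecord(
            "rufipogon_1",
            Species.RUFIPOGON,
            Group.OUTGROUP,
            "outgroup",
            cfg.chrom_lengths,
        )
    )
    panel.append(
        GenomeRecord(
            "punctata_1",
            Species.PUNCTATA,
            Group.OUTGROUP,
            "outgroup",
            cfg.chrom_lengths,
        )
    )
    reference = f"{cfg.reference_subpop}_1"
    return panel, reference


def build_branches(cfg: PanelConfig) -> List[Branch]:
    """All branches of the panel tree with their descendant tip sets."""
    groups: Dict[Group, List[str]] = {}
    for subpop in cfg.subpop_sizes:
        groups.setdefault(SUBPOPULATION_GROUP[subpop], []).append(subpop)
    tips_of_subpop = {
        sp: tuple(f"{sp}_{k}" for k in range(1, n + 1))
        for sp, n in cfg.subpop_sizes.items()
    }
    tips_of_group = {
        g: tuple(t for sp in sps for t in tips_of_subpop[sp])
        for g, sps in groups.items()
    }
    sativa_tips = tuple(t for g in tips_of_group.values() for t in g)

    branches: List[Branch] = []
    # genome tip branches
    for sp, tips in tips_of_subpop.items():
        for t in tips:
            branches.append(Branch(f"tip:{t}", 0.0, cfg.age_subpop, (t,)))
        branches.append(
            Branch(f"subpop:{sp}", cfg.age_subpop, cfg.age_group, tips)
        )
    # group branches up to the two major clades
    for g, tips in tips_of_group.items():
        branches.append(Branch(f"group:{g.value}", cfg.age_group, cfg.age_clade, tips))
    clade_a = tips_of_group.get(Group.GJ, ()) + tips_of_group.get(Group.CB, ())
    clade_b = tips_of_group.get(Group.XI, ()) + tips_of_group.get(Group.CA, ())
    if clade_a:
        branches.append(Branch("clade:GJ+cB", cfg.age_clade, cfg.age_sativa, clade_a))
    if clade_b:
        branches.append(Branch("clade:XI+cA", cfg.age_clade, cfg.age_sativa, clade_b))
    branches.append(
        Branch("stem:sativa", cfg.age_sativa, cfg.age_aa_split, sativa_tips)
    )
    branches.append(
        Branch("tip:rufipogon_1", 0.0, cfg.age_aa_split, ("rufipogon_1",))
    )
    branches.append(
        Branch(
            "stem:AA",
            cfg.age_aa_split,
            cfg.age_bb_split,
            sativa_tips + ("rufipogon_1",),
        )
    )
    branches.append(Branch("tip:punctata_1", 0.0, cfg.age_bb_split, ("punctata_1",)))
    return branches


def pairwise_tmrca(cfg: PanelConfig, g1: GenomeRecord, g2: GenomeRecord) -> float:
    """Divergence time (MY) of two panel genomes under the panel tree."""
    if g1.genome_id == g2.genome_id:
        return 0.0
    if Species.PUNCTATA in (g1.species, g2.species):
        return cfg.age_bb_split
    if Species.RUFIPOGON in (g1.species, g2.species):
        return cfg.age_aa_split
    if g1.subpopulation == g2.subpopulation:
        return cfg.age_subpop
    if g1.group == g2.group:
        return cfg.age_group
    same_clade = {g1.group, g2.group} <= {Group.GJ, Group.CB} or {
        g1.group,
        g2.group,
    } <= {Group.XI, Group.CA}
    return cfg.age_clade if same_clade else cfg.age_sativa


@dataclass
class SimulatedPanel:
    panel: List[GenomeRecord]
    reference_genome: str
    calls: Dict[str, List[InversionCall]]
    truth: pd.DataFrame  # one row per planted event
    config: PanelConfig


def _draw_interval(
    rng: np.random.Generator,
    cfg: PanelConfig,
    occupied: Dict[str, List[Tuple[int, int]]],
    guard: int,
) -> Tuple[str, int, int]:
    chroms = sorted(cfg.chrom_lengths)
    lens = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lens / lens.sum()
    for _ in range(1000):
        length = int(
            np.exp(rng.normal(cfg.length_log_mu, cfg.length_log_sigma))
        )
        if not cfg.min_length <= length <= cfg.max_length:
            continue
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        limit = cfg.chrom_lengths[chrom] - length
        if limit < 1:
            continue
        start = int(rng.integers(1, limit + 1))
        end = start + length - 1
        if cfg.reject_overlapping:
            clash = any(
                start - guard <= e and end + guard >= s
                for s, e in occupied.get(chrom, [])
            )
            if clash:
                continue
        occupied.setdefault(chrom, []).append((start, end))
        return chrom, start, end
    raise RuntimeError("could not place a non-overlapping event; genome too full")


def simulate_panel(cfg: PanelConfig, seed: int = 0) -> SimulatedPanel:
    """Plant inversion events on the panel tree and emit per-genome calls.

    The truth table records, per event, its interval, originating branch,
    the clade carrying the inverted orientation, and the observed carrier
    set after reference ascertainment (genomes that emit a call, before
    false negatives).
    """
    rng = np.random.default_rng(seed)
    panel, reference = build_panel(cfg)
    all_tips = {g.genome_id for g in panel}
    branches = build_branches(cfg)
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    guard = 2 * cfg.jitter + 25

    events = []
    for br in branches:
        mean = _epoch_integral(cfg, br.child_age, br.parent_age)
        n_events = rng.poisson(mean)
        for _ in range(n_events):
            chrom, start, end = _draw_interval(rng, cfg, occupied, guard)
            inverted = set(br.tips)
            observed = (
                sorted(all_tips - inverted)
                if reference in inverted
                else sorted(inverted)
            )
            events.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "branch": br.name,
                    "inverted_clade": ",".join(sorted(inverted)),
                    "observed_carriers": ",".join(observed),
                }
            )
    truth = pd.DataFrame(
        events,
        columns=[
            "chrom",
            "start",
            "end",
            "branch",
            "inverted_clade",
            "observed_carriers",
        ],
    )
    truth = truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    truth.index.name = "event_id"

    calls: Dict[str, List[InversionCall]] = {g.genome_id: [] for g in panel}
    for _, ev in truth.iterrows():
        observed = ev["observed_carriers"].split(",") if ev["observed_carriers"] else []
        for genome in observed:
            if cfg.fn_rate > 0 and rng.random() < cfg.fn_rate:
                continue
            if cfg.jitter > 0:
                ds = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
                de = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
            else:
                ds = de = 0
            calls[genome].append(
                InversionCall(
                    query_genome=genome,
                    chrom=ev["chrom"],
                    ref_start=max(1, int(ev["start"]) + ds),
                    ref_end=int(ev["end"]) + de,
                    source="simulated",
                )
            )
    return SimulatedPanel(
        panel=panel,
        reference_genome=reference,
        calls=calls,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# SNP genotypes around an inversion (haplotype-class forward simulation)
# ---------------------------------------------------------------------------


@dataclass
class GenotypeSimulation:
    genotypes: pd.DataFrame  # variants x samples, dosage 0/2 (inbred)
    positions: np.ndarray  # 1-based reference coordinates of the variants
    inv_start: int
    inv_end: int
    carrier_status: pd.Series  # sample -> bool


def simulate_inversion_genotypes(
    n_samples: int = 60,
    inv_freq: float = 0.5,
    inv_length: int = 300_000,
    flank: int = 100_000,
    n_snps: int = 400,
    pop_size: int = 120,
    generations: int = 20,
    mutation_rate: float = 2e-4,
    crossovers_per_meiosis: float = 0.5,
    suppression_halo: int = 80_000,
    seed: int = 0,
) -> GenotypeSimulation:
    """Forward-simulate SNP haplotypes around an inversion.

    The population holds ``pop_size`` haplotypes, a fraction ``inv_freq`` of
    which carry the inverted orientation; the inverted class descends from a
    single founder haplotype (one origin). Each generation every offspring
    haplotype recombines two parents: crossovers fall anywhere when parents
    share a karyotype (in reversed, carrier-coordinate order inside the
    inversion when both are inverted), but only in the flanks when
    karyotypes differ - the classic heterokaryotype suppression, which
    extends ``suppression_halo`` bp beyond each breakpoint as observed
    around natural inversions. Mutations
    flip alleles at ``mutation_rate`` per site per generation. Samples are
    drawn as inbred (homozygous) individuals, dosage 0/2.

    ``inv_freq = 0`` simulates the matched no-inversion panel.
    """
    if n_snps < 10:
        raise ValueError("need at least 10 SNPs")
    if not 0 <= inv_freq < 1:
        raise ValueError("inv_freq must be in [0, 1)")
    if n_samples > pop_size:
        raise ValueError("cannot sample more individuals than haplotypes")
    rng = np.random.default_rng(seed)
    total = 2 * flank + inv_length
    inv_start, inv_end = flank + 1, flank + inv_length
    positions = np.sort(rng.choice(np.arange(1, total + 1), n_snps, replace=False))
    inside = (positions >= inv_start) & (positions <= inv_end)

    # carrier coordinates: flanks as-is, inversion interior reversed
    carrier_pos = positions.astype(np.int64).copy()
    carrier_pos[inside] = inv_start + inv_end - positions[inside]
    pinned = (positions >= inv_start - suppression_halo) & (
        positions <= inv_end + suppression_halo
    )
    ref_coords = positions.astype(np.int64)

    n_inv = int(round(inv_freq * pop_size))
    classes = np.zeros(pop_size, dtype=bool)
    classes[:n_inv] = True

    # founder haplotypes: the panel's standing diversity is represented by a
    # few deep lineages per karyotype class. Because heterokaryotypes never
    # exchange the suppressed region, variants that arose on inverted
    # chromosomes after the single origin stay private to the inverted
    # class; within that class they are structured into deep founder
    # lineages whose mosaic segments follow carrier (reversed) coordinates.
    # Most suppressed-region sites are therefore modelled as markers private
    # to one inverted founder (standard haplotypes monomorphic ancestral),
    # interleaved along the region so every founder lineage is marked
    # densely; the remainder carry standard-class standing variation.
    n_founders_std, n_founders_inv = 6, 3
    derived_rate = 0.30
    marker_fraction = 0.8
    std_founders = (
        rng.random((n_founders_std, n_snps)) < derived_rate
    ).astype(np.int8)
    inv_founders = std_founders[
        rng.integers(n_founders_std, size=n_founders_inv)
    ].copy()
    inv_founders[:, pinned] = 0
    pinned_idx = np.flatnonzero(pinned)
    is_marker = rng.random(pinned_idx.size) < marker_fraction
    marker_idx = pinned_idx[is_marker]
    std_founders[:, marker_idx] = 0
    owner = np.arange(marker_idx.size) % n_founders_inv
    for f in range(n_founders_inv):
        inv_founders[f, marker_idx[owner == f]] = 1
    haps = std_founders[rng.integers(n_founders_std, size=pop_size)].copy()
    if n_inv > 0:
        choice = rng.integers(n_founders_inv, size=n_inv)
        haps[:n_inv][:, pinned] = inv_founders[choice][:, pinned]

    def _recombine(
        h1: np.ndarray,
        h2: np.ndarray,
        coords: np.ndarray,
        flanks_only: bool,
    ) -> np.ndarray:
        n_x = rng.poisson(crossovers_per_meiosis)
        if n_x == 0:
            return h1.copy()
        cuts = rng.integers(1, total + 1, size=n_x)
        if flanks_only:
            cuts = cuts[
                (cuts < inv_start - suppression_halo)
                | (cuts > inv_end + suppression_halo)
            ]
            if cuts.size == 0:
                return h1.copy()
        # the source parent at a site flips with each crossover passed along
        # the walk, i.e. it is the parity of crossovers left of the site
        src = np.searchsorted(np.sort(cuts), coords, side="right") % 2
        child = np.where(src == 0, h1, h2).astype(np.int8)
        if flanks_only:
            # the inversion and its suppression halo segregate as a unit
            # with the karyotype parent
            child[pinned] = h1[pinned]
        return child

    for _ in range(generations):
        new_haps = np.empty_like(haps)
        inv_pool = np.flatnonzero(classes)
        std_pool = np.flatnonzero(~classes)
        for k in range(pop_size):
            # offspring karyotype is fixed; first parent provides it
            pool = inv_pool if classes[k] else std_pool
            p1 = int(rng.choice(pool))
            p2 = int(rng.integers(pop_size))
            same_class = classes[p1] == classes[p2]
            coords = carrier_pos if (same_class and classes[p1]) else ref_coords
            new_haps[k] = _recombine(
                haps[p1], haps[p2], coords, flanks_only=not same_class
            )
        haps = new_haps
        mut = rng.random(haps.shape) < mutation_rate
        haps ^= mut.astype(np.int8)

    sample_idx = rng.choice(pop_size, size=n_samples, replace=False)
    dosage = (2 * haps[sample_idx]).T.astype(float)  # inbred: hom only
    samples = [f"acc{k + 1}" for k in range(n_samples)]
    genotypes = pd.DataFrame(
        dosage, index=[f"Chr01:{p}" for p in positions], columns=samples
    )
    carrier_status = pd.Series(classes[sample_idx], index=samples)
    return GenotypeSimulation(
        genotypes=genotypes,
        positions=positions,
        inv_start=inv_start,
        inv_end=inv_end,
        carrier_status=carrier_status,
    )


# ---------------------------------------------------------------------------
# RIL bin map with suppressed recombination inside inversions
# ---------------------------------------------------------------------------


def simulate_binmap(
    n_bins: int = 200,
    chrom_length: int = 30_000_000,
    base_rate: float = 6.98,
    inversions: Sequence[Tuple[int, int]] = (),
    suppression: float = 0.3,
    noise_sd: float = 0.25,
    chrom: str = "Chr01",
    seed: int = 0,
) -> pd.DataFrame:
    """Bin map whose inter-bin genetic distances reflect base_rate cM/Mb,

    multiplied by ``suppression`` where the inter-bin interval midpoint lies
    inside a planted inversion, with multiplicative log-normal noise
    (sd ``noise_sd`` on the log scale; 0 disables noise).
    """
    if not 0 <= suppression <= 1:
        raise ValueError("suppression must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, chrom_length, n_bins + 1)
    starts = edges[:-1].astype(int) + 1
    ends = edges[1:].astype(int)
    mids = (starts + ends) / 2.0
    cm = np.zeros(n_bins)
    for k in range(1, n_bins):
        gap_mb = (mids[k] - mids[k - 1]) / 1e6
        mid = (mids[k] + mids[k - 1]) / 2.0
        rate = base_rate
        if any(s <= mid <= e for s, e in inversions):
            rate *= suppression
        noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
        cm[k] = cm[k - 1] + gap_mb * rate * noise
    return pd.DataFrame(
        {
            "bin_id": [f"bin{k + 1}" for k in range(n_bins)],
            "chrom": chrom,
            "cm": cm,
            "phys_start": starts,
            "phys_end": ends,
        }
    )


# ---------------------------------------------------------------------------
# TE annotation
# ---------------------------------------------------------------------------

DEFAULT_TE_FAMILIES: Dict[str, float] = {
    "Ty3-Gypsy": 0.4,
    "Ty1-Copia": 0.2,
    "MULE": 0.15,
    "CACTA": 0.15,
    "hAT": 0.1,
}


def simulate_te_annotation(
    chrom_lengths: Dict[str, int],
    coverage_fraction: float = 0.4,
    family_weights: Optional[Dict[str, float]] = None,
    breakpoints: Sequence[Tuple[str, int]] = (),
    enrichment: float = 1.0,
    enriched_family: str = "Ty3-Gypsy",
    window: int = 100,
    mean_te_length: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Non-overlapping TE intervals with family labels (0-based half-open).

    With ``enrichment > 1``, copies of ``enriched_family`` are additionally
    placed to overlap the +/-window regions around the supplied breakpoints:
    each breakpoint window independently receives an extra copy with
    probability proportional to (enrichment - 1).
    """
    if not 0 <= coverage_fraction < 1:
        raise ValueError("coverage_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    weights = family_weights or DEFAULT_TE_FAMILIES
    families = sorted(weights)
    probs = np.array([weights[f] for f in families], dtype=float)
    probs /= probs.sum()
    rows: List[Tuple[str, int, int, str]] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def _place(chrom: str, start: int, length: int, fam: str) -> bool:
        end = min(start + length, chrom_lengths[chrom])
        if end <= start:
            return False
        if any(s < end and e > start for s, e in occupied[chrom]):
            return False
        occupied[chrom].append((start, end))
        rows.append((chrom, start, end, fam))
        return True

    if enrichment > 1 and breakpoints:
        p_extra = min(1.0, (enrichment - 1) / enrichment)
        for chrom, pos in breakpoints:
            if rng.random() < p_extra:
                length = max(50, int(rng.exponential(mean_te_length)))
                start = max(0, int(pos) - 1 - int(rng.integers(0, window)))
                _place(chrom, start, length, enriched_family)

    for chrom, clen in sorted(chrom_lengths.items()):
        target = coverage_fraction * clen
        placed = sum(e - s for s, e in occupied[chrom])
        attempts = 0
        while placed < target and attempts < 100_000:
            attempts += 1
            length = max(50, int(rng.exponential(mean_te_length)))
            start = int(rng.integers(0, max(1, clen - length)))
            fam = families[rng.choice(len(families), p=probs)]
            if _place(chrom, start, length, fam):
                placed += min(start + length, clen) - start
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# breakpoint read-support patterns
# ---------------------------------------------------------------------------


def simulate_breakpoint_read_patterns(
    truth_genotypes: pd.DataFrame,
    dropout: float = 0.0,
    deletion_fraction: float = 0.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per accession x inversion breakpoint support states from true genotypes.

    ``truth_genotypes`` holds InversionGenotype values (inversions in rows,
    accessions in columns). Carriers show (supported, supported); a fraction
    ``deletion_fraction`` of carrier cells is converted to the
    inversion+deletion truth with a single supported breakpoint;
    non-carriers show (absent, absent). Each breakpoint state independently
    drops out to nodata with probability ``dropout``. Returns
    (support_table, effective_truth) where the effective truth records any
    deletion conversions.
    """
    if not 0 <= dropout <= 1 or not 0 <= deletion_fraction <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    support = pd.DataFrame(index=truth_genotypes.index, columns=truth_genotypes.columns,
                           dtype=object)
    truth = truth_genotypes.copy()
    for inv in truth_genotypes.index:
        for acc in truth_genotypes.columns:
            g = truth_genotypes.loc[inv, acc]
            if g == InversionGenotype.INV and rng.random() < deletion_fraction:
                g = InversionGenotype.INV_DEL
                truth.loc[inv, acc] = g
            if g == InversionGenotype.INV:
                left = right = BreakpointState.SUPPORTED
            elif g == InversionGenotype.INV_DEL:
                keep_left = rng.random() < 0.5
                left = (
                    BreakpointState.SUPPORTED if keep_left else BreakpointState.ABSENT
                )
                right = (
                    BreakpointState.ABSENT if keep_left else BreakpointState.SUPPORTED
                )
            else:
                left = right = BreakpointState.ABSENT
            if rng.random() < dropout:
                left = BreakpointState.NODATA
            if rng.random() < dropout:
                right = BreakpointState.NODATA
            support.loc[inv, acc] = (left, right)
    return support, truth
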