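"""Species-scale and population-scale classification of inversions.

Species-scale ancestral-state categories are assigned by parsimony over the
carrier pattern of the three species (O. sativa against its reference plus
the O. rufipogon and O. punctata outgroups). Population-scale categories
follow carrier frequencies across the labelled accession panel, after
4-state breakpoint genotyping and missing-data filtering.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import (
    BreakpointState,
    GenomeRecord,
    Group,
    InversionGenotype,
    PopulationCategory,
    Species,
    SpeciesCategory,
)


def classify_species_scale(
    row: pd.Series, panel: Sequence[GenomeRecord], reference_genome: str
) -> SpeciesCategory:
    """Ancestral-state category of one cluster from its carrier pattern.

    With s = any non-reference O. sativa carrier, r = O. rufipogon carrier,
    p = O. punctata carrier (carriers are genomes in the non-reference
    orientation):

    ========  ========  ========  ==========
    s         r         p         category
    ========  ========  ========  ==========
    no        no        yes       P
    no        yes       no        R
    no        yes       yes       S3  (all O. sativa derived / fixed)
    yes       no        no        S1  (reference ancestral)
    yes       yes       no        SR1 (reference ancestral)
    yes       yes       yes       SR2 (reference derived)
    yes       no        yes       S2  (reference derived)
    no        no        no        UNRESOLVED
    ========  ========  ========  ==========
    """
    species_of = {g.genome_id: g.species for g in panel}
    if row.isna().all():
        return SpeciesCategory.UNRESOLVED
    carriers = {g for g in row.index if not pd.isna(row[g]) and row[g] > 0}
    carriers.discard(reference_genome)
    s = any(species_of[g] == Species.SATIVA for g in carriers)
    r = any(species_of[g] == Species.RUFIPOGON for g in carriers)
    p = any(species_of[g] == Species.PUNCTATA for g in carriers)
    table = {
        (False, False, True): SpeciesCategory.P,
        (False, True, False): SpeciesCategory.R,
        (False, True, True): SpeciesCategory.S3,
        (True, False, False): SpeciesCategory.S1,
        (True, True, False): SpeciesCategory.SR1,
        (True, True, True): SpeciesCategory.SR2,
        (True, False, True): SpeciesCategory.S2,
        (False, False, False): SpeciesCategory.UNRESOLVED,
    }
    return table[(s, r, p)]


def classify_matrix_species_scale(
    matrix: pd.DataFrame, panel: Sequence[GenomeRecord], reference_genome: str
) -> pd.Series:
    """Species-scale category for every cluster row of a presence matrix."""
    return pd.Series(
        {
            cid: classify_species_scale(matrix.loc[cid], panel, reference_genome)
            for cid in matrix.index
        },
        name="category",
    )


def category_counts(categories: pd.Series) -> Dict[str, int]:
    """Counts per fine category plus the S/SR major-group totals."""
    counts = {c.value: 0 for c in SpeciesCategory}
    for cat in categories:
        counts[cat.value] += 1
    counts["S"] = counts["S1"] + counts["S2"] + counts["S3"]
    counts["SR"] = counts["SR1"] + counts["SR2"]
    return counts


def genotype_breakpoints(
    left: BreakpointState, right: BreakpointState
) -> Tuple[InversionGenotype, bool]:
    """4-state genotype from the two breakpoint support states.

    both supported -> INV; both absent -> NO_INV; exactly one supported with
    the other absent -> INV_DEL; no data at both -> NA. When one side has no
    data the observed side decides, flagged low-confidence (second return
    value False).
    """
    states = (left, right)
    if states == (BreakpointState.SUPPORTED, BreakpointState.SUPPORTED):
        return InversionGenotype.INV, True
    if states == (BreakpointState.ABSENT, BreakpointState.ABSENT):
        return InversionGenotype.NO_INV, True
    if states == (BreakpointState.NODATA, BreakpointState.NODATA):
        return InversionGenotype.NA, True
    if BreakpointState.NODATA in states:
        observed = left if right == BreakpointState.NODATA else right
        geno = (
            InversionGenotype.INV
            if observed == BreakpointState.SUPPORTED
            else InversionGenotype.NO_INV
        )
        return geno, False
    return InversionGenotype.INV_DEL, True


def genotype_support_table(support: pd.DataFrame) -> pd.DataFrame:
    """Apply breakpoint genotyping cell-wise.

    ``support`` is accessions x inversions with (left, right) BreakpointState
    tuples; returns the same shape with InversionGenotype values.
    """
    return support.map(lambda cell: genotype_breakpoints(*cell)[0])


def filter_missing(
    genotypes: pd.DataFrame, max_missing: float = 0.30
) -> Tuple[pd.DataFrame, List[str], List[str]]:
    """Drop inversions then accessions with too much missing data.

    ``genotypes`` is inversions (rows) x accessions (columns) with
    InversionGenotype.NA (or NaN) marking missing cells. Rows with an NA
    fraction above ``max_missing`` are dropped first; column fractions are
    then recomputed on the surviving rows and columns above the threshold
    dropped. Because removing columns can push a remaining row back over
    the threshold, the two passes repeat until stable, so no surviving row
    or column exceeds ``max_missing``. Returns
    (filtered, dropped_inversions, dropped_accessions).
    """
    isna = genotypes.map(
        lambda v: v is None
        or (isinstance(v, float) and np.isnan(v))
        or v == InversionGenotype.NA
        or v == "NA"
    )
    rows = list(genotypes.index)
    cols = list(genotypes.columns)
    dropped_rows: List[str] = []
    dropped_cols: List[str] = []
    while rows and cols:
        row_frac = isna.loc[rows, cols].mean(axis=1)
        bad_rows = list(row_frac.index[row_frac > max_missing])
        rows = [r for r in rows if r not in set(bad_rows)]
        dropped_rows.extend(bad_rows)
        if not rows:
            break
        col_frac = isna.loc[rows, cols].mean(axis=0)
        bad_cols = list(col_frac.index[col_frac > max_missing])
        cols = [c for c in cols if c not in set(bad_cols)]
        dropped_cols.extend(bad_cols)
        if not bad_rows and not bad_cols:
            break
    kept = genotypes.loc[rows, cols]
    if kept.empty:
        raise ValueError("missingness filter removed everything")
    return kept, dropped_rows, dropped_cols


def classify_population_scale(
    genotypes: pd.DataFrame, panel: Sequence[GenomeRecord]
) -> pd.DataFrame:
    """Frequency category of each inversion across the labelled panel.

    Carriers are accessions genotyped INV or INV_DEL. One carrier ->
    genome_specific; all carriers in one subpopulation (>=2) ->
    subpopulation_specific; all in one group spanning >=2 subpopulations ->
    group_specific; otherwise group_shared. Admixed accessions count as
    carriers but are ignored when judging specificity (their labels are
    unreliable). Zero-carrier inversions are excluded.
    """
    sub_of = {g.genome_id: g.subpopulation for g in panel}
    group_of = {g.genome_id: g.group for g in panel}
    rows = []
    for inv_id in genotypes.index:
        row = genotypes.loc[inv_id]
        carriers = [
            a
            for a in genotypes.columns
            if row[a] in (InversionGenotype.INV, InversionGenotype.INV_DEL)
        ]
        if not carriers:
            continue
        informative = [a for a in carriers if group_of[a] != Group.ADMIXED]
        subs = {sub_of[a] for a in informative}
        groups = {group_of[a] for a in informative}
        if len(carriers) == 1:
            cat = PopulationCategory.GENOME_SPECIFIC
        elif len(subs) == 1 and len(groups) == 1:
            cat = PopulationCategory.SUBPOPULATION_SPECIFIC
        elif len(groups) == 1:
            cat = PopulationCategory.GROUP_SPECIFIC
        else:
            cat = PopulationCategory.GROUP_SHARED
        rows.append(
            {
                "inversion": inv_id,
                "category": cat,
                "n_carriers": len(carriers),
                "carrier_groups": ",".join(sorted(g.value for g in groups)),
                "carrier_subpopulations": ",".join(sorted(subs)),
            }
        )
    return pd.DataFrame(rows).set_index("inversion")
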