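"""Readers and writers for the standard formats the pipeline touches.

Interval annotations (TEs, genes, centromeres, telomeres) are held as
pandas DataFrames with columns ``chrom, start, end, label`` in 0-based
half-open coordinates; genotype matrices as DataFrames of 0/1/2 dosages
(samples in columns, variants in rows) with missing values as NaN.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .model import (
    BreakpointState,
    GenomeRecord,
    Group,
    InversionCall,
    InversionCluster,
    InversionGenotype,
    Interval,
    MIN_INVERSION_LENGTH,
    NonredundantInversion,
    Species,
    SpeciesCategory,
    bed_to_vcf,
    vcf_to_bed,
)

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = ["chrom", "start", "end", "label"]


def read_inversion_vcf(
    path: Union[str, Path],
    query_genome: str,
    min_length: int = MIN_INVERSION_LENGTH,
    known_chroms: Optional[Iterable[str]] = None,
) -> Tuple[List[InversionCall], int]:
    """Read SVTYPE=INV records from a VCF into InversionCall objects.

    Records shorter than ``min_length`` are dropped and counted; records
    without an END are rejected with a logged reason. Returns
    ``(calls, n_dropped_short)``.
    """
    known = set(known_chroms) if known_chroms is not None else None
    calls: List[InversionCall] = []
    n_short = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            alts = rec.alts or ()
            if svtype != "INV" and "<INV>" not in alts:
                continue
            if known is not None and rec.chrom not in known:
                raise ValueError(f"unknown chromosome {rec.chrom!r} in {path}")
            end = rec.info.get("END", rec.stop if rec.stop > rec.pos else None)
            if end is None:
                logger.warning(
                    "record %s:%d lacks INFO/END; rejected", rec.chrom, rec.pos
                )
                continue
            call = InversionCall(
                query_genome=query_genome,
                chrom=rec.chrom,
                ref_start=rec.pos,
                ref_end=int(end),
                source=str(path),
            )
            if call.length < min_length:
                n_short += 1
                continue
            calls.append(call)
    return calls, n_short


def write_inversion_vcf(
    calls: Sequence[InversionCall],
    path: Union[str, Path],
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write inversion calls as a minimal VCF 4.2 with SVTYPE=INV records."""
    chroms: Dict[str, int] = dict(chrom_lengths or {})
    for c in calls:
        chroms.setdefault(c.chrom, 0)
        chroms[c.chrom] = max(chroms[c.chrom], c.ref_end)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        fh.write(
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n'
        )
        for chrom in sorted(chroms):
            fh.write(f"##contig=<ID={chrom},length={chroms[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(sorted(calls, key=lambda x: (x.chrom, x.ref_start))):
            fh.write(
                f"{c.chrom}\t{c.ref_start}\tinv{i + 1}\tN\t<INV>\t.\tPASS\t"
                f"SVTYPE=INV;END={c.ref_end}\n"
            )


def write_index_bed(
    index: Sequence[NonredundantInversion], path: Union[str, Path]
) -> None:
    """Write the non-redundant index as BED6 (score = carrier count)."""
    with open(path, "w") as fh:
        for inv in index:
            start, end = vcf_to_bed(inv.ref_start, inv.ref_end)
            fh.write(
                f"{inv.chrom}\t{start}\t{end}\t{inv.inv_id}\t{len(inv.carriers)}\t+\n"
            )


def read_index_bed(path: Union[str, Path]) -> List[NonredundantInversion]:
    """Read an index BED back into NonredundantInversion stubs (no member calls)."""
    out: List[NonredundantInversion] = []
    for i, line in enumerate(open(path), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise ValueError(f"{path}: malformed BED line {i}")
        start, end = bed_to_vcf(int(fields[1]), int(fields[2]))
        out.append(
            NonredundantInversion(
                inv_id=fields[3],
                chrom=fields[0],
                ref_start=start,
                ref_end=end,
                carriers=frozenset(f"carrier{k}" for k in range(int(fields[4]))),
            )
        )
    return out


def read_bed(path: Union[str, Path], label: str = "") -> pd.DataFrame:
    """Read a BED file into an interval frame (0-based half-open)."""
    rows = []
    for i, line in enumerate(open(path), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: malformed BED line {i}")
        rows.append(
            (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                fields[3] if len(fields) > 3 else label,
            )
        )
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_bed(intervals: pd.DataFrame, path: Union[str, Path]) -> None:
    intervals.to_csv(
        path, sep="\t", header=False, index=False, columns=INTERVAL_COLUMNS
    )


def read_interval_gff3(
    path: Union[str, Path], feature_types: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Read GFF3 features into an interval frame.

    GFF3 is 1-based inclusive; the result is 0-based half-open. The label is
    the feature type (e.g. a TE family such as Gypsy, or 'gene').
    """
    wanted = set(feature_types) if feature_types is not None else None
    rows = []
    for i, line in enumerate(open(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 8:
            raise ValueError(f"{path}: malformed GFF3 line {i}")
        ftype = fields[2]
        if wanted is not None and ftype not in wanted:
            continue
        start, end = int(fields[3]), int(fields[4])
        rows.append((fields[0], start - 1, end, ftype))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_interval_gff3(
    intervals: pd.DataFrame, path: Union[str, Path], source: str = "pgii"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in intervals.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\t{row.label}\t{row.start + 1}\t{row.end}"
                f"\t.\t+\t.\t.\n"
            )


def intervals_from_records(records: Iterable[Interval]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.label) for r in records],
        columns=INTERVAL_COLUMNS,
    )


def _gt_to_dosage(gt: Tuple) -> float:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return np.nan
    return float(sum(1 for a in alleles if a > 0))


def read_genotype_matrix(path: Union[str, Path]) -> pd.DataFrame:
    """Read SNP genotypes into a variants x samples dosage matrix.

    VCF input: GT fields are coded as alternate-allele dosage 0/1/2 with
    missing as NaN; row index is ``chrom:pos``. TSV input: first two columns
    chrom and pos, remaining columns one per sample.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        rows = []
        idx = []
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                rows.append(
                    [_gt_to_dosage(rec.samples[s].get("GT", ())) for s in samples]
                )
                idx.append(f"{rec.chrom}:{rec.pos}")
        return pd.DataFrame(rows, index=idx, columns=samples, dtype=float)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: genotype TSV needs chrom, pos and sample columns")
    df.index = df.iloc[:, 0].astype(str) + ":" + df.iloc[:, 1].astype(str)
    return df.iloc[:, 2:].astype(float)


def read_binmap(path: Union[str, Path]) -> pd.DataFrame:
    """Read a RIL bin map TSV: columns bin_id, chrom, cm, phys_start, phys_end."""
    df = pd.read_csv(path, sep="\t", dtype={"bin_id": str, "chrom": str})
    required = {"bin_id", "chrom", "cm", "phys_start", "phys_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: bin map missing columns {sorted(missing)}")
    for chrom, grp in df.groupby("chrom"):
        if not grp["cm"].is_monotonic_increasing:
            raise ValueError(f"{path}: genetic positions decrease on {chrom}")
    return df


def write_binmap(binmap: pd.DataFrame, path: Union[str, Path]) -> None:
    binmap.to_csv(path, sep="\t", index=False)


def read_panel_table(path: Union[str, Path]) -> List[GenomeRecord]:
    """Read a genome metadata TSV: genome_id, species, group, subpopulation."""
    panel = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            panel.append(
                GenomeRecord(
                    genome_id=row["genome_id"],
                    species=Species(row["species"]),
                    group=Group(row["group"]),
                    subpopulation=row["subpopulation"],
                )
            )
    ids = [g.genome_id for g in panel]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate genome_id")
    return panel


def write_panel_table(panel: Sequence[GenomeRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tspecies\tgroup\tsubpopulation\n")
        for g in panel:
            fh.write(
                f"{g.genome_id}\t{g.species.value}\t{g.group.value}\t{g.subpopulation}\n"
            )


def read_chrom_lengths(path: Union[str, Path]) -> Dict[str, int]:
    """Read a two-column TSV (chrom, length in bp) into a dict."""
    out: Dict[str, int] = {}
    for i, line in enumerate(open(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: malformed chromosome-length line {i}")
        if fields[0] == "chrom" and not fields[1].isdigit():
            continue
        length = int(fields[1])
        if length <= 0:
            raise ValueError(f"{path}: non-positive length for {fields[0]}")
        out[fields[0]] = length
    if not out:
        raise ValueError(f"{path}: no chromosome lengths found")
    return out


def write_chrom_lengths(
    chrom_lengths: Dict[str, int], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"{chrom}\t{chrom_lengths[chrom]}\n")


def write_index_table(
    index: Sequence[NonredundantInversion], path: Union[str, Path]
) -> None:
    """Write the non-redundant index with carrier sets (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("inv_id\tchrom\tref_start\tref_end\tn_carriers\tcarriers\n")
        for inv in index:
            fh.write(
                f"{inv.inv_id}\t{inv.chrom}\t{inv.ref_start}\t{inv.ref_end}"
                f"\t{len(inv.carriers)}\t{','.join(sorted(inv.carriers))}\n"
            )


def read_index_table(path: Union[str, Path]) -> List[NonredundantInversion]:
    """Read an index table written by :func:`write_index_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"carriers": str})
    required = {"inv_id", "chrom", "ref_start", "ref_end", "carriers"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: index table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        carriers = row.carriers if isinstance(row.carriers, str) else ""
        out.append(
            NonredundantInversion(
                inv_id=str(row.inv_id),
                chrom=str(row.chrom),
                ref_start=int(row.ref_start),
                ref_end=int(row.ref_end),
                carriers=frozenset(c for c in carriers.split(",") if c),
            )
        )
    return out


def write_cluster_table(
    clusters: Sequence["InversionCluster"], path: Union[str, Path]
) -> None:
    """Write clustered inversions with member and carrier sets."""
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tchrom\tspan_start\tspan_end\tn_members\tmembers"
            "\tcarriers\tcategory\n"
        )
        for clu in clusters:
            fh.write(
                f"{clu.cluster_id}\t{clu.chrom}\t{clu.span_start}\t{clu.span_end}"
                f"\t{len(clu.members)}\t{','.join(sorted(clu.members))}"
                f"\t{','.join(sorted(clu.carriers_union))}\t{clu.category.value}\n"
            )


def read_cluster_table(path: Union[str, Path]) -> List["InversionCluster"]:
    """Read a cluster table written by :func:`write_cluster_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"members": str, "carriers": str})
    out = []
    for row in df.itertuples(index=False):
        members = row.members if isinstance(row.members, str) else ""
        carriers = row.carriers if isinstance(row.carriers, str) else ""
        out.append(
            InversionCluster(
                cluster_id=str(row.cluster_id),
                chrom=str(row.chrom),
                span_start=int(row.span_start),
                span_end=int(row.span_end),
                members=frozenset(m for m in members.split(",") if m),
                carriers_union=frozenset(c for c in carriers.split(",") if c),
                category=SpeciesCategory(row.category)
                if hasattr(row, "category")
                else SpeciesCategory.UNRESOLVED,
            )
        )
    return out


def read_support_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a breakpoint-support table (inversions x accessions).

    Cells hold the two breakpoint states joined by '|', e.g.
    ``supported|nodata``; the result holds (left, right) BreakpointState
    tuples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)

    def _parse(cell: str):
        parts = str(cell).split("|")
        if len(parts) != 2:
            raise ValueError(f"malformed support cell {cell!r}")
        return (BreakpointState(parts[0]), BreakpointState(parts[1]))

    return df.map(_parse)


def write_support_table(support: pd.DataFrame, path: Union[str, Path]) -> None:
    formatted = support.map(lambda cell: f"{cell[0].value}|{cell[1].value}")
    formatted.to_csv(path, sep="\t")


def write_genotype_table(genotypes: pd.DataFrame, path: Union[str, Path]) -> None:
    genotypes.map(
        lambda v: v.value if isinstance(v, InversionGenotype) else v
    ).to_csv(path, sep="\t")


def read_genotype_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    return df.map(InversionGenotype)


def write_presence_matrix(matrix: pd.DataFrame, path: Union[str, Path]) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_presence_matrix(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
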