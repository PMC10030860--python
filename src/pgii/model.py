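"""Domain types shared across the pan-genome inversion index pipeline.

Coordinates are 1-based and inclusive throughout the in-memory model
(the convention of VCF and of SyRI-style structural-variant callers);
conversion to 0-based half-open BED coordinates happens only at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Tuple

MIN_INVERSION_LENGTH = 100


class Species(str, Enum):
    SATIVA = "sativa"
    RUFIPOGON = "rufipogon"
    PUNCTATA = "punctata"


class Group(str, Enum):
    """Major varietal groups of Asian rice, plus admixed and the wild outgroups."""

    GJ = "GJ"
    XI = "XI"
    CA = "cA"
    CB = "cB"
    ADMIXED = "admixed"
    OUTGROUP = "outgroup"


#: Canonical subpopulation -> group lookup for the K = 15 structure of
#: O. sativa (Geng/japonica, Xian/indica, circum-Aus, circum-Basmati),
#: plus admixed material and the two wild outgroup species.
SUBPOPULATION_GROUP: Dict[str, Group] = {
    "GJ-temp": Group.GJ,
    "GJ-trop1": Group.GJ,
    "GJ-trop2": Group.GJ,
    "GJ-subtrop": Group.GJ,
    "XI-1A": Group.XI,
    "XI-1B1": Group.XI,
    "XI-1B2": Group.XI,
    "XI-2": Group.XI,
    "XI-3": Group.XI,
    "XI-adm": Group.XI,
    "cA1": Group.CA,
    "cA2": Group.CA,
    "cA3": Group.CA,
    "cB1": Group.CB,
    "cB2": Group.CB,
    "admixed": Group.ADMIXED,
    "outgroup": Group.OUTGROUP,
}


class SpeciesCategory(str, Enum):
    """Ancestral-state category of an inversion cluster.

    S  - segregating in O. sativa only (S1: reference orientation ancestral,
         S2: reference orientation derived, S3: fixed derived in O. sativa);
    SR - segregating in both O. sativa and O. rufipogon (SR1/SR2 by the
         reference's ancestral/derived orientation);
    R  - O. rufipogon specific;
    P  - O. punctata specific, or fixed in the AA lineage (ancestral state
         not resolvable with these outgroups).
    """

    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    SR1 = "SR1"
    SR2 = "SR2"
    R = "R"
    P = "P"
    UNRESOLVED = "UNRESOLVED"

    @property
    def major(self) -> str:
        if self.value.startswith("SR"):
            return "SR"
        if self.value.startswith("S"):
            return "S"
        return self.value


class PopulationCategory(str, Enum):
    GENOME_SPECIFIC = "genome_specific"
    SUBPOPULATION_SPECIFIC = "subpopulation_specific"
    GROUP_SPECIFIC = "group_specific"
    GROUP_SHARED = "group_shared"


class BreakpointState(str, Enum):
    SUPPORTED = "supported"
    ABSENT = "absent"
    NODATA = "nodata"


class InversionGenotype(str, Enum):
    INV = "INV"
    NO_INV = "NO_INV"
    INV_DEL = "INV_DEL"
    NA = "NA"


@dataclass(frozen=True)
class GenomeRecord:
    """One panel member: a genome assembly compared against the reference."""

    genome_id: str
    species: Species
    group: Group
    subpopulation: str
    chrom_lengths: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        expected = SUBPOPULATION_GROUP.get(self.subpopulation)
        if expected is not None and expected != self.group:
            raise ValueError(
                f"subpopulation {self.subpopulation!r} belongs to group "
                f"{expected.value}, not {self.group.value}"
            )
        if self.chrom_lengths is not None:
            for chrom, length in self.chrom_lengths.items():
                if length <= 0:
                    raise ValueError(f"chromosome {chrom} has non-positive length")


@dataclass(frozen=True)
class InversionCall:
    """A single inversion observed in one query genome versus the reference."""

    query_genome: str
    chrom: str
    ref_start: int  # 1-based, inclusive
    ref_end: int  # 1-based, inclusive
    query_start: Optional[int] = None
    query_end: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError(
                f"ref_start {self.ref_start} > ref_end {self.ref_end} on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass
class NonredundantInversion:
    """Merged representative of near-identical calls across genomes.

    The representative interval is the medoid member call: the call
    minimizing the summed start+end coordinate distance to all members.
    """

    inv_id: str
    chrom: str
    ref_start: int
    ref_end: int
    carriers: FrozenSet[str]
    member_calls: List[InversionCall] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def breakpoints(self) -> Tuple[int, int]:
        return (self.ref_start, self.ref_end)


@dataclass
class InversionCluster:
    """A group of non-redundant inversions with >=80% reciprocal overlap."""

    cluster_id: str
    chrom: str
    span_start: int
    span_end: int
    members: FrozenSet[str]
    carriers_union: FrozenSet[str]
    category: SpeciesCategory = SpeciesCategory.UNRESOLVED

    @property
    def length(self) -> int:
        return self.span_end - self.span_start + 1


@dataclass(frozen=True)
class Interval:
    """Generic 0-based half-open annotation interval (TE, gene, centromere...)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def vcf_to_bed(ref_start: int, ref_end: int) -> Tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return ref_start - 1, ref_end


def bed_to_vcf(start: int, end: int) -> Tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end
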