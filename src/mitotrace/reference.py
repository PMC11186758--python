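"""Mitochondrial reference handling: genomes, SNP tables and feature annotation.

The central object is the :class:`SnpTable` — the catalogue of fixed
substitution differences between the maternal and paternal mitochondrial
genomes of a hybrid cross. Read parental origin in the embryo is later
assigned at exactly these positions, so the table must contain only
trustworthy substitutions: alignment columns with gaps or Ns, and
mismatches in the immediate neighbourhood of a gap (which are frequently
alignment artifacts rather than biology), are excluded.

Coordinates are 1-based on the maternal genome throughout, matching the
alignment reference used for the embryo RNA-seq data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignment import OP_MATCH, aligned_columns, banded_global_align

__all__ = [
    "MitoGenome",
    "SnpRecord",
    "SnpTable",
    "Feature",
    "FeatureAnnotation",
    "BIOTYPES",
    "BIOTYPE_PRECEDENCE",
    "derive_snp_table",
    "annotate_snps",
]

BIOTYPES = ("mt-tRNA", "mt-rRNA", "mt-mRNA", "control_region", "intergenic")
#: overlap resolution order — tRNA genes punctuate the mitochondrial transcript
BIOTYPE_PRECEDENCE = ("mt-tRNA", "mt-rRNA", "mt-mRNA", "control_region")

_VALID_BASES = set("ACGTN")
#: mismatch columns this close (in alignment columns) to a gap are dropped
GAP_EXCLUSION_BP = 3


@dataclass(frozen=True)
class MitoGenome:
    """A mitochondrial genome in heavy-strand (reference) orientation."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise ValueError(f"genome {self.name!r} is empty")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"genome {self.name!r} contains non-DNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SnpRecord:
    """One substitution difference, 1-based on the maternal genome."""

    position: int
    maternal_allele: str
    paternal_allele: str
    feature_id: str | None = None
    biotype: str = "intergenic"

    def __post_init__(self) -> None:
        if self.maternal_allele == self.paternal_allele:
            raise ValueError(f"position {self.position}: alleles are identical")
        for allele in (self.maternal_allele, self.paternal_allele):
            if allele not in "ACGT" or len(allele) != 1:
                raise ValueError(f"position {self.position}: invalid allele {allele!r}")
        if self.position < 1:
            raise ValueError(f"invalid 1-based position {self.position}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")


@dataclass
class SnpTable:
    """Ordered catalogue of substitutions between two parental genomes."""

    records: list[SnpRecord]
    maternal_name: str = "maternal"
    paternal_name: str = "paternal"

    def __post_init__(self) -> None:
        positions = [r.position for r in self.records]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("SNP positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.position for r in self.records], dtype=np.int64)

    @property
    def maternal_alleles(self) -> list[str]:
        return [r.maternal_allele for r in self.records]

    @property
    def paternal_alleles(self) -> list[str]:
        return [r.paternal_allele for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [r.position for r in self.records],
                "maternal_allele": self.maternal_alleles,
                "paternal_allele": self.paternal_alleles,
                "feature_id": [r.feature_id for r in self.records],
                "biotype": [r.biotype for r in self.records],
            }
        )


@dataclass(frozen=True)
class Feature:
    """An annotated interval, 1-based inclusive on the maternal genome."""

    id: str
    start: int
    end: int
    strand: str
    biotype: str
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id!r}: invalid strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"feature {self.id!r}: unknown biotype {self.biotype!r}")
        if self.start > self.end and not self.wraps_origin:
            raise ValueError(
                f"feature {self.id!r}: start {self.start} > end {self.end} "
                "without the circular-origin flag"
            )
        if min(self.start, self.end) < 1:
            raise ValueError(f"feature {self.id!r}: coordinates must be >= 1")

    def contains(self, position: int, genome_length: int | None = None) -> bool:
        if not self.wraps_origin:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("genome_length required for an origin-spanning feature")
        return genome_length - self.start + 1 + self.end


@dataclass
class FeatureAnnotation:
    """Feature set on a mitochondrial genome."""

    features: list[Feature]
    genome_name: str = "chrM"
    genome_length: int | None = None

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def by_id(self) -> dict[str, Feature]:
        return {f.id: f for f in self.features}

    def by_biotype(self, biotype: str) -> list[Feature]:
        return [f for f in self.features if f.biotype == biotype]

    def validate_against(self, genome: MitoGenome) -> None:
        for f in self.features:
            if max(f.start, f.end) > len(genome):
                raise ValueError(
                    f"feature {f.id!r} extends past genome {genome.name!r} "
                    f"({max(f.start, f.end)} > {len(genome)})"
                )


def derive_snp_table(
    maternal: MitoGenome,
    paternal: MitoGenome,
    band_width: int = 256,
    *,
    full_dp: bool = False,
) -> SnpTable:
    """Catalogue substitution differences between two parental genomes.

    The genomes are globally aligned (banded Needleman-Wunsch, match +1,
    mismatch -1, gap open -5, gap extend -1) and every aligned column with
    two different unambiguous bases becomes a :class:`SnpRecord` on the
    maternal coordinate system. Columns containing a gap or an N, and
    mismatch columns within ``GAP_EXCLUSION_BP`` columns of a gap, are
    excluded. Indels are deliberately not reported.
    """
    ops, _score = banded_global_align(
        maternal.sequence, paternal.sequence, band=band_width, full_dp=full_dp
    )
    pos_a, pos_b = aligned_columns(ops)
    is_gap = ops != OP_MATCH
    near_gap = np.zeros(len(ops), dtype=bool)
    if is_gap.any():
        gap_idx = np.flatnonzero(is_gap)
        for offset in range(-GAP_EXCLUSION_BP, GAP_EXCLUSION_BP + 1):
            shifted = gap_idx + offset
            shifted = shifted[(shifted >= 0) & (shifted < len(ops))]
            near_gap[shifted] = True

    records = []
    mat_seq, pat_seq = maternal.sequence, paternal.sequence
    for idx in np.flatnonzero(~is_gap & ~near_gap):
        base_m = mat_seq[pos_a[idx] - 1]
        base_p = pat_seq[pos_b[idx] - 1]
        if base_m != base_p and base_m != "N" and base_p != "N":
            records.append(
                SnpRecord(position=int(pos_a[idx]), maternal_allele=base_m, paternal_allele=base_p)
            )
    return SnpTable(records=records, maternal_name=maternal.name, paternal_name=paternal.name)


def _assign_biotype(
    position: int, trees: dict[str, IntervalTree], wrapping: Sequence[Feature]
) -> tuple[str | None, str]:
    for biotype in BIOTYPE_PRECEDENCE:
        tree = trees.get(biotype)
        if tree is not None:
            hits = tree[position]
            if hits:
                # deterministic tie-break inside one biotype: leftmost, then id
                best = min(hits, key=lambda iv: (iv.begin, iv.data))
                return best.data, biotype
        for f in wrapping:
            if f.biotype == biotype and f.contains(position):
                return f.id, biotype
    return None, "intergenic"


def annotate_snps(table: SnpTable, ann: FeatureAnnotation) -> SnpTable:
    """Label each SNP with the feature and biotype containing its position.

    Overlaps are resolved by the precedence mt-tRNA > mt-rRNA > mt-mRNA >
    control_region; positions inside no feature become ``intergenic``.
    """
    trees: dict[str, IntervalTree] = {}
    wrapping = [f for f in ann.features if f.wraps_origin]
    for f in ann.features:
        if f.wraps_origin:
            continue
        trees.setdefault(f.biotype, IntervalTree()).addi(f.start, f.end + 1, f.id)

    new_records = []
    for rec in table.records:
        feature_id, biotype = _assign_biotype(rec.position, trees, wrapping)
        new_records.append(dataclasses.replace(rec, feature_id=feature_id, biotype=biotype))
    return SnpTable(
        records=new_records,
        maternal_name=table.maternal_name,
        paternal_name=table.paternal_name,
    )
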