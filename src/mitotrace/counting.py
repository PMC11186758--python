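"""Per-SNP allele counting from single-embryo alignments.

Each embryo's RNA-seq alignment against the maternal mitochondrial
reference is reduced to a 4-base count at every SNP position, after
mapping-quality, base-quality and duplicate filtering. Heteroplasmy is
then 1 minus the maternal allele frequency: the fraction of transcripts
that cannot have come from the maternal mitochondrial genome.

"Uniquely mapped" is operationalized as a mapping-quality threshold
(default 30), which covers both the STAR unique-mapper convention
(MAPQ 255) and general aligners. Overlapping mate pairs are counted once
per site (fragment-level deduplication), the standard practice in
allele-specific expression so a fragment never votes twice.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pysam

from .reference import MitoGenome, SnpTable

__all__ = [
    "PileupFilters",
    "AlleleCountTensor",
    "HeteroplasmyMatrix",
    "pileup_allele_counts",
    "compute_heteroplasmy",
    "BASES",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

MASK_OK = 0
MASK_LOW_COVERAGE = 1
MASK_REASONS = {MASK_OK: "ok", MASK_LOW_COVERAGE: "low_coverage"}


@dataclass(frozen=True)
class PileupFilters:
    """Read- and site-level filters applied before counting."""

    min_base_quality: int = 20
    min_mapping_quality: int = 30
    min_site_coverage: int = 20
    count_duplicates: bool = False

    def __post_init__(self) -> None:
        for name in ("min_base_quality", "min_mapping_quality", "min_site_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AlleleCountTensor:
    """counts[embryo, snp, base] with base order A, C, G, T."""

    embryo_ids: list[str]
    positions: np.ndarray  # 1-based SNP positions, sorted
    counts: np.ndarray  # (n_embryos, n_snps, 4) non-negative ints

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        expected = (len(self.embryo_ids), len(self.positions), 4)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if (self.counts < 0).any():
            raise ValueError("negative allele counts")

    @property
    def depth(self) -> np.ndarray:
        """Per-site depth: the sum over the four bases."""
        return self.counts.sum(axis=2)


@dataclass
class HeteroplasmyMatrix:
    """Per-embryo, per-SNP paternal-allele fraction with a coverage mask."""

    embryo_ids: list[str]
    positions: np.ndarray
    values: np.ndarray  # (n_embryos, n_snps) in [0,1]; undefined where masked
    coverage: np.ndarray  # (n_embryos, n_snps) int depth
    mask: np.ndarray  # bool; True = masked (do not use)
    mask_reason: np.ndarray  # int codes, see MASK_REASONS

    def __post_init__(self) -> None:
        unmasked = self.values[~self.mask]
        if unmasked.size and ((unmasked < 0) | (unmasked > 1)).any():
            raise ValueError("unmasked heteroplasmy values must lie in [0, 1]")

    @property
    def masked_values(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)


def _check_reference(aln: pysam.AlignmentFile, genome: MitoGenome) -> None:
    names = list(aln.references)
    if genome.name not in names:
        raise ValueError(
            f"alignment references {names} do not include SNP-table genome {genome.name!r}"
        )
    length = aln.get_reference_length(genome.name)
    if length != len(genome):
        raise ValueError(
            f"reference {genome.name!r} length {length} != genome length {len(genome)}"
        )


def pileup_allele_counts(
    alignments: Mapping[str, str | os.PathLike],
    snps: SnpTable,
    filters: PileupFilters = PileupFilters(),
    genome: MitoGenome | None = None,
) -> AlleleCountTensor:
    """Count observed bases at every SNP position for each embryo.

    ``alignments`` maps embryo id -> SAM/BAM path aligned to the maternal
    mitochondrial reference. Reads failing the mapping-quality filter,
    marked duplicates (unless ``count_duplicates``), secondary and
    supplementary records are excluded entirely; bases below
    ``min_base_quality`` and sites where the read has a deletion or
    reference skip contribute nothing. Overlapping bases of a read pair
    are counted once.
    """
    embryo_ids = list(alignments)
    positions = snps.positions
    pos_index = {int(p) - 1: i for i, p in enumerate(positions)}  # 0-based ref -> snp idx
    counts = np.zeros((len(embryo_ids), len(positions), 4), dtype=np.int64)

    for e_idx, embryo in enumerate(embryo_ids):
        path = str(alignments[embryo])
        mode = "rb" if path.endswith(".bam") else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as aln:
            if genome is not None:
                _check_reference(aln, genome)
            seen: set[tuple[int, str]] = set()
            for read in aln.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.is_duplicate and not filters.count_duplicates:
                    continue
                if read.mapping_quality < filters.min_mapping_quality:
                    continue
                quals = read.query_qualities
                seq = read.query_sequence
                if seq is None:
                    continue
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    snp_idx = pos_index.get(rpos)
                    if snp_idx is None:
                        continue
                    if quals is not None and quals[qpos] < filters.min_base_quality:
                        continue
                    base = seq[qpos]
                    b_idx = _BASE_INDEX.get(base)
                    if b_idx is None:
                        continue
                    key = (snp_idx, read.query_name)
                    if key in seen:
                        continue  # overlapping mate already counted this fragment
                    seen.add(key)
                    counts[e_idx, snp_idx, b_idx] += 1
    return AlleleCountTensor(embryo_ids=embryo_ids, positions=positions, counts=counts)


def compute_heteroplasmy(
    counts: AlleleCountTensor,
    snps: SnpTable,
    filters: PileupFilters = PileupFilters(),
) -> HeteroplasmyMatrix:
    """Heteroplasmy = 1 - maternal allele frequency, per embryo and SNP.

    The denominator is the full four-base depth, so sequencing errors
    toward third alleles inflate heteroplasmy symmetrically rather than
    vanishing. Sites with depth below ``min_site_coverage`` are masked.
    """
    if not np.array_equal(counts.positions, snps.positions):
        raise ValueError("AlleleCountTensor and SnpTable positions differ")
    maternal_idx = np.array([_BASE_INDEX[a] for a in snps.maternal_alleles])
    depth = counts.depth
    maternal_counts = np.take_along_axis(
        counts.counts, maternal_idx[None, :, None], axis=2
    )[:, :, 0]
    mask = depth < filters.min_site_coverage
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 - maternal_counts / depth
    values = np.where(mask, np.nan, values)
    reason = np.where(mask, MASK_LOW_COVERAGE, MASK_OK)
    return HeteroplasmyMatrix(
        embryo_ids=counts.embryo_ids,
        positions=counts.positions,
        values=values,
        coverage=depth,
        mask=mask,
        mask_reason=reason,
    )
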