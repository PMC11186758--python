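"""Small-RNA biotype accounting and tRNA fragmentation profiling.

Sperm small-RNA libraries are dominated by fragments of longer parents
(tRNAs, rRNAs) plus mature miRNAs and piRNAs. Reads are annotated by
matching the read sequence as a substring of reference sequences,
allowing a bounded number of substitutions (no indels — the reads are
16-45 nt), with the annotation cascade miRNA > rRNA > tRNA > piRNA.
The matched parent's nuclear/mitochondrial tag gives the fragment's
origin; a read matching both compartments of the winning biotype is
ambiguous.

Fragment positional classes on a mature tRNA of length L use a 3-nt end
tolerance: a read is a 5' fragment if it starts in the first 3 nt and
stops before the last 3, a 3' fragment if it reaches the last 3 nt but
starts after the first 3, full-length if it does both, internal
otherwise.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceSeq",
    "ReferenceBundle",
    "SmallRnaCountMatrix",
    "FragmentProfile",
    "assign_reads",
    "rpm_normalize",
    "filter_fragments",
    "fragmentation_profile",
    "biotype_log2fc",
]

#: annotation cascade: first matching class wins
CLASS_PRECEDENCE = ("miRNA", "rRNA", "tRNA", "piRNA")
#: biotype label produced by each reference class
CLASS_BIOTYPE = {"miRNA": "miRNA", "rRNA": "rsRNA", "tRNA": "tsRNA", "piRNA": "piRNA"}
ORIGINS = ("nuclear", "mitochondrial", "ambiguous")
END_TOLERANCE = 3
LOG2FC_EPS = 0.01  # RPM pseudocount


@dataclass(frozen=True)
class ReferenceSeq:
    id: str
    sequence: str
    ref_class: str  # one of CLASS_PRECEDENCE
    origin: str  # nuclear | mitochondrial

    def __post_init__(self) -> None:
        if self.ref_class not in CLASS_PRECEDENCE:
            raise ValueError(f"unknown reference class {self.ref_class!r}")
        if self.origin not in ("nuclear", "mitochondrial"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class ReferenceBundle:
    refs: list[ReferenceSeq]

    def __post_init__(self) -> None:
        if not self.refs:
            raise ValueError("empty reference bundle")
        self._encoded = [
            (r, np.frombuffer(r.sequence.upper().encode(), dtype=np.uint8)) for r in self.refs
        ]

    def by_class(self, ref_class: str) -> list[tuple[ReferenceSeq, np.ndarray]]:
        return [(r, e) for r, e in self._encoded if r.ref_class == ref_class]

    def by_id(self) -> dict[str, ReferenceSeq]:
        return {r.id: r for r in self.refs}

    @classmethod
    def from_fastas(cls, tagged_paths: Iterable[tuple[str, str, str]]) -> "ReferenceBundle":
        """Build from (path, ref_class, origin) triples of FASTA files."""
        refs = []
        for path, ref_class, origin in tagged_paths:
            for rec in SeqIO.parse(str(path), "fasta"):
                refs.append(ReferenceSeq(rec.id, str(rec.seq).upper(), ref_class, origin))
        return cls(refs)


@dataclass
class SmallRnaCountMatrix:
    """Unique read sequences x samples, with per-sequence annotation.

    ``seq_info`` columns: sequence, length, biotype, origin, parent_id,
    offset (1-based start of the best match within the parent, 0 when
    unassigned). ``rpm`` is populated by :func:`rpm_normalize`.
    """

    seq_info: pd.DataFrame
    counts: pd.DataFrame
    rpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.seq_info.index.equals(self.counts.index):
            raise ValueError("seq_info and counts must share an index")
        if (self.seq_info["length"] < 1).any():
            raise ValueError("sequence lengths must be >= 1")

    def biotype_fractions(self) -> pd.DataFrame:
        """Per-sample fraction of reads in each biotype (columns sum to 1)."""
        totals = self.counts.groupby(self.seq_info["biotype"]).sum()
        return totals / totals.sum(axis=0)


def _best_match(read: np.ndarray, refs, max_mismatch: int):
    """Best (parent_id, offset, mismatches, origins) over one reference class."""
    m = len(read)
    best_mm = max_mismatch + 1
    best: tuple[str, int] | None = None
    origins: set[str] = set()
    for ref, enc in refs:
        L = len(enc)
        if L < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, m)
        mism = (windows != read).sum(axis=1)
        idx = int(mism.argmin())
        mm = int(mism[idx])
        if mm <= max_mismatch:
            origins.add(ref.origin)
            if mm < best_mm:
                best_mm = mm
                best = (ref.id, idx + 1)
    if best is None:
        return None
    return best[0], best[1], best_mm, origins


def assign_reads(
    reads: Mapping[str, str | os.PathLike | Sequence[str]],
    refs: ReferenceBundle,
    max_mismatch: int = 2,
) -> SmallRnaCountMatrix:
    """Annotate reads against the reference bundle and count per sample.

    ``reads`` maps sample id -> FASTQ path (optionally gzipped) or an
    iterable of read sequences. Unique read sequences are matched as
    substrings of the references with at most ``max_mismatch``
    substitutions, classes tried in the precedence order; unmatched reads
    are kept with biotype ``other``.
    """
    sample_ids = list(reads)
    seq_counts: dict[str, np.ndarray] = {}
    for s_idx, sample in enumerate(sample_ids):
        src = reads[sample]
        if isinstance(src, (str, os.PathLike)):
            opener = gzip.open if str(src).endswith(".gz") else open
            with opener(str(src), "rt") as fh:
                seqs = [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]
        else:
            seqs = [s.upper() for s in src]
        for s in seqs:
            if s not in seq_counts:
                seq_counts[s] = np.zeros(len(sample_ids), dtype=np.int64)
            seq_counts[s][s_idx] += 1

    sequences = sorted(seq_counts)
    info_rows = []
    for s in sequences:
        enc = np.frombuffer(s.encode(), dtype=np.uint8)
        biotype, origin, parent, offset = "other", "nuclear", None, 0
        for ref_class in CLASS_PRECEDENCE:
            hit = _best_match(enc, refs.by_class(ref_class), max_mismatch)
            if hit is not None:
                parent, offset, _mm, origins = hit
                biotype = CLASS_BIOTYPE[ref_class]
                origin = "ambiguous" if len(origins) > 1 else next(iter(origins))
                break
        info_rows.append((s, len(s), biotype, origin, parent, offset))

    index = pd.RangeIndex(len(sequences))
    seq_info = pd.DataFrame(
        info_rows, index=index,
        columns=["sequence", "length", "biotype", "origin", "parent_id", "offset"],
    )
    counts = pd.DataFrame(
        np.stack([seq_counts[s] for s in sequences]) if sequences else
        np.zeros((0, len(sample_ids)), dtype=np.int64),
        index=index, columns=sample_ids,
    )
    return SmallRnaCountMatrix(seq_info=seq_info, counts=counts)


def rpm_normalize(matrix: SmallRnaCountMatrix) -> SmallRnaCountMatrix:
    """Scale each sample to reads-per-million (column sums of 1e6)."""
    totals = matrix.counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"cannot RPM-normalize all-zero samples: {empty}")
    rpm = matrix.counts / totals * 1e6
    return SmallRnaCountMatrix(seq_info=matrix.seq_info.copy(), counts=matrix.counts.copy(), rpm=rpm)


def filter_fragments(
    matrix: SmallRnaCountMatrix,
    min_rpm: float = 0.01,
    min_len: int = 16,
    max_len: int = 45,
) -> SmallRnaCountMatrix:
    """Retain sequences with RPM >= ``min_rpm`` in every sample and
    length in [``min_len``, ``max_len``] inclusive."""
    if matrix.rpm is None:
        matrix = rpm_normalize(matrix)
    keep = (
        (matrix.rpm >= min_rpm).all(axis=1)
        & matrix.seq_info["length"].between(min_len, max_len)
    )
    return SmallRnaCountMatrix(
        seq_info=matrix.seq_info[keep].copy(),
        counts=matrix.counts[keep].copy(),
        rpm=matrix.rpm[keep].copy(),
    )


@dataclass
class FragmentProfile:
    """Positional coverage along one mature tRNA with fragment fractions."""

    trna_id: str
    length: int
    coverage: np.ndarray  # 1..L, RPM-weighted
    f5: float
    f3: float
    f_full: float
    f_internal: float

    def __post_init__(self) -> None:
        total = self.f5 + self.f3 + self.f_full + self.f_internal
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fragment fractions sum to {total}, not 1")
        if (np.asarray(self.coverage) < 0).any():
            raise ValueError("negative positional coverage")


def classify_fragment(start: int, end: int, length: int, tol: int = END_TOLERANCE) -> str:
    """Classify a read spanning 1-based [start, end] on a tRNA of ``length``."""
    at5 = start <= tol
    at3 = end >= length - tol
    if at5 and at3:
        return "full"
    if at5:
        return "5p"
    if at3:
        return "3p"
    return "internal"


def fragmentation_profile(
    reads: Iterable[tuple[int, int, float]],
    trna_id: str,
    trna_length: int,
) -> FragmentProfile:
    """Build the positional profile of one tRNA from (start, read_length,
    weight) triples; ``start`` is the 1-based offset within the mature
    tRNA and ``weight`` is usually the read's RPM. Reads extending past
    the 3' end are clipped with a warning."""
    import warnings

    coverage = np.zeros(trna_length)
    w5 = w3 = wfull = winternal = 0.0
    for start, read_len, weight in reads:
        if start < 1:
            raise ValueError(f"invalid 1-based offset {start}")
        end = start + read_len - 1
        if end > trna_length:
            warnings.warn(
                f"read at {trna_id}:{start} extends past the mature 3' end; clipped"
            )
            end = trna_length
        coverage[start - 1 : end] += weight
        klass = classify_fragment(start, end, trna_length)
        if klass == "5p":
            w5 += weight
        elif klass == "3p":
            w3 += weight
        elif klass == "full":
            wfull += weight
        else:
            winternal += weight
    total = w5 + w3 + wfull + winternal
    if total == 0:
        raise ValueError(f"no weighted reads for {trna_id}")
    return FragmentProfile(
        trna_id=trna_id, length=trna_length, coverage=coverage,
        f5=w5 / total, f3=w3 / total, f_full=wfull / total, f_internal=winternal / total,
    )


def biotype_log2fc(
    matrix: SmallRnaCountMatrix,
    group_a: list[str],
    group_b: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
    eps: float = LOG2FC_EPS,
) -> pd.DataFrame:
    """Per-sequence log2 fold change (group A over group B) on RPM, with a
    label-permutation p-value. Plumbing for exploratory contrast, not a
    replacement for a count-model differential test."""
    if matrix.rpm is None:
        matrix = rpm_normalize(matrix)
    rpm = matrix.rpm
    for col in [*group_a, *group_b]:
        if col not in rpm.columns:
            raise ValueError(f"unknown sample {col!r}")
    a = rpm[group_a].to_numpy()
    b = rpm[group_b].to_numpy()
    obs = np.log2((a.mean(axis=1) + eps) / (b.mean(axis=1) + eps))

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b], axis=1)
    n_a = len(group_a)
    exceed = np.zeros(len(obs), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[1])
        pa = pooled[:, perm[:n_a]]
        pb = pooled[:, perm[n_a:]]
        stat = np.log2((pa.mean(axis=1) + eps) / (pb.mean(axis=1) + eps))
        exceed += np.abs(stat) >= np.abs(obs) - 1e-12
    pvals = (1 + exceed) / (n_perm + 1)
    return pd.DataFrame(
        {
            "sequence": matrix.seq_info["sequence"].to_numpy(),
            "biotype": matrix.seq_info["biotype"].to_numpy(),
            "origin": matrix.seq_info["origin"].to_numpy(),
            "log2fc": obs,
            "p_value": pvals,
        },
        index=matrix.seq_info.index,
    )
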