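"""Synthetic data with the statistical structure of a hybrid-embryo study.

Everything the pipeline consumes can be generated here: a pair of
near-identical circular mitochondrial haplotypes differing at a known set
of substitutions, single-embryo read sets drawn as maternal/paternal
mixtures with per-feature paternal fractions, nuclear count matrices with
sex-specific Y-gene expression and a boosted male subpopulation, and
small-RNA fragment mixtures over tRNA references. Each generator returns
the ground truth alongside its output so every downstream estimate can be
checked against what was simulated.

The default configuration encodes the study design this package targets:
416 substitutions on a 16.3 kb genome, a 1% baseline paternal fraction,
mt-tRNA paternal boosts of 12x / 2x / 3.5x in the three treatment groups
over low-fat-diet controls, 40 embryos per group at a mean site depth of
500, and a 30% boosted subpopulation among treatment males. Per-embryo
feature-level paternal fractions are drawn from a Beta distribution with
the group mean and a coefficient of variation of 0.3 — heteroplasmy
transmission through the oocyte bottleneck is strongly variable between
individual embryos, and a point-mass fraction would make embryo-level
resampling degenerate.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .counting import AlleleCountTensor, BASES
from .embryos import ExpressionMatrix
from .fragments import ReferenceBundle, ReferenceSeq
from .reference import (
    Feature,
    FeatureAnnotation,
    MitoGenome,
    SnpRecord,
    SnpTable,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "Y_GENES",
    "DEFAULT_GROUP_BOOSTS",
    "draw_embryo_fractions",
    "simulate_hybrid_genomes",
    "simulate_embryo_reads",
    "simulate_allele_counts",
    "simulate_embryo_counts",
    "simulate_small_rna_refs",
    "simulate_small_rna_reads",
]

_COMPLEMENTABLE = np.frombuffer(b"ACGT", dtype=np.uint8)

#: group -> mt-tRNA paternal boost factor over the baseline fraction.
DEFAULT_GROUP_BOOSTS = {"LFD": 1.0, "HFD_A": 12.0, "HFD_B": 2.0, "HFD_female": 3.5}

Y_GENES = ("Ddx3y", "Eif2s3y", "Uty", "Kdm5d")


@dataclass
class SimConfig:
    """All knobs of the generator; every random draw derives from ``seed``."""

    seed: int = 0
    genome_length: int = 16300
    n_snps: int = 416
    min_snp_spacing: int = 5
    n_embryos_per_group: int = 40
    sex_ratio: float = 0.5  # fraction male
    mean_depth: float = 500.0  # reads covering each mitochondrial base
    read_length: int = 150
    error_rate: float = 0.001  # per-base substitution probability
    paternal_baseline: float = 0.01
    group_boosts: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_BOOSTS))
    boost_biotype: str = "mt-tRNA"
    embryo_cv: float = 0.3  # between-embryo CV of the paternal fraction
    hfd_a_fraction: float = 0.30
    y_gene_cpm: float = 20.0  # per Y gene, male mean
    n_nuclear_genes: int = 2000
    nb_dispersion: float = 0.1
    library_size: int = 1_000_000
    mito_expression_boost: float = 3.0  # subpopulation mt-tRNA gene boost
    fragment_mix: tuple = (0.6, 0.3, 0.1)  # (f5, f3, f_full)

    def __post_init__(self) -> None:
        for name in ("sex_ratio", "error_rate", "paternal_baseline", "hfd_a_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.fragment_mix) - 1.0) > 1e-9:
            raise ValueError("fragment_mix must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """A named, reproducible substream of the master seed."""
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF  # stable across processes
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class SimTruth:
    """Ground truth serialized alongside generated outputs."""

    embryo_group: dict = field(default_factory=dict)
    embryo_sex: dict = field(default_factory=dict)
    embryo_subpop: dict = field(default_factory=dict)
    feature_paternal_fraction: dict = field(default_factory=dict)  # embryo -> {feature: p}
    snp_positions: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _mito_architecture(genome_length: int) -> list[tuple[str, str, int]]:
    """(id, biotype, length) tiles mimicking mammalian mtDNA architecture:
    22 tRNA genes punctuating 2 rRNAs and 13 protein-coding genes, plus a
    control region. Scaled to fill ``genome_length``."""
    trna_len = 70
    n_trna, n_rrna, n_mrna = 22, 2, 13
    control_len = max(200, int(round(genome_length * 0.054)))  # ~880 bp at 16.3 kb
    rrna_lens = [
        max(100, int(round(genome_length * 0.058))),  # small subunit, ~950
        max(150, int(round(genome_length * 0.095))),  # large subunit, ~1550
    ]
    remaining = genome_length - n_trna * trna_len - sum(rrna_lens) - control_len
    mrna_len = remaining // n_mrna
    if mrna_len < trna_len:
        raise ValueError(f"genome_length {genome_length} too short for the mtDNA layout")
    tiles: list[tuple[str, str, int]] = []
    trna_i = mrna_i = 0
    # opening block mirrors the canonical gene order: tRNA, rRNA, tRNA, rRNA
    tiles.append((f"mt-T{trna_i + 1}", "mt-tRNA", trna_len)); trna_i += 1
    tiles.append(("mt-Rnr1", "mt-rRNA", rrna_lens[0]))
    tiles.append((f"mt-T{trna_i + 1}", "mt-tRNA", trna_len)); trna_i += 1
    tiles.append(("mt-Rnr2", "mt-rRNA", rrna_lens[1]))
    # alternate remaining tRNAs with the 13 protein-coding genes
    while trna_i < n_trna or mrna_i < n_mrna:
        if trna_i < n_trna:
            tiles.append((f"mt-T{trna_i + 1}", "mt-tRNA", trna_len)); trna_i += 1
        if mrna_i < n_mrna:
            tiles.append((f"mt-M{mrna_i + 1}", "mt-mRNA", mrna_len)); mrna_i += 1
    tiles.append(("control_region", "control_region", control_len))
    return tiles


def _tile_annotation(genome_length: int) -> FeatureAnnotation:
    tiles = _mito_architecture(genome_length)
    features = []
    pos = 1
    for fid, biotype, length in tiles:
        end = min(pos + length - 1, genome_length)
        features.append(Feature(id=fid, start=pos, end=end, strand="+", biotype=biotype))
        pos = end + 1
    # stretch the control region to the genome end (absorbs rounding slack)
    last = features[-1]
    features[-1] = Feature(
        id=last.id, start=last.start, end=genome_length, strand="+", biotype=last.biotype
    )
    return FeatureAnnotation(features=features, genome_name="chrM_maternal",
                             genome_length=genome_length)


def _draw_spaced_positions(
    rng: np.random.Generator, n: int, length: int, spacing: int
) -> np.ndarray:
    """Uniformly distributed positions with a guaranteed minimum spacing.

    Classic contraction trick: draw n distinct positions in the range
    shortened by (n-1)(spacing-1), sort, and re-expand by (spacing-1) per
    rank — every admissible spaced configuration is equally likely."""
    slack = length - (n - 1) * (spacing - 1)
    if slack < n:
        raise ValueError(f"cannot place {n} positions with spacing {spacing} in {length} bp")
    base = np.sort(rng.choice(np.arange(1, slack + 1), size=n, replace=False))
    return base + np.arange(n) * (spacing - 1)


def simulate_hybrid_genomes(
    cfg: SimConfig,
) -> tuple[MitoGenome, MitoGenome, SnpTable, FeatureAnnotation]:
    """A random maternal genome, a paternal copy differing at ``n_snps``
    programmed substitutions (uniform placement, minimum spacing), the
    truth SNP table and a tiled mtDNA-like feature annotation."""
    rng = cfg.rng("genomes")
    maternal_arr = rng.choice(_COMPLEMENTABLE, size=cfg.genome_length)
    positions = _draw_spaced_positions(rng, cfg.n_snps, cfg.genome_length, cfg.min_snp_spacing)
    paternal_arr = maternal_arr.copy()
    records = []
    for p in positions:
        ref_base = maternal_arr[p - 1]
        alternatives = _COMPLEMENTABLE[_COMPLEMENTABLE != ref_base]
        alt_base = rng.choice(alternatives)
        paternal_arr[p - 1] = alt_base
        records.append(
            SnpRecord(position=int(p), maternal_allele=chr(ref_base), paternal_allele=chr(alt_base))
        )
    maternal = MitoGenome("chrM_maternal", maternal_arr.tobytes().decode())
    paternal = MitoGenome("chrM_paternal", paternal_arr.tobytes().decode())
    truth = SnpTable(records=records, maternal_name=maternal.name, paternal_name=paternal.name)
    return maternal, paternal, truth, _tile_annotation(cfg.genome_length)


def draw_embryo_fractions(
    cfg: SimConfig,
    annotation: FeatureAnnotation,
    group: str,
    n_embryos: int,
    rng: np.random.Generator,
) -> list[dict[str, float]]:
    """Per-embryo, per-feature true paternal fractions for one group.

    Features of ``cfg.boost_biotype`` get the group's boost over the
    baseline. Between-embryo variability enters as a single gamma
    multiplier per embryo (mean 1, CV ``cfg.embryo_cv``) shared across
    features: transmission through the oocyte bottleneck perturbs the
    paternal contribution of the whole embryo, not each gene
    independently. CV 0 makes the fractions deterministic."""
    boost = cfg.group_boosts.get(group, 1.0)
    out = []
    cv = cfg.embryo_cv
    for _ in range(n_embryos):
        mult = float(rng.gamma(1.0 / cv**2, cv**2)) if cv > 0 else 1.0
        fractions = {}
        for f in annotation:
            mean = cfg.paternal_baseline * (boost if f.biotype == cfg.boost_biotype else 1.0)
            fractions[f.id] = float(min(mean * mult, 0.95))
        out.append(fractions)
    return out


def _apply_errors(
    read: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    if error_rate <= 0:
        return read
    hits = np.flatnonzero(rng.random(read.shape[0]) < error_rate)
    for h in hits:
        alternatives = _COMPLEMENTABLE[_COMPLEMENTABLE != read[h]]
        read[h] = rng.choice(alternatives)
    return read


def simulate_embryo_reads(
    cfg: SimConfig,
    maternal: MitoGenome,
    paternal: MitoGenome,
    annotation: FeatureAnnotation,
    out_dir: str | os.PathLike,
    groups: dict[str, int] | None = None,
) -> tuple[dict[str, Path], SimTruth]:
    """Write one coordinate-sorted SAM file per embryo.

    For each feature, reads start uniformly inside the feature (clipped
    to its 3' end so feature-level paternal fractions stay exact) and are
    copied from the paternal haplotype with that embryo's feature-level
    probability, with per-base substitution errors. Reads are emitted
    pre-aligned at their true positions with mapping quality 60 — the
    placement is known by construction, so no aligner runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if groups is None:
        groups = {g: cfg.n_embryos_per_group for g in cfg.group_boosts}
    rng = cfg.rng("reads")
    mat = np.frombuffer(maternal.sequence.encode(), dtype=np.uint8)
    pat = np.frombuffer(paternal.sequence.encode(), dtype=np.uint8)
    truth = SimTruth()
    paths: dict[str, Path] = {}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": maternal.name, "LN": len(maternal)}],
    }
    for group, n_embryos in groups.items():
        fractions = draw_embryo_fractions(cfg, annotation, group, n_embryos, rng)
        for e in range(n_embryos):
            embryo = f"{group}_e{e:03d}"
            truth.embryo_group[embryo] = group
            truth.feature_paternal_fraction[embryo] = fractions[e]
            records = []  # (pos0, seq)
            for f in annotation:
                flen = f.end - f.start + 1
                rlen = min(cfg.read_length, flen)
                n_reads = rng.poisson(cfg.mean_depth * flen / rlen)
                if n_reads == 0:
                    continue
                starts = rng.integers(f.start, f.end - rlen + 2, size=n_reads)
                is_pat = rng.random(n_reads) < fractions[e][f.id]
                for s, from_pat in zip(starts, is_pat):
                    tmpl = pat if from_pat else mat
                    read = tmpl[s - 1 : s - 1 + rlen].copy()
                    read = _apply_errors(read, cfg.error_rate, rng)
                    records.append((int(s) - 1, read.tobytes().decode()))
            records.sort(key=lambda r: r[0])
            path = out_dir / f"{embryo}.sam"
            with pysam.AlignmentFile(str(path), "wh", header=header) as out:
                for i, (pos0, seq) in enumerate(records):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = f"{embryo}_r{i:07d}"
                    a.query_sequence = seq
                    a.flag = 0
                    a.reference_id = 0
                    a.reference_start = pos0
                    a.mapping_quality = 60
                    a.cigarstring = f"{len(seq)}M"
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                    out.write(a)
            paths[embryo] = path
    truth.snp_positions = []
    return paths, truth


def simulate_allele_counts(
    cfg: SimConfig,
    snps: SnpTable,
    paternal_fraction: np.ndarray,
    rng: np.random.Generator,
    embryo_ids: list[str] | None = None,
) -> AlleleCountTensor:
    """Draw per-SNP base counts directly, bypassing read emission.

    ``paternal_fraction`` has shape (n_embryos, n_snps): the true per-site
    paternal fraction for each embryo. Site depths are Poisson with mean
    ``cfg.mean_depth``; each base errs to one of the three others with
    total probability ``cfg.error_rate``. This site-level path serves
    estimator tests at depths where per-read emission would be wasteful.
    """
    p = np.atleast_2d(np.asarray(paternal_fraction, dtype=float))
    n_embryos, n_snps = p.shape
    if n_snps != len(snps):
        raise ValueError("paternal_fraction second dimension must match the SNP table")
    e = cfg.error_rate
    mat_idx = np.array([BASES.index(a) for a in snps.maternal_alleles])
    pat_idx = np.array([BASES.index(a) for a in snps.paternal_alleles])
    depth = rng.poisson(cfg.mean_depth, size=(n_embryos, n_snps))
    counts = np.zeros((n_embryos, n_snps, 4), dtype=np.int64)
    # per-base observation probabilities: a true base is read correctly with
    # probability 1-e, or as each of the other three with probability e/3
    probs = np.full((n_embryos, n_snps, 4), e / 3.0)
    idx_e = np.arange(n_embryos)[:, None]
    idx_s = np.arange(n_snps)[None, :]
    probs[idx_e, idx_s, mat_idx[None, :]] = (1 - p) * (1 - e) + p * (e / 3.0)
    probs[idx_e, idx_s, pat_idx[None, :]] = p * (1 - e) + (1 - p) * (e / 3.0)
    flat_probs = probs.reshape(-1, 4)
    flat_depth = depth.reshape(-1)
    counts = rng.multinomial(flat_depth, flat_probs).reshape(n_embryos, n_snps, 4)
    if embryo_ids is None:
        embryo_ids = [f"e{i:03d}" for i in range(n_embryos)]
    return AlleleCountTensor(embryo_ids=embryo_ids, positions=snps.positions, counts=counts)


def simulate_embryo_counts(
    cfg: SimConfig,
    groups: dict[str, int] | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Nuclear + mitochondrial count matrix with sex and subpopulation
    structure.

    Counts are negative-binomial (gamma-Poisson, dispersion
    ``cfg.nb_dispersion``) around lognormal per-gene means scaled to the
    library size. Y-linked genes express at ``cfg.y_gene_cpm`` per gene in
    males and exactly zero in females. In treatment ("HFD"-labelled)
    groups, an exact ``hfd_a_fraction`` share of the male embryos — chosen
    by permutation, a designed rather than Bernoulli assignment — carries
    a ``mito_expression_boost``-fold increase of every mitochondrial gene.
    """
    rng = cfg.rng("counts")
    if groups is None:
        groups = {"LFD": cfg.n_embryos_per_group, "HFD": cfg.n_embryos_per_group}
    n_nuc = cfg.n_nuclear_genes
    gene_ids = [f"gene_{i:04d}" for i in range(n_nuc)]
    tiles = _mito_architecture(cfg.genome_length)
    mito_ids = [fid for fid, _, _ in tiles]
    # the subpopulation signature is mt-tRNA overexpression; boosting every
    # mitochondrial gene would cancel under within-mito CPM normalization
    mito_boost_mask = np.array([biotype == "mt-tRNA" for _, biotype, _ in tiles])
    all_ids = gene_ids + list(Y_GENES) + mito_ids
    chrom = (["nuclear"] * n_nuc) + (["Y"] * len(Y_GENES)) + (["mito"] * len(mito_ids))

    base_mean = rng.lognormal(mean=3.0, sigma=1.2, size=n_nuc)
    mito_mean = rng.lognormal(mean=6.0, sigma=0.6, size=len(mito_ids))
    # Y genes are pinned to their target CPM, the rest scale to the library
    y_mean_counts = np.full(len(Y_GENES), cfg.y_gene_cpm * cfg.library_size / 1e6)
    scale = cfg.library_size / (base_mean.sum() + mito_mean.sum())

    truth = SimTruth()
    columns = {}
    disp = cfg.nb_dispersion

    def _nb(mean_vec: np.ndarray) -> np.ndarray:
        lam = rng.gamma(shape=1.0 / disp, scale=mean_vec * disp)
        return rng.poisson(lam)

    for group, n_embryos in groups.items():
        is_male = np.zeros(n_embryos, dtype=bool)
        n_male = int(round(cfg.sex_ratio * n_embryos))
        is_male[rng.permutation(n_embryos)[:n_male]] = True
        subpop = np.zeros(n_embryos, dtype=bool)
        if group.upper().startswith("HFD"):
            male_idx = np.flatnonzero(is_male)
            n_boost = int(round(cfg.hfd_a_fraction * len(male_idx)))
            subpop[rng.permutation(male_idx)[:n_boost]] = True
        for e in range(n_embryos):
            embryo = f"{group}_e{e:03d}"
            nuc = _nb(base_mean * scale)
            y = _nb(y_mean_counts) if is_male[e] else np.zeros(len(Y_GENES), dtype=np.int64)
            mboost = np.where(
                mito_boost_mask, cfg.mito_expression_boost if subpop[e] else 1.0, 1.0
            )
            mito = _nb(mito_mean * scale * mboost)
            columns[embryo] = np.concatenate([nuc, y, mito])
            truth.embryo_group[embryo] = group
            truth.embryo_sex[embryo] = "male" if is_male[e] else "female"
            truth.embryo_subpop[embryo] = bool(subpop[e])
    import pandas as pd

    counts = pd.DataFrame(columns, index=all_ids)
    expr = ExpressionMatrix(counts=counts, chrom=pd.Series(chrom, index=all_ids))
    return expr, truth


def simulate_small_rna_refs(cfg: SimConfig) -> ReferenceBundle:
    """A compact reference bundle: nuclear + mitochondrial tRNAs, rRNA
    stand-ins, miRNAs and piRNAs, all synthetic random sequences."""
    rng = cfg.rng("smallrna_refs")

    def _seq(n: int) -> str:
        return rng.choice(_COMPLEMENTABLE, size=n).tobytes().decode()

    refs = []
    for i in range(6):
        refs.append(ReferenceSeq(f"n-tRNA-{i + 1}", _seq(73), "tRNA", "nuclear"))
    for i in range(6):
        refs.append(ReferenceSeq(f"mt-tRNA-{i + 1}", _seq(70), "tRNA", "mitochondrial"))
    refs.append(ReferenceSeq("n-rRNA-5.8S", _seq(150), "rRNA", "nuclear"))
    refs.append(ReferenceSeq("mt-Rnr1", _seq(200), "rRNA", "mitochondrial"))
    for i in range(8):
        refs.append(ReferenceSeq(f"miR-{i + 1}", _seq(22), "miRNA", "nuclear"))
    for i in range(8):
        refs.append(ReferenceSeq(f"piR-{i + 1}", _seq(28), "piRNA", "nuclear"))
    return ReferenceBundle(refs)


def simulate_small_rna_reads(
    cfg: SimConfig,
    refs: ReferenceBundle,
    n_reads: int = 20_000,
    biotype_mix: dict[str, float] | None = None,
    out_fastq: str | os.PathLike | None = None,
) -> tuple[list[str], SimTruth]:
    """Sample a small-RNA read set from the reference bundle.

    tRNA-derived reads are fragmented per ``cfg.fragment_mix`` (5', 3',
    full-length; lengths 16-45 within the parent), other biotypes are
    sampled near full length; per-base errors at ``cfg.error_rate``.
    Returns the read sequences and truth; optionally writes a FASTQ with
    uniform qualities.
    """
    rng = cfg.rng("smallrna_reads")
    if biotype_mix is None:
        biotype_mix = {"tRNA": 0.5, "rRNA": 0.2, "miRNA": 0.15, "piRNA": 0.15}
    classes = list(biotype_mix)
    probs = np.array([biotype_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    f5, f3, ffull = cfg.fragment_mix
    reads: list[str] = []
    truth = SimTruth()
    truth.extras = {"source_class": [], "source_ref": [], "offset": [], "kind": []}
    for i in range(n_reads):
        ref_class = classes[rng.choice(len(classes), p=probs)]
        pool = refs.by_class(ref_class)
        ref, enc = pool[rng.integers(len(pool))]
        L = len(enc)
        if ref_class == "tRNA":
            kind = ("5p", "3p", "full")[rng.choice(3, p=[f5, f3, ffull])]
            if kind == "full":
                start, rlen = 1, L  # full-length reads span the whole parent
            elif kind == "5p":
                rlen = int(rng.integers(16, min(L - 4, 45) + 1))
                start = int(rng.integers(1, 4))
                rlen = min(rlen, L - 4 - start + 1)  # end < L-3: stay clear of the 3' end
            else:
                rlen = int(rng.integers(16, min(L - 4, 45) + 1))
                end = int(L - rng.integers(0, 4))
                start = max(4, end - rlen + 1)
                rlen = end - start + 1
        else:
            kind = "full"
            rlen = min(L, 45)
            rlen = max(rlen, 16)
            start = 1
        frag = enc[start - 1 : start - 1 + rlen].copy()
        frag = _apply_errors(frag, cfg.error_rate, rng)
        reads.append(frag.tobytes().decode())
        truth.extras["source_class"].append(ref_class)
        truth.extras["source_ref"].append(ref.id)
        truth.extras["offset"].append(start)
        truth.extras["kind"].append(kind)
    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@read_{i:06d}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads, truth
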