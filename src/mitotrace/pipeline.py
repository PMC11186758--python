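"""End-to-end run configuration and orchestration.

One call chains the whole parental-origin analysis: SNP table from the
two parental genomes, allele counting over the per-embryo alignments,
heteroplasmy, sexing from the nuclear count matrix, mitochondrial PCA and
clustering, and feature/biotype enrichment over the control group. Every
run writes a machine-readable manifest (config, seed, package version) so
outputs are attributable to their inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counting import PileupFilters, compute_heteroplasmy, pileup_allele_counts
from .embryos import (
    ExpressionMatrix,
    cluster_embryos,
    pca_embryos,
    sex_embryos,
    split_transcriptome,
)
from .io import read_bed, read_fasta, read_gff, write_vcf
from .reference import annotate_snps, derive_snp_table
from .simulate import Y_GENES
from .tracing import feature_heteroplasmy, group_enrichment, snp_density_summary

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    maternal_fasta: str
    paternal_fasta: str
    features: str  # GFF3 (.gff/.gff3) or BED
    alignments: dict  # embryo id -> SAM/BAM path
    counts_tsv: str  # genes x embryos; gene metadata column 'chrom'
    groups: dict  # embryo id -> group label
    out_dir: str
    control_label: str = "LFD"
    seed: int = 0
    band_width: int = 256
    full_dp: bool = False
    min_base_quality: int = 20
    min_mapping_quality: int = 30
    min_site_coverage: int = 20
    y_genes: list = field(default_factory=lambda: list(Y_GENES))
    min_cpm_sum: float = 5.0
    min_detected: int = 2
    n_components: int = 10
    cluster_k: object = "auto"
    n_boot: int = 1000
    density_bins: int = 50

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_counts(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "chrom" not in df.columns:
        raise ValueError(f"{path}: counts TSV needs a 'chrom' gene-tag column")
    chrom = df["chrom"]
    counts = df.drop(columns=["chrom"]).astype(np.int64)
    return ExpressionMatrix(counts=counts, chrom=chrom)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle into ``config.out_dir``.

    Artifacts: snps.vcf, heteroplasmy.tsv, embryos.tsv, enrichment.tsv,
    density.tsv and manifest.json. Returns the in-memory results keyed by
    the same names.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrap

    maternal = stage("read_maternal")(read_fasta, config.maternal_fasta)[0]
    paternal = stage("read_paternal")(read_fasta, config.paternal_fasta)[0]
    reader = read_gff if config.features.endswith((".gff", ".gff3")) else read_bed
    annotation = stage("read_features")(reader, config.features)

    snps = stage("snptable")(
        derive_snp_table, maternal, paternal, config.band_width, full_dp=config.full_dp
    )
    snps = stage("annotate")(annotate_snps, snps, annotation)
    write_vcf(snps, out / "snps.vcf", genome_length=len(maternal))
    logger.info("SNP table: %d substitutions", len(snps))

    filters = PileupFilters(
        min_base_quality=config.min_base_quality,
        min_mapping_quality=config.min_mapping_quality,
        min_site_coverage=config.min_site_coverage,
    )
    tensor = stage("pileup")(
        pileup_allele_counts, config.alignments, snps, filters, genome=maternal
    )
    het = stage("heteroplasmy")(compute_heteroplasmy, tensor, snps, filters)
    het_df = pd.DataFrame(het.values, index=het.embryo_ids, columns=het.positions)
    het_df.to_csv(out / "heteroplasmy.tsv", sep="\t", na_rep="NA")

    expr = stage("read_counts")(_load_counts, config.counts_tsv)
    sexes = stage("sexing")(
        sex_embryos, expr, config.y_genes, config.min_cpm_sum, config.min_detected
    )
    nuclear, mito = stage("split")(split_transcriptome, expr)
    pca = stage("pca")(pca_embryos, mito, n_components=config.n_components)
    clusters = stage("cluster")(
        cluster_embryos, pca.scores, k=config.cluster_k, seed=config.seed
    )

    embryo_table = pd.DataFrame(
        {
            "group": pd.Series(config.groups),
            "sex": sexes,
            "cluster": clusters,
            "library_size": expr.library_sizes,
        }
    )
    embryo_table.index.name = "embryo"
    embryo_table.to_csv(out / "embryos.tsv", sep="\t", na_rep="NA")

    fh = stage("feature_heteroplasmy")(feature_heteroplasmy, het, snps)
    groups = pd.Series(config.groups).reindex(het.embryo_ids)
    enrich_feature = stage("enrichment")(
        group_enrichment, fh, groups, config.control_label,
        stratify_by="feature", n_boot=config.n_boot, seed=config.seed,
    )
    enrich_biotype = stage("enrichment")(
        group_enrichment, fh, groups, config.control_label,
        stratify_by="biotype", n_boot=config.n_boot, seed=config.seed,
    )
    enrich_df = pd.DataFrame(
        [dataclasses.asdict(r) for r in [*enrich_biotype, *enrich_feature]]
    )
    enrich_df.insert(0, "stratify_by", ["biotype"] * len(enrich_biotype) + ["feature"] * len(enrich_feature))
    enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    density = stage("density")(snp_density_summary, het, groups, config.density_bins)
    density.to_csv(out / "density.tsv", sep="\t", index=False)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_snps": len(snps),
        "n_embryos": len(het.embryo_ids),
        "pca_variance_explained": pca.variance_explained.tolist(),
        "versions": {
            "mitotrace": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fhandle:
        json.dump(manifest, fhandle, indent=1, sort_keys=True)

    return {
        "snps": snps,
        "heteroplasmy": het,
        "embryos": embryo_table,
        "enrichment": enrich_df,
        "density": density,
        "manifest": manifest,
    }
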