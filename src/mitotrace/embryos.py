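"""Single-embryo transcriptome analysis: sexing, splitting, PCA, clustering.

Embryos are sexed by the exclusive expression of Y-linked genes: any
Y-gene signal at all is incompatible with a female embryo, so females are
called only on exactly zero summed Y CPM, males on a combined
abundance-and-breadth criterion, everything else is left undetermined
(and excluded downstream rather than imputed).

Clustering of the mitochondrial transcriptome uses PCA on log1p(CPM)
followed by k-means, with the number of clusters chosen by mean
silhouette when not fixed. This is a deliberate substitution for
graph-based community detection: the target is the recovery of a discrete
subpopulation structure, for which centroid clustering with an explicit
model-selection criterion is the more transparent tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "ExpressionMatrix",
    "EmbryoTable",
    "sex_embryos",
    "split_transcriptome",
    "pca_embryos",
    "cluster_embryos",
]

CHROM_TAGS = ("nuclear", "mito", "Y")


@dataclass
class ExpressionMatrix:
    """Gene x embryo raw counts with a per-gene chromosome tag."""

    counts: pd.DataFrame  # genes x embryos, non-negative ints
    chrom: pd.Series  # gene id -> tag in CHROM_TAGS

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.chrom = self.chrom.reindex(self.counts.index)
        unknown = set(self.chrom.dropna().unique()) - set(CHROM_TAGS)
        if unknown or self.chrom.isna().any():
            raise ValueError(f"every gene needs a chromosome tag from {CHROM_TAGS}")

    @property
    def embryo_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        lib = self.library_sizes
        if (lib == 0).any():
            zero = list(lib.index[lib == 0])
            raise ValueError(f"embryos with empty libraries: {zero}")
        return self.counts / lib * 1e6


@dataclass
class EmbryoTable:
    """Per-embryo metadata: group, inferred sex, cluster, QC."""

    table: pd.DataFrame  # index embryo id; columns: group, sex, cluster, library_size

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate embryo ids")

    @property
    def sexes(self) -> pd.Series:
        return self.table["sex"]


def sex_embryos(
    expr: ExpressionMatrix,
    y_genes: list[str],
    min_cpm_sum: float = 5.0,
    min_detected: int = 2,
) -> pd.Series:
    """Infer embryo sex from Y-linked gene expression.

    female: summed Y CPM exactly 0; male: summed Y CPM >= ``min_cpm_sum``
    and at least ``min_detected`` Y genes with nonzero counts; otherwise
    undetermined. CPM-based, hence invariant to library size.
    """
    if not y_genes:
        raise ValueError("y_genes must be non-empty")
    missing = [g for g in y_genes if g not in expr.counts.index]
    if missing:
        raise ValueError(f"Y genes absent from the matrix: {missing}")
    y_cpm = expr.cpm().loc[y_genes].sum(axis=0)
    y_detected = (expr.counts.loc[y_genes] > 0).sum(axis=0)
    sex = pd.Series("undetermined", index=expr.counts.columns, name="sex")
    sex[(y_cpm >= min_cpm_sum) & (y_detected >= min_detected)] = "male"
    sex[y_cpm == 0] = "female"
    return sex


def split_transcriptome(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition into (nuclear incl. Y-linked, mitochondrial) matrices."""
    is_mito = expr.chrom == "mito"
    nuclear = ExpressionMatrix(expr.counts.loc[~is_mito], expr.chrom[~is_mito])
    mito = ExpressionMatrix(expr.counts.loc[is_mito], expr.chrom[is_mito])
    return nuclear, mito


def merge_transcriptomes(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    counts = pd.concat([a.counts, b.counts])
    chrom = pd.concat([a.chrom, b.chrom])
    return ExpressionMatrix(counts, chrom)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # embryos x components
    variance_explained: np.ndarray  # fractions, non-increasing, sum <= 1
    normalization: str
    scaled: bool


def pca_embryos(
    expr: ExpressionMatrix,
    normalize: str = "log1p_cpm",
    scale_unit_variance: bool = False,
    n_components: int = 10,
) -> PcaResult:
    """PCA of embryos on normalized expression.

    Normalization is log1p of counts-per-million; genes with zero variance
    are dropped before optional unit-variance scaling. Component signs are
    fixed so the largest-magnitude gene loading of each component is
    positive, making the scores deterministic.
    """
    if normalize != "log1p_cpm":
        raise ValueError(f"unsupported normalization {normalize!r}")
    if expr.counts.shape[1] < 2 or expr.counts.shape[0] < 2:
        raise ValueError("PCA needs at least 2 embryos and 2 genes")
    x = np.log1p(expr.cpm()).to_numpy().T  # embryos x genes
    var = x.var(axis=0)
    if scale_unit_variance:
        keep = var > 0
        x = x[:, keep]
        x = (x - x.mean(axis=0)) / x.std(axis=0)
    n_components = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    # deterministic sign convention
    flip = np.sign(pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=expr.counts.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        variance_explained=pca.explained_variance_ratio_.copy(),
        normalization=normalize,
        scaled=scale_unit_variance,
    )


def cluster_embryos(
    scores: pd.DataFrame,
    method: str = "kmeans",
    k: int | str = "auto",
    seed: int = 0,
) -> pd.Series:
    """Cluster embryos on PCA scores.

    ``k="auto"`` selects k in 2..6 by mean silhouette. Identical embryos
    leave the silhouette undefined, in which case a single cluster is
    returned with a warning.
    """
    if method != "kmeans":
        raise ValueError(f"unsupported clustering method {method!r}")
    x = scores.to_numpy(dtype=float)
    n = x.shape[0]
    if np.allclose(x, x[0]):
        warnings.warn("all embryos identical: silhouette undefined, forcing a single cluster")
        return pd.Series(np.zeros(n, dtype=int), index=scores.index, name="cluster")
    if k == "auto":
        best_k, best_sil = None, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            labels = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit_predict(x)
            if len(np.unique(labels)) < 2:
                continue
            sil = silhouette_score(x, labels)
            if sil > best_sil:
                best_k, best_sil = kk, sil
        if best_k is None:
            warnings.warn("no multi-cluster solution found, forcing a single cluster")
            return pd.Series(np.zeros(n, dtype=int), index=scores.index, name="cluster")
        k = best_k
    else:
        k = int(k)
        if k < 2:
            raise ValueError("fixed k must be >= 2")
        if n < k:
            raise ValueError(f"cannot form {k} clusters from {n} embryos")
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
    return pd.Series(labels, index=scores.index, name="cluster")
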