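"""Study-scale simulation experiments exercising the whole pipeline.

Each function sets up the simulated study the package targets — hybrid
two-cell embryos from a cross of two mitochondrial haplotypes, with
treatment groups carrying mt-tRNA-specific paternal boosts — runs the
relevant pipeline stages, and returns summary statistics against the
generator's ground truth. They serve the reproduction script and the
statistical test suite; problem sizes are the study conditions (416 SNPs
on 16.3 kb, depth 500, 40 embryos per group, 30% boosted subpopulation).
"""

from __future__ import annotations



import numpy as np
import pandas as pd

from .counting import PileupFilters, compute_heteroplasmy
from .embryos import ExpressionMatrix, cluster_embryos, pca_embryos, sex_embryos, split_transcriptome
from .fragments import fragmentation_profile
from .reference import annotate_snps, derive_snp_table
from .simulate import (
    DEFAULT_GROUP_BOOSTS,
    SimConfig,
    Y_GENES,
    draw_embryo_fractions,
    simulate_allele_counts,
    simulate_embryo_counts,
    simulate_hybrid_genomes,
    simulate_small_rna_reads,
    simulate_small_rna_refs,
)
from .tracing import feature_heteroplasmy, group_enrichment

__all__ = [
    "snp_recovery_experiment",
    "heteroplasmy_recovery_experiment",
    "enrichment_experiment",
    "subpopulation_experiment",
    "sexing_experiment",
    "fragmentation_experiment",
]


def snp_recovery_experiment(
    n_pairs: int = 100, n_snps: int = 40, seed_start: int = 1
) -> dict:
    """Fraction of simulated genome pairs whose SNP table is recovered
    exactly (positions and both alleles) by the banded aligner."""
    exact = 0
    for seed in range(seed_start, seed_start + n_pairs):
        cfg = SimConfig(seed=seed, n_snps=n_snps)
        maternal, paternal, truth, _ = simulate_hybrid_genomes(cfg)
        table = derive_snp_table(maternal, paternal)
        ok = (
            list(table.positions) == list(truth.positions)
            and table.maternal_alleles == truth.maternal_alleles
            and table.paternal_alleles == truth.paternal_alleles
        )
        exact += ok
    return {"exact_fraction": exact / n_pairs, "n_pairs": n_pairs}


def expected_heteroplasmy(p: float, error_rate: float) -> float:
    """Expectation of 1 - maternal frequency under the substitution-error
    model: maternal reads err away with probability e, paternal reads err
    back to the maternal base with probability e/3."""
    e = error_rate
    return p + e * (1 - 4.0 * p / 3.0)


def heteroplasmy_recovery_experiment(
    fractions=(0.01, 0.05, 0.2),
    n_replicates: int = 100,
    seed: int = 1,
    mean_depth: float = 500.0,
    error_rate: float = 0.001,
) -> dict:
    """Across-SNP mean heteroplasmy versus its analytic expectation.

    One replicate is one embryo at the study depth over the default 416
    SNPs; a replicate scores as recovered when its coverage-weighted mean
    estimate is within 3 binomial standard errors of the expectation."""
    cfg = SimConfig(seed=seed, mean_depth=mean_depth, error_rate=error_rate)
    _, _, truth, _ = simulate_hybrid_genomes(cfg)
    filters = PileupFilters(min_site_coverage=20)
    out = {}
    for p in fractions:
        rng = cfg.rng(f"recovery_{p}")
        tensor = simulate_allele_counts(
            cfg, truth, np.full((n_replicates, len(truth)), p), rng
        )
        het = compute_heteroplasmy(tensor, truth, filters)
        weights = np.where(het.mask, 0, het.coverage)
        means = (np.nan_to_num(het.values) * weights).sum(axis=1) / weights.sum(axis=1)
        mu = expected_heteroplasmy(p, error_rate)
        tol = 3 * np.sqrt(p * (1 - p) / (len(truth) * mean_depth))
        within = np.abs(means - mu) < tol
        out[p] = {
            "recovered_fraction": float(within.mean()),
            "mean_estimate": float(means.mean()),
            "expectation": mu,
            "n_replicates": n_replicates,
        }
    return out


def _snp_fractions_from_features(truth, annotated, fractions: dict) -> np.ndarray:
    """Map one embryo's feature-level fractions onto the SNP axis."""
    baseline = min(fractions.values()) if fractions else 0.0
    return np.array([
        fractions.get(rec.feature_id, baseline) if rec.feature_id else baseline
        for rec in annotated
    ])


def enrichment_experiment(
    n_replicates: int = 20,
    seed: int = 1,
    n_embryos: int = 40,
    n_boot: int = 1000,
    boosts: dict | None = None,
) -> dict:
    """Recovery of programmed biotype-level enrichment ratios.

    Groups carry mt-tRNA paternal boosts over a shared baseline; each
    replicate simulates the full cohort at the study depth, estimates
    heteroplasmy, aggregates to biotypes and bootstraps the group/control
    ratio. Reports CI coverage of the programmed ratios, the fraction of
    replicates preserving the programmed ordering, and mean recovered
    ratios. Sequencing error is left at zero here: estimator bias under
    error is quantified separately by the recovery experiment."""
    boosts = dict(boosts or DEFAULT_GROUP_BOOSTS)
    cfg = SimConfig(seed=seed, error_rate=0.0, group_boosts=boosts,
                    n_embryos_per_group=n_embryos)
    maternal, paternal, truth, ann = simulate_hybrid_genomes(cfg)
    annotated = annotate_snps(truth, ann)
    filters = PileupFilters(min_site_coverage=20)
    treatment_groups = [g for g in boosts if boosts[g] != 1.0]
    covered = {g: 0 for g in treatment_groups}
    ratios = {g: [] for g in treatment_groups}
    order_ok = 0
    for rep in range(n_replicates):
        rng = cfg.rng(f"enrichment_{rep}")
        embryo_ids, group_of, p_rows = [], {}, []
        for group in boosts:
            for i, fr in enumerate(
                draw_embryo_fractions(cfg, ann, group, n_embryos, rng)
            ):
                embryo = f"{group}_e{i:03d}"
                embryo_ids.append(embryo)
                group_of[embryo] = group
                p_rows.append(_snp_fractions_from_features(truth, annotated, fr))
        tensor = simulate_allele_counts(
            cfg, annotated, np.vstack(p_rows), rng, embryo_ids=embryo_ids
        )
        het = compute_heteroplasmy(tensor, annotated, filters)
        fh = feature_heteroplasmy(het, annotated)
        groups = pd.Series(group_of).reindex(embryo_ids)
        results = group_enrichment(
            fh, groups, "LFD", "biotype", n_boot=n_boot, seed=seed * 100_000 + rep
        )
        trna = {r.group: r for r in results if r.stratum == "mt-tRNA"}
        for g in treatment_groups:
            r = trna[g]
            ratios[g].append(r.ratio)
            covered[g] += r.ci_low <= boosts[g] <= r.ci_high
        ranked = sorted(treatment_groups, key=lambda g: trna[g].ratio, reverse=True)
        programmed = sorted(treatment_groups, key=lambda g: boosts[g], reverse=True)
        order_ok += ranked == programmed
    n_ci = n_replicates * len(treatment_groups)
    return {
        "ci_coverage": sum(covered.values()) / n_ci,
        "ordering_fraction": order_ok / n_replicates,
        "mean_ratios": {g: float(np.mean(ratios[g])) for g in treatment_groups},
        "programmed": {g: boosts[g] for g in treatment_groups},
        "n_replicates": n_replicates,
    }


def subpopulation_experiment(
    n_replicates: int = 50, seed: int = 1, n_treatment: int = 100
) -> dict:
    """Recovery of the boosted male subpopulation as a minority cluster.

    Each replicate simulates a treatment cohort, keeps the males, clusters
    their mitochondrial transcriptomes (PCA + k-means, silhouette-selected
    k) and scores whether a two-cluster solution appears whose minority
    share is within 10 percentage points of the designed 30%."""
    hits = 0
    minority_fractions = []
    base = SimConfig(seed=seed)
    for rep in range(n_replicates):
        cfg = SimConfig(seed=seed * 1000 + rep,
                        hfd_a_fraction=base.hfd_a_fraction)
        expr, truth = simulate_embryo_counts(cfg, groups={"HFD": n_treatment})
        males = [e for e in expr.counts.columns if truth.embryo_sex[e] == "male"]
        _, mito = split_transcriptome(expr)
        sub = ExpressionMatrix(mito.counts[males], mito.chrom)
        labels = cluster_embryos(pca_embryos(sub).scores, k="auto", seed=cfg.seed)
        if labels.nunique() == 2:
            minority = labels.value_counts().min() / len(males)
            minority_fractions.append(minority)
            hits += abs(minority - base.hfd_a_fraction) <= 0.10
    return {
        "recovered_fraction": hits / n_replicates,
        "mean_minority_fraction": float(np.mean(minority_fractions))
        if minority_fractions else float("nan"),
        "n_replicates": n_replicates,
    }


def sexing_experiment(n_seeds: int = 100, seed_start: int = 1, cohort: int = 40) -> dict:
    """Sexing accuracy over simulated cohorts with exclusive Y expression."""
    correct = total = 0
    for seed in range(seed_start, seed_start + n_seeds):
        cfg = SimConfig(seed=seed)
        expr, truth = simulate_embryo_counts(
            cfg, groups={"LFD": cohort // 2, "HFD": cohort - cohort // 2}
        )
        sexes = sex_embryos(expr, list(Y_GENES))
        expected = pd.Series(truth.embryo_sex).reindex(sexes.index)
        correct += int((sexes == expected).sum())
        total += len(sexes)
    return {"accuracy": correct / total, "n_embryos": total, "n_seeds": n_seeds}


def fragmentation_experiment(seed: int = 1, n_reads: int = 30_000) -> dict:
    """Recovery of the programmed 5'/3'/full fragment mixture, pooled over
    all mitochondrial tRNA references."""
    cfg = SimConfig(seed=seed, error_rate=0.0)
    refs = simulate_small_rna_refs(cfg)
    reads, truth = simulate_small_rna_reads(
        cfg, refs, n_reads=n_reads, biotype_mix={"tRNA": 1.0}
    )
    by_ref: dict[str, list] = {}
    for i, ref_id in enumerate(truth.extras["source_ref"]):
        by_ref.setdefault(ref_id, []).append(
            (truth.extras["offset"][i], len(reads[i]), 1.0)
        )
    w5 = w3 = wfull = wint = 0.0
    for ref_id, triples in by_ref.items():
        length = len(refs.by_id()[ref_id].sequence)
        profile = fragmentation_profile(triples, ref_id, length)
        n = len(triples)
        w5 += profile.f5 * n
        w3 += profile.f3 * n
        wfull += profile.f_full * n
        wint += profile.f_internal * n
    total = w5 + w3 + wfull + wint
    return {
        "f5": w5 / total,
        "f3": w3 / total,
        "f_full": wfull / total,
        "f_internal": wint / total,
        "programmed": dict(zip(("f5", "f3", "f_full"), cfg.fragment_mix)),
        "n_reads": n_reads,
    }
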