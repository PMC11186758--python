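# mitotrace

Parental-origin tracing of mitochondrial RNAs in hybrid two-cell embryos,
plus small-RNA (tRNA-fragment) profiling of sperm — as a tested, reusable
Python pipeline.

## The problem

In a hybrid cross between two inbred mouse strains whose mitochondrial
genomes differ at a few hundred fixed substitutions, every mitochondrial
transcript in the embryo can be assigned a parental origin: reads carrying
the maternal allele at a diagnostic SNP came from the oocyte's mtDNA, reads
carrying the paternal allele point to sperm-delivered mitochondrial RNA.
The per-site statistic is **heteroplasmy**,

```
h = 1 − f_maternal
```

the fraction of reads at a SNP that do *not* carry the maternal allele.
Aggregated over the SNPs inside a gene, and then over gene biotypes
(mt-tRNA, mt-rRNA, mt-mRNA, control region), group-versus-control fold
ratios of heteroplasmy measure a paternal contribution to the embryonic
mitochondrial RNA pool — e.g. a 12× mt-tRNA enrichment in a subpopulation of
male embryos sired by high-fat-diet fathers. The package covers the whole
analysis chain:

| stage | module | what it does |
|---|---|---|
| SNP table | `mitotrace.reference` | banded Needleman–Wunsch alignment of the two mitochondrial genomes; substitution-only SNP catalogue with feature/biotype annotation |
| allele counting | `mitotrace.counting` | filtered per-SNP base counts from per-embryo SAM/BAM; heteroplasmy with a coverage mask |
| enrichment | `mitotrace.tracing` | coverage-weighted feature/biotype aggregation; bootstrap fold ratios over a control group |
| embryo analysis | `mitotrace.embryos` | sexing by exclusive Y-linked expression; nuclear/mito split; PCA + k-means clustering |
| small RNA | `mitotrace.fragments` | biotype annotation of small-RNA reads (miRNA > rRNA > tRNA > piRNA cascade), RPM filtering, 5′/3′/full tRNA-fragment profiling |
| synthetic data | `mitotrace.simulate` | generates every input above with ground truth, so the full pipeline is testable without any sequencing data |
| orchestration | `mitotrace.pipeline`, `mitotrace.cli` | YAML-configured end-to-end runs, `mitotrace` CLI |

File formats are the standard ones: FASTA, GFF3/BED, VCF v4.2 (REF =
maternal allele, ALT = paternal allele), SAM/BAM, FASTQ, TSV.

## Worked example

Simulate a complete input bundle (two haplotypes 200 substitutions apart,
four embryos per diet group, reads, counts, small RNA) and derive the SNP
table:

```bash
$ mitotrace simulate --seed 11 --out-dir demo --n-embryos 4 \
      --mean-depth 60 --genome-length 8000 --n-snps 200
simulated bundle (16 embryo alignments) -> demo
$ mitotrace snptable --maternal demo/maternal.fa --paternal demo/paternal.fa \
      --features demo/features.gff3 --out demo/snps.vcf
200 substitutions -> demo/snps.vcf
```

Run the full pipeline from a config (`mitotrace run --config run.yaml`, or
`mitotrace.pipeline.run_pipeline` from Python) and inspect the
biotype-level enrichment it writes. The generator programmed mt-tRNA
paternal boosts of 12× (HFD_A), 2× (HFD_B) and 3.5× (HFD_female) over the
LFD controls, and the recovered ratios bracket exactly those values while
the other biotypes stay near 1:

```
     group        stratum  ratio  ci_low  ci_high  n_group  n_control
     HFD_A        mt-tRNA  12.78    7.63    18.91        4          4
     HFD_A        mt-mRNA   0.69    0.36     1.33        4          4
     HFD_B        mt-tRNA   2.00    1.52     2.67        4          4
HFD_female        mt-tRNA   3.79    2.72     5.54        4          4
```

`ratio` is the group mean of biotype-level heteroplasmy divided by the
control mean; `ci_low`/`ci_high` is a percentile bootstrap 95% interval
from resampling embryos. The run also writes the per-SNP heteroplasmy
matrix, the embryo table (diet group, inferred sex, cluster label), the
heteroplasmy density histogram and a JSON manifest of the configuration.

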