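"""Readers and writers for the standard formats the pipeline touches.

Conventions: FASTA for genomes; GFF3 (1-based inclusive) or BED
(0-based half-open) for the mitochondrial feature annotation; VCF v4.2
for the SNP table with REF = maternal allele and ALT = paternal allele.
All round-trips are lossless for the in-memory types they serve.
"""

from __future__ import annotations

import os

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import BIOTYPES, Feature, FeatureAnnotation, MitoGenome, SnpRecord, SnpTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff",
    "read_bed",
    "write_vcf",
    "read_vcf",
    "ParseError",
]


class ParseError(ValueError):
    """A malformed record, reported with its line number."""

    def __init__(self, path: str | os.PathLike, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


def read_fasta(path: str | os.PathLike, circular: bool = True) -> list[MitoGenome]:
    genomes = [
        MitoGenome(name=rec.id, sequence=str(rec.seq).upper(), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not genomes:
        raise ParseError(path, 1, "no FASTA records found")
    return genomes


def write_fasta(genomes: MitoGenome | list[MitoGenome], path: str | os.PathLike) -> None:
    if isinstance(genomes, MitoGenome):
        genomes = [genomes]
    records = [SeqRecord(Seq(g.sequence), id=g.name, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


_GFF_BIOTYPE_KEYS = ("biotype", "gene_biotype", "gbkey")


def _normalize_biotype(raw: str) -> str:
    aliases = {
        "trna": "mt-tRNA",
        "mt-trna": "mt-tRNA",
        "rrna": "mt-rRNA",
        "mt-rrna": "mt-rRNA",
        "mrna": "mt-mRNA",
        "mt-mrna": "mt-mRNA",
        "protein_coding": "mt-mRNA",
        "cds": "mt-mRNA",
        "d_loop": "control_region",
        "d-loop": "control_region",
        "control_region": "control_region",
        "intergenic": "intergenic",
    }
    key = raw.strip().lower()
    if raw in BIOTYPES:
        return raw
    if key in aliases:
        return aliases[key]
    raise ValueError(f"unknown biotype {raw!r}")


def read_gff(path: str | os.PathLike) -> FeatureAnnotation:
    """Read a GFF3 feature annotation (1-based inclusive coordinates).

    The biotype is taken from the first of the ``biotype``, ``gene_biotype``
    or ``gbkey`` attributes, falling back to the feature type column.
    A feature with start > end must carry a truthy ``circular`` or
    ``wraps_origin`` attribute, otherwise it is rejected.
    """
    # gffutils validates GFF3 structure; coordinate sanity is checked below
    # on the raw lines so errors can name the offending line.
    features: list[Feature] = []
    genome_name = "chrM"
    with open(path) as fh:
        lines = fh.readlines()
    raw_rows = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise ParseError(path, lineno, f"expected 9 tab-separated columns, got {len(cols)}")
        raw_rows.append((lineno, cols))
    if not raw_rows:
        raise ParseError(path, 1, "no GFF3 feature lines found")

    for lineno, cols in raw_rows:
        attrs = {}
        for chunk in cols[8].split(";"):
            if "=" in chunk:
                k, v = chunk.split("=", 1)
                attrs[k.strip()] = v.strip()
        wraps = attrs.get("circular", attrs.get("wraps_origin", "")).lower() in ("1", "true", "yes")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {cols[3]!r}/{cols[4]!r}")
        if start > end and not wraps:
            raise ParseError(
                path, lineno, f"start {start} > end {end} without a circular-origin flag"
            )
        raw_biotype = None
        for key in _GFF_BIOTYPE_KEYS:
            if key in attrs:
                raw_biotype = attrs[key]
                break
        if raw_biotype is None:
            raw_biotype = cols[2]
        try:
            biotype = _normalize_biotype(raw_biotype)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
        feature_id = attrs.get("ID", attrs.get("Name", f"feature_{lineno}"))
        genome_name = cols[0]
        features.append(
            Feature(
                id=feature_id,
                start=start,
                end=end,
                strand=cols[6] if cols[6] in "+-" else "+",
                biotype=biotype,
                wraps_origin=wraps,
            )
        )
    # structural validation through gffutils (attribute syntax, uniqueness)
    gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", from_string=False,
    )
    return FeatureAnnotation(features=features, genome_name=genome_name)


def write_gff(ann: FeatureAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in ann.features:
            attrs = f"ID={f.id};biotype={f.biotype}"
            if f.wraps_origin:
                attrs += ";circular=true"
            fh.write(
                f"{ann.genome_name}\tmitotrace\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def read_bed(path: str | os.PathLike, biotypes: dict[str, str] | None = None) -> FeatureAnnotation:
    """Read a BED6 annotation (0-based half-open -> 1-based inclusive).

    The biotype is parsed from the name field when it is of the form
    ``id|biotype``, otherwise looked up in ``biotypes`` by feature id.
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "score": str, "strand": str},
        )
    except Exception as exc:  # pandas errors carry no useful line numbers here
        raise ParseError(path, 1, f"malformed BED: {exc}")
    features = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start0, end0 = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise ParseError(path, lineno, "non-integer BED coordinates")
        if start0 < 0 or end0 <= start0:
            raise ParseError(path, lineno, f"invalid BED interval [{start0}, {end0})")
        name = row.name if isinstance(row.name, str) else f"feature_{lineno}"
        if "|" in name:
            feature_id, raw_biotype = name.split("|", 1)
        else:
            feature_id = name
            if biotypes is None or feature_id not in biotypes:
                raise ParseError(path, lineno, f"no biotype for feature {feature_id!r}")
            raw_biotype = biotypes[feature_id]
        try:
            biotype = _normalize_biotype(raw_biotype)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
        strand = row.strand if row.strand in ("+", "-") else "+"
        features.append(
            Feature(id=feature_id, start=start0 + 1, end=end0, strand=strand, biotype=biotype)
        )
    chrom = df["chrom"].iloc[0] if len(df) else "chrM"
    return FeatureAnnotation(features=features, genome_name=str(chrom))


def write_vcf(
    table: SnpTable, path: str | os.PathLike, genome_length: int | None = None
) -> None:
    """Write the SNP table as VCF v4.2 (REF = maternal, ALT = paternal)."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=FEATURE,Number=1,Type=String,Description="Containing feature id">')
    header.add_line('##INFO=<ID=BIOTYPE,Number=1,Type=String,Description="Feature biotype">')
    header.add_line(f"##maternal={table.maternal_name}")
    header.add_line(f"##paternal={table.paternal_name}")
    length = genome_length or (int(table.positions.max()) if len(table) else 1)
    header.contigs.add(table.maternal_name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in table.records:
            v = out.new_record(
                contig=table.maternal_name,
                start=rec.position - 1,
                stop=rec.position,
                alleles=(rec.maternal_allele, rec.paternal_allele),
            )
            if rec.feature_id is not None:
                v.info["FEATURE"] = rec.feature_id
            v.info["BIOTYPE"] = rec.biotype
            out.write(v)


def read_vcf(path: str | os.PathLike) -> SnpTable:
    records = []
    maternal_name = paternal_name = None
    with pysam.VariantFile(str(path)) as vcf:
        for line in str(vcf.header).splitlines():
            if line.startswith("##maternal="):
                maternal_name = line.split("=", 1)[1]
            elif line.startswith("##paternal="):
                paternal_name = line.split("=", 1)[1]
        for v in vcf:
            if len(v.alts or ()) != 1 or len(v.ref) != 1 or len(v.alts[0]) != 1:
                raise ParseError(path, v.pos, "only biallelic single-base substitutions supported")
            records.append(
                SnpRecord(
                    position=v.pos,
                    maternal_allele=v.ref,
                    paternal_allele=v.alts[0],
                    feature_id=v.info.get("FEATURE"),
                    biotype=v.info.get("BIOTYPE", "intergenic"),
                )
            )
        contig_name = maternal_name or (next(iter(vcf.header.contigs)) if vcf.header.contigs else "maternal")
    return SnpTable(
        records=records,
        maternal_name=contig_name,
        paternal_name=paternal_name or "paternal",
    )
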