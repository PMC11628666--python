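"""Readers and writers for the interchange formats.

Counts and metadata travel as TSV, gene annotation as BED6 (0-based
half-open) or GFF3 (1-based closed, converted on read), variants as VCF 4.2
with FORMAT GT:DP:GQ:AD, and the simulation truth as JSON. All coordinates
round-trip across these conventions.

VCF reading goes through pysam; multi-allelic records are decomposed into
biallelic rows (one per alternate allele, using that allele's AD component).
VCF writing is a small text writer: the files this package emits use a fixed,
fully specified header.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import (
    CountMatrix,
    ValidationError,
    VariantTable,
    validate_gene_table,
    validate_metadata,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_annotation",
    "write_bed6",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "read_histology",
    "write_histology",
    "write_dataset",
]


# -------------------------------------------------------------------- TSVs


def read_counts(path, annotation: pd.DataFrame | None = None):
    """Read a genes x samples count TSV (first column = gene id).

    With ``annotation`` (a validated gene table) a :class:`CountMatrix` is
    returned, otherwise the raw DataFrame.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated gene ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValidationError(f"duplicated sample ids in {path}")
    df = df.astype(np.int64)
    if annotation is not None:
        return CountMatrix(df, annotation)
    return df


def write_counts(counts, path) -> None:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def read_histology(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("bird_id", "section_id", "ES", "SP") if c not in df.columns]
    if missing:
        raise ValidationError(f"histology table {path} lacks columns {missing}")
    if (df[["ES", "SP"]] < 0).any().any():
        raise ValidationError(f"negative histology counts in {path}")
    return df


def write_histology(hist: pd.DataFrame, path) -> None:
    hist.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- annotation


def write_bed6(genes: pd.DataFrame, path) -> None:
    """Write a gene table as BED6 (0-based half-open; score column unused)."""
    with open(path, "w") as fh:
        for gene_id, row in genes.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{gene_id}\t.\t{row.get('strand', '+')}\n"
            )


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write a gene table as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, row in genes.iterrows():
            attrs = f"ID={gene_id};biotype={row.get('biotype', 'protein_coding')}"
            fh.write(
                f"{row['chrom']}\tinvex\tgene\t{int(row['start']) + 1}\t{int(row['end'])}\t.\t"
                f"{row.get('strand', '+')}\t.\t{attrs}\n"
            )


def _read_bed6(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{ln}: BED line has fewer than 4 fields")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append(
                {"gene_id": name, "chrom": chrom, "start": int(start), "end": int(end),
                 "strand": strand, "biotype": "protein_coding"}
            )
    return pd.DataFrame(rows).set_index("gene_id")


def _read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValidationError(f"{path}:{ln}: GFF3 line does not have 9 fields")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr.get("ID") or attr.get("gene_id")
            if gene_id is None:
                raise ValidationError(f"{path}:{ln}: gene feature without an ID attribute")
            gene_id = gene_id.removeprefix("gene:")
            rows.append(
                {"gene_id": gene_id, "chrom": chrom, "start": int(start) - 1,
                 "end": int(end), "strand": strand,
                 "biotype": attr.get("biotype", "protein_coding")}
            )
    return pd.DataFrame(rows).set_index("gene_id")


def read_annotation(path) -> pd.DataFrame:
    """Read gene intervals from BED6 or GFF3 into the internal 0-based table."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _read_gff3(path)
    elif path.suffix.lower() == ".bed":
        genes = _read_bed6(path)
    else:
        with open(path) as fh:
            first = fh.readline()
        genes = _read_gff3(path) if first.startswith("##gff") else _read_bed6(path)
    if not len(genes):
        raise ValidationError(f"no gene records found in {path}")
    return validate_gene_table(genes)


# --------------------------------------------------------------------- VCF


def write_vcf(
    variants: VariantTable, path, contig_lengths: dict[str, int] | None = None
) -> None:
    """Write a VariantTable as VCF 4.2 with FORMAT GT:DP:GQ:AD."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=invex\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        else:
            for chrom in pd.unique(variants.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(variants.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for i, row in variants.sites.iterrows():
            qual = row["qual"]
            qual_txt = "." if pd.isna(qual) else f"{qual:g}"
            fields = [
                str(row["chrom"]), str(int(row["pos"])), ".", str(row["ref"]),
                str(row["alt"]), qual_txt, "PASS", f"DP={int(row['info_dp'])}",
                "GT:DP:GQ:AD",
            ]
            for j in range(variants.n_samples):
                g = int(variants.gt[i, j])
                fields.append(
                    f"{gt_str.get(g, './.')}:{int(variants.dp[i, j])}:"
                    f"{int(variants.gq[i, j])}:"
                    f"{int(variants.ad_ref[i, j])},{int(variants.ad_alt[i, j])}"
                )
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> VariantTable:
    """Read a VCF 4.2 with GT/DP/GQ/AD; multi-allelic sites are decomposed."""
    sites = []
    gt_rows, dp_rows, gq_rows, adr_rows, ada_rows = [], [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            for alt_idx, alt in enumerate(alts, start=1):
                gt_row = np.full(len(samples), -1, dtype=np.int16)
                dp_row = np.zeros(len(samples), dtype=np.int32)
                gq_row = np.zeros(len(samples), dtype=np.int32)
                adr_row = np.zeros(len(samples), dtype=np.int32)
                ada_row = np.zeros(len(samples), dtype=np.int32)
                for j, s in enumerate(samples):
                    data = rec.samples[s]
                    alleles = data.get("GT", (None, None))
                    if alleles is not None and None not in alleles:
                        gt_row[j] = sum(1 for a in alleles if a == alt_idx)
                    dp = data.get("DP")
                    gq = data.get("GQ")
                    ad = data.get("AD")
                    if ad is not None and len(ad) > alt_idx and ad[0] is not None:
                        adr_row[j] = int(ad[0])
                        ada_row[j] = int(ad[alt_idx]) if ad[alt_idx] is not None else 0
                    dp_row[j] = int(dp) if dp is not None else int(adr_row[j] + ada_row[j])
                    gq_row[j] = int(gq) if gq is not None else 0
                info_dp = rec.info.get("DP")
                sites.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "qual": rec.qual if rec.qual is not None else np.nan,
                        "info_dp": int(info_dp) if info_dp is not None else int(dp_row.sum()),
                    }
                )
                gt_rows.append(gt_row)
                dp_rows.append(dp_row)
                gq_rows.append(gq_row)
                adr_rows.append(adr_row)
                ada_rows.append(ada_row)
    if not sites:
        raise ValidationError(f"no variant records found in {path}")
    return VariantTable(
        sites=pd.DataFrame(sites),
        samples=samples,
        gt=np.vstack(gt_rows),
        dp=np.vstack(dp_rows),
        gq=np.vstack(gq_rows),
        ad_ref=np.vstack(adr_rows),
        ad_alt=np.vstack(ada_rows),
    )


# ----------------------------------------------------------- whole dataset


def write_dataset(dataset, outdir) -> None:
    """Write a simulated dataset (counts, annotation, metadata, VCF, truth)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for tissue, cm in dataset.counts.items():
        write_counts(cm, out / f"counts_{tissue}.tsv")
    genes = next(iter(dataset.counts.values())).genes
    write_bed6(genes, out / "genes.bed")
    write_gff3(genes, out / "genes.gff3")
    write_metadata(dataset.meta, out / "metadata.tsv")
    write_histology(dataset.histology, out / "histology.tsv")
    write_vcf(dataset.variants, out / "variants.vcf", dataset.config.chromosome_lengths)
    (out / "truth.json").write_text(dataset.truth.to_json())
    (out / "config.json").write_text(
        json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataset.config.__dict__.items()
            },
            indent=2,
            default=str,
        )
    )
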