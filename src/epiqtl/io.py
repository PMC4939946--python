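"""Readers and writers for the plain-text study formats.

Genotypes: TSV (rows = SNPs: chrom, pos, ref, alt, then one 0/1 column per
accession) or minimal haploid GT-only VCF. Methylation: long-format TSV with
columns accession, chrom, pos (1-based), strand, trinucleotide context,
mc_count, total_count. Expression: TSV genes x accessions. Annotation: GFF3
gene features. Kinships: square TSV with an accession header row/column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from epiqtl.datatypes import BIN_META_COLUMNS, GenotypeMatrix

# --------------------------------------------------------------- genotypes


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": genotypes.chrom,
            "pos": genotypes.pos + 1,  # 1-based on disk
            "ref": "A",
            "alt": "T",
        }
    )
    for j, acc in enumerate(genotypes.accessions):
        df[acc] = genotypes.matrix[j, :]
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["chrom", "pos", "ref", "alt"]
    accessions = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(
        matrix=df[accessions].to_numpy(dtype=np.int8).T,
        chrom=df["chrom"].to_numpy(),
        pos=df["pos"].to_numpy(dtype=np.int64) - 1,
        accessions=accessions,
    )


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal haploid, GT-only VCF 4.2."""
    contigs = list(dict.fromkeys(genotypes.chrom.tolist()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=epiqtl\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.accessions)
            + "\n"
        )
        for i in range(genotypes.n_snps):
            gts = "\t".join(str(int(a)) for a in genotypes.matrix[:, i])
            fh.write(
                f"{genotypes.chrom[i]}\t{genotypes.pos[i] + 1}\t{genotypes.snp_ids[i]}"
                f"\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a haploid GT-only VCF via pysam."""
    import pysam

    vf = pysam.VariantFile(str(path))
    accessions = list(vf.header.samples)
    chroms, poss, rows, ids = [], [], [], []
    for rec in vf:
        chroms.append(str(rec.chrom))
        poss.append(rec.pos - 1)
        ids.append(rec.id or f"snp_{rec.chrom}_{rec.pos}")
        alleles = []
        for acc in accessions:
            gt = rec.samples[acc]["GT"]
            alleles.append(0 if gt[0] in (0, None) else 1)
        rows.append(alleles)
    return GenotypeMatrix(
        matrix=np.asarray(rows, dtype=np.int8).T,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        accessions=accessions,
        snp_ids=ids,
    )


# -------------------------------------------------------------- methylation


def write_cytosine_tsv(records: pd.DataFrame, path: str | Path) -> None:
    cols = ["accession", "chrom", "pos", "strand", "context", "mc_count", "total_count"]
    records[cols].to_csv(path, sep="\t", index=False)


def read_cytosine_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "accession": str})
    bad = df[(df["mc_count"] < 0) | (df["mc_count"] > df["total_count"])]
    if len(bad):
        raise ValueError(f"{len(bad)} cytosine records have mc_count outside [0, total_count]")
    return df


# --------------------------------------------------------------- expression


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# --------------------------------------------------------------- annotation


def write_annotation_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """genes: columns gene_id, chrom, start (0-based), end, strand."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\tepiqtl\tgene\t{int(g['start']) + 1}\t{int(g['end'])}"
                f"\t.\t{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def read_annotation_gff3(path: str | Path) -> pd.DataFrame:
    """Gene features as a DataFrame with 0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    for gene in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": gene.id,
                "chrom": str(gene.seqid),
                "start": gene.start - 1,
                "end": gene.end,
                "strand": gene.strand,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# -------------------------------------------------------- bins and kinships


def write_bins_tsv(bins: pd.DataFrame, path: str | Path) -> None:
    """BED-like: chrom, start, end, context_class, then one column/accession."""
    acc = [c for c in bins.columns if c not in BIN_META_COLUMNS]
    bins[BIN_META_COLUMNS + acc].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bins_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_kinship_tsv(matrix: np.ndarray, accessions: list[str], path: str | Path) -> None:
    pd.DataFrame(matrix, index=accessions, columns=accessions).to_csv(
        path, sep="\t", index_label="accession"
    )


def read_kinship_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="accession")
    return df.to_numpy(dtype=float), list(df.columns)
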