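"""Readers and writers for the pipeline's on-disk formats.

Formats handled: PAV matrix TSV, long coverage TSV, population-map TSV,
VCF v4.2 (GT-only writing; reading via cyvcf2), GFF3 gene models (via
gffutils), PAF contig alignments, bedgraph depth tracks, BED intervals.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from panpav.containers import MISSING, VariantPanel, validate_pav

# ---------------------------------------------------------------------------
# TSV tables


def read_pav_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a PAV matrix TSV (first column gene ID, header = sample IDs)."""
    pav = pd.read_csv(path, sep="\t", index_col=0)
    return validate_pav(pav.astype(np.int8))


def write_pav_tsv(pav: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_pav(pav)
    pav.to_csv(path, sep="\t", index_label="gene")


def read_coverage_tsv(path: str | os.PathLike) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t")
    expected = {"gene", "sample", "gene_breadth", "cds_breadth"}
    if not expected.issubset(cov.columns):
        raise ValueError(f"coverage TSV missing columns {expected - set(cov.columns)}")
    return cov


def write_coverage_tsv(cov: pd.DataFrame, path: str | os.PathLike) -> None:
    cov.to_csv(path, sep="\t", index=False)


def read_popmap_tsv(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (sample, population) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def write_popmap_tsv(popmap: Mapping[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(sorted(popmap.items()), columns=["sample", "population"]).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# VCF


def write_vcf(panel: VariantPanel, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields.

    Dosage 0/1/2 maps to 0/0, 0/1, 1/1; missing maps to ./.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = pd.unique(panel.sites["chrom"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panpav\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        sites = panel.sites
        for i in range(panel.n_sites):
            row = sites.iloc[i]
            qual = "." if pd.isna(row["qual"]) else f"{row['qual']:g}"
            gts = "\t".join(gt_strings[int(g)] for g in panel.genotypes[i])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(
    path: str | os.PathLike, popmap: Mapping[str, str] | None = None
) -> VariantPanel:
    """Read a VCF into a :class:`VariantPanel` using cyvcf2.

    Multi-allelic records are retained (alt alleles comma-joined) so the
    bi-allelic filter can tally them; any non-reference allele counts
    toward the dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": ",".join(var.ALT) if var.ALT else ".",
                "qual": var.QUAL if var.QUAL is not None else np.nan,
            }
        )
        gt = np.asarray(var.genotype.array())[:, :2]
        missing = (gt < 0).any(axis=1)
        dos = (gt > 0).sum(axis=1).astype(np.int8)
        dos[missing] = MISSING
        dosages.append(dos)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    genotypes = (
        np.vstack(dosages) if dosages else np.empty((0, len(samples)), dtype=np.int8)
    )
    return VariantPanel(sites, genotypes, samples, dict(popmap or {}))


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Extract gene models from GFF3 into a flat table.

    Returns one row per gene: ``gene``, ``chrom``, ``start``, ``end``
    (converted to 0-based half-open) and ``cds`` (list of 0-based
    half-open (start, end) tuples across the gene's mRNAs, un-merged).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        cds = [
            (c.start - 1, c.end)
            for c in db.children(gene, featuretype="CDS", order_by="start")
        ]
        rows.append(
            {
                "gene": gene.id,
                "chrom": gene.seqid,
                "start": gene.start - 1,
                "end": gene.end,
                "cds": cds,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "cds"])


# ---------------------------------------------------------------------------
# PAF / bedgraph / BED

PAF_COLUMNS = [
    "query", "query_len", "qstart", "qend", "strand",
    "target", "target_len", "tstart", "tend", "matches", "block_len",
]


def read_paf(path: str | os.PathLike) -> pd.DataFrame:
    """Read the first 11 columns of a PAF alignment file."""
    return pd.read_csv(
        path, sep="\t", header=None, usecols=range(11), names=PAF_COLUMNS
    )


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    """Read a bedgraph depth track (chrom, start, end, depth; 0-based half-open)."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        comment="#",
    )


def write_bed(intervals: Iterable[tuple], path: str | os.PathLike) -> None:
    """Write (chrom, start, end) intervals as 0-based half-open BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")
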