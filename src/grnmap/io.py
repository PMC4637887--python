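"""Readers and writers for the standard formats the pipeline touches.

VCF (v4.x, biallelic SNPs) via pysam, FASTA promoters via Biopython, and
TSV tables (phenotypes / expression / covariates) via pandas.  All writers
emit deterministic row and column order.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .datatypes import (
    Cohort,
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    PromoterSet,
    SNPRecord,
    StructureCovariates,
)


class VCFContentError(ValueError):
    pass


def read_vcf(path: str | Path, strict_biallelic: bool = False) -> GenotypeMatrix:
    """Load a VCF of biallelic SNPs into a minor-allele-count matrix.

    Genotype codes count the minor allele determined per site from the loaded
    cohort, not the VCF ALT allele; missing GTs become NaN.  Multiallelic
    records raise (``strict_biallelic=True``) or are skipped with a warning.
    The per-site ``gene_id`` is taken from an INFO ``GENE`` tag when present.
    """
    vf = pysam.VariantFile(str(path))
    individual_ids = list(vf.header.samples)
    snps: list[SNPRecord] = []
    columns: list[np.ndarray] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 \
                or len(rec.alts[0]) != 1:
            if strict_biallelic:
                raise VCFContentError(
                    f"non-biallelic-SNP record at {rec.chrom}:{rec.pos}"
                )
            warnings.warn(f"skipping non-biallelic-SNP record at {rec.chrom}:{rec.pos}")
            continue
        col = np.full(len(individual_ids), np.nan)
        for i, sample in enumerate(individual_ids):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            col[i] = float(sum(gt))  # ALT-allele count for now
        gene = rec.info.get("GENE", "")
        if isinstance(gene, tuple):
            gene = gene[0]
        snp_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        snps.append(
            SNPRecord(
                snp_id=snp_id,
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                gene_id=str(gene),
            )
        )
        columns.append(col)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(individual_ids), 0))
    )
    gm = GenotypeMatrix(individual_ids, snps, calls)
    gm.recompute_maf()  # orient codes to the cohort minor allele
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix back out as VCF v4.2 (uncompressed text).

    Codes are converted back to REF/ALT genotypes using each record's
    ``minor_is_alt`` orientation, so ``read_vcf(write_vcf(gm))`` reproduces
    the same minor-allele codes.
    """
    lines = ["##fileformat=VCFv4.2"]
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = []
    for s in gm.snps:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += gm.individual_ids
    lines.append("\t".join(header))
    for j, s in enumerate(gm.snps):
        gts = []
        for code in gm.calls[:, j]:
            if np.isnan(code):
                gts.append("./.")
                continue
            n_alt = int(code) if s.minor_is_alt else 2 - int(code)
            gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[n_alt])
        info = f"GENE={s.gene_id}" if s.gene_id else "."
        row = [s.chrom, str(s.pos), s.snp_id, s.ref_allele, s.alt_allele,
               ".", "PASS", info, "GT"] + gts
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_promoters_fasta(path: str | Path, promoter_length: int = 2000) -> PromoterSet:
    """Read promoter sequences; header token 1 is the gene id."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate gene id in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return PromoterSet(seqs, promoter_length=promoter_length)


def write_promoters_fasta(promoters: PromoterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in promoters.gene_ids:
            fh.write(f">{gid}\n{promoters[gid]}\n")


_MISSING_MARKERS = ["NA", "NaN", "nan", ""]


def _read_numeric_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_MISSING_MARKERS,
        keep_default_na=False, dtype=str,
    )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated identifier in {path}: {dup!r}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            row = bad.index[0]
            raise ValueError(
                f"non-numeric cell in {path} at row {row!r}, column {col!r}: "
                f"{bad.iloc[0]!r}"
            ) from None
    return out


def read_table(path: str | Path, kind: str):
    """Read a TSV with header row and identifier first column.

    kind: 'phenotype' -> PhenotypeTable; 'expression' -> ExpressionMatrix;
    'covariates' -> StructureCovariates.
    """
    df = _read_numeric_tsv(path)
    ids = [str(i) for i in df.index]
    if kind == "phenotype":
        return PhenotypeTable(ids, df.astype(float))
    if kind == "expression":
        return ExpressionMatrix(ids, list(df.columns), df.to_numpy(dtype=float))
    if kind == "covariates":
        if df.isna().any().any():
            raise ValueError("covariates table may not contain missing values")
        return StructureCovariates(ids, df.to_numpy(dtype=float))
    raise ValueError(f"unknown table kind {kind!r}")


def write_table(obj, path: str | Path) -> None:
    """Write a phenotype / expression / covariates object as TSV."""
    if isinstance(obj, PhenotypeTable):
        df = obj.traits
        df.to_csv(path, sep="\t", index_label="individual_id")
    elif isinstance(obj, ExpressionMatrix):
        obj.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")
    elif isinstance(obj, StructureCovariates):
        df = pd.DataFrame(
            obj.q,
            index=obj.individual_ids,
            columns=[f"Q{i + 1}" for i in range(obj.k)],
        )
        df.to_csv(path, sep="\t", index_label="individual_id")
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")


def align_cohort(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    covariates: StructureCovariates | None = None,
) -> Cohort:
    """Restrict all inputs to the sorted intersection of individual ids."""
    common = set(genotypes.individual_ids) & set(phenotypes.individual_ids)
    if covariates is not None:
        common &= set(covariates.individual_ids)
    if not common:
        raise ValueError("no individuals common to all inputs")
    ids = sorted(common)
    all_ids = set(genotypes.individual_ids) | set(phenotypes.individual_ids)
    if covariates is not None:
        all_ids |= set(covariates.individual_ids)
    dropped = sorted(all_ids - common)
    return Cohort(
        genotypes=genotypes.subset_individuals(ids),
        phenotypes=phenotypes.subset_individuals(ids),
        covariates=covariates.subset_individuals(ids) if covariates else None,
        dropped_ids=dropped,
    )
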