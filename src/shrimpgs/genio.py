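"""Readers and writers for the plain-text formats the pipeline exchanges.

The dosage TSV (individuals as rows, marker ids as header, ``NA`` for missing)
is the canonical internal format; VCF v4.2 with GT-only records is supported
for interoperability. Phenotype, family and square-matrix TSVs round-trip the
remaining containers.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FamilyStructure, GenotypeMatrix, PhenotypeTable

_GT_TO_DOSAGE = {0: 0.0, 1: 1.0, 2: 1.0, 3: 2.0}  # cyvcf2 gt_types; 2 = unknown


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.individual_ids, columns=genotypes.marker_ids
    )
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_dosage_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal GT-only VCF v4.2 (unphased, './.' for missing).

    Fractional dosages cannot be represented; the caller must pass integral
    (pre-imputation) genotypes.
    """
    d = genotypes.dosages
    vals = d[~np.isnan(d)]
    if vals.size and not np.allclose(vals, np.round(vals)):
        raise ValueError("VCF output requires integral dosages")
    m = genotypes.n_markers
    chrom = genotypes.chrom if genotypes.chrom is not None else np.array(["1"] * m)
    pos = genotypes.pos if genotypes.pos is not None else np.arange(1, m + 1)
    ref = genotypes.ref if genotypes.ref is not None else np.array(["A"] * m)
    alt = genotypes.alt if genotypes.alt is not None else np.array(["T"] * m)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j in range(m):
            calls = [
                "./." if np.isnan(x) else gt_strings[int(round(x))] for x in d[:, j]
            ]
            fh.write(
                f"{chrom[j]}\t{int(pos[j])}\t{genotypes.marker_ids[j]}\t"
                f"{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; multi-allelic records are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    marker_ids, chrom, pos, ref, alt, rows = [], [], [], [], [], []
    for k, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                f"(record {k}, id {variant.ID or '.'}) — split or remove it first"
            )
        marker_ids.append(
            variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}"
        )
        chrom.append(variant.CHROM)
        pos.append(variant.POS)
        ref.append(variant.REF)
        alt.append(variant.ALT[0])
        row = np.array(
            [np.nan if t == 2 else _GT_TO_DOSAGE[t] for t in variant.gt_types],
            dtype=float,
        )
        rows.append(row)
    return GenotypeMatrix(
        individual_ids=individual_ids,
        marker_ids=marker_ids,
        dosages=np.vstack(rows).T if rows else np.empty((len(individual_ids), 0)),
        chrom=np.array(chrom),
        pos=np.array(pos),
        ref=np.array(ref),
        alt=np.array(alt),
    )


def read_genotypes(path: str | os.PathLike, format: str = "auto") -> GenotypeMatrix:
    """Dispatch on ``format`` ('vcf' | 'dosage_tsv' | 'auto' by extension)."""
    if format == "auto":
        format = "vcf" if str(path).endswith(".vcf") else "dosage_tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_phenotypes(phenotypes: PhenotypeTable, path: str | os.PathLike) -> None:
    phenotypes.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["individual_id"] = df["individual_id"].astype(str)
    return PhenotypeTable(df)


def write_families(families: FamilyStructure, path: str | os.PathLike) -> None:
    families.table.to_csv(path, sep="\t", index=False)


def read_families(path: str | os.PathLike) -> FamilyStructure:
    df = pd.read_csv(path, sep="\t")
    for col in ("individual_id", "sire_id", "dam_id"):
        df[col] = df[col].astype(str)
    return FamilyStructure(df)


def write_matrix_tsv(
    ids: list[str], values: np.ndarray, path: str | os.PathLike
) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_matrix_tsv(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
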