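"""Readers and writers for the study's text formats.

Pedigree, genotype-dosage, phenotype and truth tables travel as TSV;
genotypes can also be read from / written to VCF (biallelic SNPs, unphased
GT).  Relationship matrices have their own writers on
:class:`~herit.relmat.RelationshipMatrix`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix
from .pedigree import PedigreeTable

log = logging.getLogger("herit")

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_dosage", "write_dosage",
    "read_phenotypes", "write_phenotypes",
    "write_truth",
    "read_vcf", "write_vcf",
]


def read_pedigree(path: str | Path) -> PedigreeTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    return PedigreeTable.from_frame(df)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def read_dosage(path: str | Path) -> GenotypeMatrix:
    """Dosage TSV: rows = individuals (first column `id`), columns = SNP ids,
    entries 0/1/2 or NA."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    ids = list(df["id"])
    snp_ids = [c for c in df.columns if c != "id"]
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids,
                          counts=df[snp_ids].to_numpy(float))


def write_dosage(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.counts, columns=g.snp_ids)
    # keep dosages as integers where complete, NA where missing
    df = df.astype("Int64") if not np.isnan(g.counts).any() else df
    df.insert(0, "id", g.ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    # default float repr is shortest-roundtrip, so a resumed run reloading
    # this file sees bit-identical phenotypes
    df.to_csv(path, sep="\t", index=False)


def write_truth(truth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


# ----------------------------------------------------------------------
_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with unphased GT; the counted allele is ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.ids) + "\n")
        for j, snp in enumerate(g.snp_ids):
            calls = "\t".join(
                _GT.get(x, "./.") if not np.isnan(x) else "./."
                for x in g.counts[:, j]
            )
            fh.write(f"1\t{j + 1}\t{snp}\tA\tB\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """Read biallelic SNP records into alt-allele counts.

    Returns the genotype matrix and the number of records skipped for not
    being biallelic.  Uses cyvcf2's genotype classification (missing calls
    become NaN dosages).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    lookup = np.array([0.0, 1.0, np.nan, 2.0])
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            skipped += 1
            continue
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(lookup[np.asarray(var.gt_types)])
    vcf.close()
    if skipped:
        log.info("read_vcf(%s): skipped %d non-biallelic records", path, skipped)
    counts = np.column_stack(rows) if rows else np.empty((len(ids), 0))
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids, counts=counts), skipped
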