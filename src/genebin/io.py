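"""Reading and writing genotype, phenotype and result files.

Two genotype formats are supported: VCF (biallelic SNP records with GT
calls, parsed with cyvcf2) and a plain TSV matrix whose first column is
the sample id and whose header row carries SNP ids.  Phenotypes are TSV
with columns ``sample`` and ``trait``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .data import MIN_MAF, GenotypeMatrix, Phenotype

logger = logging.getLogger(__name__)


def read_genotypes(
    path: str | Path,
    format: Literal["vcf", "matrix"] = "matrix",
    min_maf: float = MIN_MAF,
) -> GenotypeMatrix:
    """Load a genotype matrix for one gene region.

    Additive coding always counts the minor allele: columns where the
    coded allele is the major allele in the sample are recoded 2 - g.
    Monomorphic SNPs and SNPs with sample MAF below ``min_maf`` are
    dropped with a warning.  MAF is recomputed from the sample, never
    taken from file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, min_maf)
    if format == "matrix":
        return _read_matrix(path, min_maf)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, min_maf: float) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, positions, columns = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} ({rec.ID}); "
                "split or drop it before loading"
            )
        arr = rec.genotype.array()
        alt_count = (arr[:, :2] > 0).sum(axis=1).astype(float)
        if (arr[:, :2] < 0).any():
            raise ValueError(
                f"missing genotype at {rec.CHROM}:{rec.POS}; complete data required"
            )
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        positions.append(rec.POS)
        columns.append(alt_count)
    if not columns:
        raise ValueError(f"no biallelic SNP records in {path}")
    G = np.column_stack(columns)
    return GenotypeMatrix.from_raw(samples, ids, positions, G, min_maf=min_maf)


def _read_matrix(path: Path, min_maf: float) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no SNP columns")
    samples = [str(s) for s in df.index]
    snp_ids = [str(c) for c in df.columns]
    positions = list(range(1, len(snp_ids) + 1))
    return GenotypeMatrix.from_raw(samples, snp_ids, positions, df.to_numpy(), min_maf=min_maf)


def read_phenotype(path: str | Path) -> Phenotype:
    """Read a TSV phenotype file with columns ``sample`` and ``trait``."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "trait" not in cols:
        raise ValueError(f"{path}: expected columns 'sample' and 'trait'")
    return Phenotype(
        [str(s) for s in df[cols["sample"]]], df[cols["trait"]].to_numpy(dtype=float)
    )


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        gm.G.astype(int), index=pd.Index(gm.samples, name="sample"), columns=gm.snp_ids
    )
    df.to_csv(path, sep="\t")


def write_phenotype(ph: Phenotype, path: str | Path) -> None:
    pd.DataFrame({"sample": ph.samples, "trait": ph.y}).to_csv(path, sep="\t", index=False)


def write_vcf(gm: GenotypeMatrix, path: str | Path, chrom: str = "1") -> None:
    """Write genotypes as a minimal VCF 4.2 text file (GT only).

    The coded (counted) allele is written as ALT, so reading the file
    back reproduces the same additive coding.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, snp in enumerate(gm.snps):
            calls = "\t".join(gt_codes[int(g)] for g in gm.G[:, j])
            fh.write(f"{chrom}\t{snp.position}\t{snp.id}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n")


def write_bin_report(snp_ids: Iterable[str], bin_of, flipped, path: str | Path) -> None:
    pd.DataFrame(
        {"snp": list(snp_ids), "bin": np.asarray(bin_of), "flipped": np.asarray(flipped)}
    ).to_csv(path, sep="\t", index=False)


def write_results(results, path: str | Path) -> None:
    """Write a list of TestResult objects as one TSV row each."""
    rows = []
    for r in results:
        rows.append(
            {
                "statistic": r.name,
                "analysis_set": r.analysis_set,
                "value": r.value,
                "df": r.df if r.df is not None else "",
                "n_snps": r.n_snps,
                "n_bins": r.n_bins if r.n_bins is not None else "",
                "p_value": r.p_value,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
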