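"""Readers for every external file dialect the tool consumes.

Dialects: VCF v4.x (GT field, diploid), PLINK ``.raw`` dosage export,
plain genotype matrix TSV (rows = samples, header = SNP ids), FAM-style
pedigree, SetID-style region file (two columns: region_id snp_id),
square kinship TSV, and the phenotype table (TSV with header, missing =
``NA``).  All genotype access is by id; alignment to the phenotype
sample order is explicit (:func:`GenotypeSource.subset_samples`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix, Pedigree

logger = logging.getLogger("kinskat")

__all__ = [
    "GenotypeSource",
    "read_genotypes",
    "read_regions",
    "read_phenotypes",
    "read_fam",
    "read_kinship",
    "write_kinship",
]


@dataclass
class GenotypeSource:
    """In-memory dosage store with lookup by SNP id."""

    backend: str
    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # n x m, np.nan = missing

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids in genotype source")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicated SNP ids in genotype source")
        self._snp_pos = {s: j for j, s in enumerate(self.snp_ids)}

    def get_columns(self, snp_ids: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
        """Dosage columns for the requested SNPs, preserving request order.

        Returns ``(matrix, found_ids, missing_ids)``; unknown ids are
        reported, not fatal.
        """
        found = [s for s in snp_ids if s in self._snp_pos]
        missing = [s for s in snp_ids if s not in self._snp_pos]
        cols = self.dosages[:, [self._snp_pos[s] for s in found]] if found else np.empty((len(self.sample_ids), 0))
        return cols, found, missing

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeSource":
        """Align rows to ``sample_ids`` (by id).  Samples present here but
        not requested are dropped with a log line; a requested sample
        missing from the source is an error."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        absent = [s for s in sample_ids if s not in pos]
        if absent:
            raise ValueError(
                f"phenotyped samples missing from genotypes: {absent[:5]}"
                " (exclude them from the phenotype table or fix the genotype file)"
            )
        extra = len(self.sample_ids) - len(sample_ids)
        if extra > 0:
            logger.info("dropping %d genotyped samples absent from phenotypes", extra)
        take = [pos[s] for s in sample_ids]
        return GenotypeSource(self.backend, list(sample_ids), list(self.snp_ids),
                              self.dosages[take])


def _read_vcf(path: str) -> GenotypeSource:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            logger.info("skipping multi-allelic site %s", v.ID or f"{v.CHROM}:{v.POS}")
            continue
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        dos = np.empty(len(samples))
        for i, g in enumerate(v.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise ValueError(f"non-diploid GT at record {vid} sample {samples[i]}")
            if -1 in alleles:
                dos[i] = np.nan
            else:
                dos[i] = float(alleles[0] + alleles[1])
        snp_ids.append(vid)
        cols.append(dos)
    vcf.close()
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeSource("vcf", samples, snp_ids, dosages)


def _read_plink_raw(path: str) -> GenotypeSource:
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in df.columns:
        raise ValueError("PLINK .raw file must carry an IID column")
    snp_cols = [c for c in df.columns if c not in meta]
    # .raw SNP columns carry a _A allele suffix; strip it for the id
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    dosages = df[snp_cols].to_numpy(dtype=float)
    return GenotypeSource("plink_raw", df["IID"].astype(str).tolist(), snp_ids, dosages)


def _read_matrix_tsv(path: str) -> GenotypeSource:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    snp_ids = list(df.columns[1:])
    return GenotypeSource(
        "matrix_tsv",
        df[id_col].astype(str).tolist(),
        snp_ids,
        df[snp_ids].to_numpy(dtype=float),
    )


def read_genotypes(path, backend: str = "auto") -> GenotypeSource:
    """Load genotype dosages from VCF, PLINK .raw, or matrix TSV."""
    path = str(path)
    if backend == "auto":
        if path.endswith((".vcf", ".vcf.gz")):
            backend = "vcf"
        elif path.endswith(".raw"):
            backend = "plink_raw"
        else:
            backend = "matrix_tsv"
    readers = {"vcf": _read_vcf, "plink_raw": _read_plink_raw, "matrix_tsv": _read_matrix_tsv}
    if backend not in readers:
        raise ValueError(f"unknown genotype backend {backend!r}")
    return readers[backend](path)


def read_regions(path) -> dict[str, list[str]]:
    """SetID-style two-column file -> ordered region map.

    Preserves file order of regions and of SNPs within a region;
    duplicate (region, snp) pairs are dropped with a log line.
    """
    regions: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'region_id snp_id', got {line!r}")
            rid, sid = parts
            if (rid, sid) in seen:
                logger.info("%s:%d: duplicate pair (%s, %s) ignored", path, ln, rid, sid)
                continue
            seen.add((rid, sid))
            regions.setdefault(rid, []).append(sid)
    return regions


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table: TSV with header; first column must be 'id'; NA = missing."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("phenotype table must have an 'id' column")
    if df["id"].duplicated().any():
        raise ValueError("duplicated sample ids in phenotype table")
    return df


def read_fam(path) -> Pedigree:
    """FAM-style pedigree: family_id individual_id father mother sex [pheno]."""
    fams, ids, fas, mos, sexes = [], [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected at least 5 columns")
            fams.append(parts[0])
            ids.append(parts[1])
            fas.append(parts[2])
            mos.append(parts[3])
            try:
                sexes.append(int(parts[4]))
            except ValueError:
                sexes.append(0)
    return Pedigree(ids, fas, mos, sexes, family_ids=fams)


def read_kinship(path) -> KinshipMatrix:
    """Square kinship TSV: first row and column are sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(s) for s in df.columns]
    row_ids = [str(s) for s in df.index]
    if ids != row_ids:
        raise ValueError("kinship TSV row and column ids differ")
    return KinshipMatrix(ids, df.to_numpy(dtype=float))


def write_kinship(km: KinshipMatrix, path) -> None:
    pd.DataFrame(km.values, index=km.sample_ids, columns=km.sample_ids).to_csv(
        path, sep="\t"
    )
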