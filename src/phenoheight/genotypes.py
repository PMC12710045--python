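"""Genotype matrix container and VCF 4.2 round-trip.

Dosages are stored samples x SNPs as int8 allele counts of the alternate
allele (0/1/2), with -1 marking a missing call. Reading goes through cyvcf2;
writing emits minimal uncompressed VCF 4.2 with GT fields only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-dosage matrix with positions and identifiers."""

    dosages: np.ndarray  # int8, samples x SNPs, -1 = missing
    chrom: np.ndarray  # per-SNP chromosome name
    pos: np.ndarray  # per-SNP 1-based bp position
    sample_ids: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        n, m = self.dosages.shape
        if not (len(self.chrom) == len(self.pos) == len(self.snp_ids) == m):
            raise ValueError("per-SNP arrays must match the dosage matrix width")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids must match the dosage matrix height")
        bad = (self.dosages < -1) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        # positions sorted within chromosome
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.dosages == MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency among non-missing calls."""
        d = self.dosages.astype(float)
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_alt = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * n_obs)
        p_alt = np.where(n_obs == 0, np.nan, p_alt)
        return np.minimum(p_alt, 1.0 - p_alt)

    def imputed(self) -> np.ndarray:
        """Float dosages with missing calls mean-imputed per SNP."""
        d = self.dosages.astype(float)
        miss = d == MISSING
        d[miss] = np.nan
        col_mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        idx = np.where(miss)
        d[idx] = col_mean[idx[1]]
        return d

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, index],
            self.chrom[index],
            self.pos[index],
            self.sample_ids,
            self.snp_ids[index],
        )


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal uncompressed VCF 4.2 (GT only, synthetic REF/ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(G.chrom.astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids.astype(str))
            + "\n"
        )
        for j in range(G.n_snps):
            gts = "\t".join(_GT[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{G.chrom[j]}\t{G.pos[j]}\t{G.snp_ids[j]}\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read GT dosages from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.array(vcf.samples, dtype=object)
    chrom, pos, ids, rows = [], [], [], []
    for var in vcf:
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types
        row = np.where(gt == 3, 2, gt).astype(np.int8)
        row[gt == 2] = MISSING
        rows.append(row)
    vcf.close()
    dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(dosages, np.array(chrom, object), np.array(pos), samples, np.array(ids, object))
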