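"""Phased haplotype matrices and their on-disk formats.

A :class:`HaplotypeMatrix` holds one chromosome of phased biallelic
haplotypes: two rows per diploid individual (rows ``2k`` and ``2k+1``
belong to individual ``k``), one column per SNP, entries 0/1.

Two formats are supported:

* phased VCF (``GT`` fields with ``|`` separators; ``/`` is an error),
  read through :mod:`cyvcf2`;
* a simple hap/map text pair -- the hap file has one row per haplotype
  (individual id followed by 0/1 alleles, two consecutive rows per
  individual), the map file has columns ``snp_id  chrom  bp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "HaplotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_hapmap",
    "write_hapmap",
]


@dataclass
class HaplotypeMatrix:
    alleles: np.ndarray  # (2 * n_individuals, n_sites) of 0/1
    positions: np.ndarray  # bp per site, strictly increasing
    snp_ids: list[str]
    individual_ids: list[str]
    chrom: str = "1"
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise DataError("allele matrix must be 2-dimensional")
        if self.alleles.shape[0] != 2 * len(self.individual_ids):
            raise DataError("haplotype rows must be 2 per individual")
        if self.alleles.shape[1] != len(self.positions) or len(self.snp_ids) != len(
            self.positions
        ):
            raise DataError("positions / snp ids do not match site count")
        if np.any(self.alleles > 1):
            raise DataError("alleles must be 0/1")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise DataError("positions must be strictly increasing")
        self._index = {iid: k for k, iid in enumerate(self.individual_ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def individual_of_haplotype(self, row: int) -> str:
        """Individual id owning haplotype row ``row``."""
        return self.individual_ids[row // 2]

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the '1' allele per site."""
        return self.alleles.mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per site."""
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def genotypes(self, minor: bool = True) -> np.ndarray:
        """Per-individual allele counts, ``(n_individuals, n_sites)``.

        With ``minor=True`` counts copies of the minor allele (ties count
        the '1' allele), otherwise copies of the '1' allele.
        """
        g = self.alleles[0::2].astype(np.int8) + self.alleles[1::2]
        if minor:
            flip = self.allele_frequency() > 0.5
            g = np.where(flip, 2 - g, g)
        return g

    def filter_maf(self, threshold: float = 0.05) -> "HaplotypeMatrix":
        """Drop sites with minor allele frequency below ``threshold``."""
        keep = self.maf() >= threshold
        return self.take_sites(np.flatnonzero(keep))

    def take_sites(self, sites: np.ndarray) -> "HaplotypeMatrix":
        sites = np.asarray(sites, dtype=np.int64)
        return HaplotypeMatrix(
            self.alleles[:, sites],
            self.positions[sites],
            [self.snp_ids[i] for i in sites],
            list(self.individual_ids),
            self.chrom,
        )

    def drop_site(self, site: int) -> "HaplotypeMatrix":
        keep = np.concatenate(
            [np.arange(site), np.arange(site + 1, self.n_sites)]
        )
        return self.take_sites(keep)

    def take_individuals(self, ids: list[str]) -> "HaplotypeMatrix":
        rows = np.empty(2 * len(ids), dtype=np.int64)
        for j, iid in enumerate(ids):
            try:
                k = self._index[iid]
            except KeyError:
                raise DataError(f"individual {iid!r} not genotyped") from None
            rows[2 * j] = 2 * k
            rows[2 * j + 1] = 2 * k + 1
        return HaplotypeMatrix(
            self.alleles[rows], self.positions, list(self.snp_ids), list(ids), self.chrom
        )


def read_vcf(path: str, maf_threshold: float = 0.0) -> HaplotypeMatrix:
    """Read phased biallelic genotypes from a VCF.

    Unphased genotypes ('/' separator) and missing alleles raise
    :class:`DataError`.  Sites below ``maf_threshold`` are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    individual_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    positions: list[int] = []
    snp_ids: list[str] = []
    chrom = "1"
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(f"site {var.ID or var.POS} is not biallelic")
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        col = np.empty(2 * len(individual_ids), dtype=np.uint8)
        for k, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise DataError(f"missing genotype at {var.ID or var.POS}")
            if not phased and a != b:
                raise DataError(
                    f"unphased heterozygote at {var.ID or var.POS}, sample "
                    f"{individual_ids[k]}"
                )
            col[2 * k] = a
            col[2 * k + 1] = b
        cols.append(col)
        positions.append(var.POS)
        snp_ids.append(var.ID or f"snp_{var.POS}")
        chrom = var.CHROM
    if not cols:
        raise DataError(f"no variants in {path}")
    hap = HaplotypeMatrix(
        np.column_stack(cols), np.array(positions), snp_ids, individual_ids, chrom
    )
    if maf_threshold > 0:
        hap = hap.filter_maf(maf_threshold)
    return hap


def write_vcf(hap: HaplotypeMatrix, path: str) -> None:
    """Write a minimal phased VCF (v4.2, alleles A/G placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hap.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hap.individual_ids)
            + "\n"
        )
        for j in range(hap.n_sites):
            col = hap.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * k]}|{col[2 * k + 1]}" for k in range(hap.n_individuals)
            )
            fh.write(
                f"{hap.chrom}\t{hap.positions[j]}\t{hap.snp_ids[j]}\tA\tG\t.\t"
                f"PASS\t.\tGT\t{gts}\n"
            )


def read_hapmap(
    hap_path: str, map_path: str, maf_threshold: float = 0.0
) -> HaplotypeMatrix:
    """Read the simple hap/map text pair."""
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["snp_id", "chrom", "bp"], dtype=str
    )
    if mp.iloc[0]["bp"].lower() in ("bp", "pos", "position"):
        mp = mp.iloc[1:].reset_index(drop=True)
    positions = mp["bp"].astype(np.int64).to_numpy()
    snp_ids = mp["snp_id"].tolist()
    chrom = str(mp["chrom"].iloc[0])

    rows: list[np.ndarray] = []
    individual_ids: list[str] = []
    with open(hap_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            iid, alleles = parts[0], parts[1:]
            if len(rows) % 2 == 0:
                individual_ids.append(iid)
            elif individual_ids[-1] != iid:
                raise DataError(
                    f"hap file rows not paired per individual near {iid!r}"
                )
            rows.append(np.array(alleles, dtype=np.uint8))
    if len(rows) % 2 != 0:
        raise DataError("hap file has an odd number of haplotype rows")
    hap = HaplotypeMatrix(np.vstack(rows), positions, snp_ids, individual_ids, chrom)
    if maf_threshold > 0:
        hap = hap.filter_maf(maf_threshold)
    return hap


def write_hapmap(hap: HaplotypeMatrix, hap_path: str, map_path: str) -> None:
    with open(map_path, "w") as fh:
        for sid, pos in zip(hap.snp_ids, hap.positions):
            fh.write(f"{sid}\t{hap.chrom}\t{pos}\n")
    with open(hap_path, "w") as fh:
        for r in range(hap.n_haplotypes):
            iid = hap.individual_of_haplotype(r)
            fh.write(iid + " " + " ".join(map(str, hap.alleles[r])) + "\n")
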