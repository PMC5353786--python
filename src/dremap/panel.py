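"""Phased haplotype panel: a SNP-by-haplotype 0/1 matrix with alleles.

The panel emulates a reference-population genotype resource (phased
diploid samples). It round-trips through a minimal phased-GT VCF dialect:
fixed columns plus per-sample ``a|b`` genotype fields, two haplotypes per
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HaplotypePanel:
    snps: pd.DataFrame  # snp_id, chrom, pos, ref, alt — row order == matrix rows
    haplotypes: np.ndarray  # shape (n_snps, n_haplotypes), entries 0 (ref) / 1 (alt)

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 2 or len(self.snps) != self.haplotypes.shape[0]:
            raise ValueError("haplotype matrix shape does not match SNP table")
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1 (phased, no missing)")
        self._row = {s: i for i, s in enumerate(self.snps["snp_id"])}

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._row

    def row(self, snp_id: str) -> int:
        if snp_id not in self._row:
            raise KeyError(f"SNP {snp_id} not in panel")
        return self._row[snp_id]

    def column(self, snp_id: str) -> np.ndarray:
        return self.haplotypes[self.row(snp_id)]

    def alleles(self, snp_id: str) -> tuple[str, str]:
        r = self.row(snp_id)
        return self.snps.iloc[r]["ref"], self.snps.iloc[r]["alt"]

    def allele_codes(self, snp_id: str, allele: str) -> np.ndarray:
        """Boolean mask over haplotypes carrying ``allele`` at the SNP."""
        ref, alt = self.alleles(snp_id)
        col = self.column(snp_id)
        if allele == ref:
            return col == 0
        if allele == alt:
            return col == 1
        return np.zeros_like(col, dtype=bool)

    def write_vcf(self, path) -> None:
        if self.n_haplotypes % 2:
            raise ValueError("phased VCF output needs an even haplotype count")
        n_samples = self.n_haplotypes // 2
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(sample_ids) + "\n")
            for i, row in enumerate(self.snps.itertuples(index=False)):
                hap = self.haplotypes[i]
                gts = "\t".join(f"{hap[2*j]}|{hap[2*j+1]}" for j in range(n_samples))
                fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.snp_id}\t{row.ref}\t"
                         f"{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def read_vcf(cls, path) -> "HaplotypePanel":
        meta_rows, hap_rows = [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                chrom, pos, snp_id, ref, alt = fields[:5]
                meta_rows.append((snp_id, chrom, int(pos) - 1, ref, alt))
                haps = []
                for gt in fields[9:]:
                    if "|" not in gt:
                        raise ValueError(f"{snp_id}: unphased genotype {gt!r}")
                    a, b = gt.split("|")
                    haps.extend((int(a), int(b)))
                hap_rows.append(haps)
        snps = pd.DataFrame(meta_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
        matrix = np.array(hap_rows, dtype=np.int8) if hap_rows else np.empty((0, 0), dtype=np.int8)
        return cls(snps, matrix)
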