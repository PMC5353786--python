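"""Haplotype association between a CLL-associated allele and a GWAS risk allele.

Over all chromosomes (haplotypes) of a phased reference panel, a 2x2
table counts co-occurrence of the CLL-associated allele at SNP m with the
risk allele at the tag SNP m_tag:

    D11 = #(1|m, 1|m_tag)   D12 = #(1|m, 2|m_tag)
    D21 = #(2|m, 1|m_tag)   D22 = #(2|m, 2|m_tag)

with "2|·" pooling every non-focal allele. The association is tested with
Fisher's exact test and summarized by the odds ratio OR = D11*D22 / (D12*D21).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import HaplotypePanel


@dataclass
class HaplotypeTable:
    D11: int
    D12: int
    D21: int
    D22: int

    def __post_init__(self) -> None:
        if min(self.D11, self.D12, self.D21, self.D22) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def total(self) -> int:
        return self.D11 + self.D12 + self.D21 + self.D22

    def as_array(self) -> np.ndarray:
        return np.array([[self.D11, self.D12], [self.D21, self.D22]])


def build_contingency(panel: HaplotypePanel, m: str, cll_allele: str,
                      m_tag: str, risk_allele: str) -> HaplotypeTable:
    """Count panel chromosomes by focal-allele carriage at both SNPs."""
    for snp in (m, m_tag):
        if snp not in panel:
            raise ValueError(f"SNP {snp} missing from panel")
    a = panel.allele_codes(m, cll_allele)
    b = panel.allele_codes(m_tag, risk_allele)
    return HaplotypeTable(
        D11=int(np.sum(a & b)),
        D12=int(np.sum(a & ~b)),
        D21=int(np.sum(~a & b)),
        D22=int(np.sum(~a & ~b)),
    )


def odds_ratio(table: HaplotypeTable) -> float:
    """OR = D11*D22 / (D12*D21); inf when only the denominator vanishes,
    nan when both products are zero."""
    num = table.D11 * table.D22
    den = table.D12 * table.D21
    if den == 0:
        return math.inf if num > 0 else float("nan")
    return num / den


def fisher_exact_p(table: HaplotypeTable, alternative: str = "two-sided") -> float:
    """Fisher's exact p (two-sided by the point-probability rule: sum of
    all tables at the margins with probability <= the observed table's)."""
    _, p = stats.fisher_exact(table.as_array(), alternative=alternative)
    return float(p)
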