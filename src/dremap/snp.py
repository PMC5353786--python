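"""Read-level SNP assay classification and case/control association.

SNPs covered by bisulfite reads are tested for a genotypic difference
between the case (CLL) and control classes. For an allele k, with n_k,c
its pooled occurrence count among the n_c case allele observations and
p_k,n its pooled frequency in controls, the association statistic is the
strict upper-tail binomial probability

    Pr(X > n_k,c) = 1 - sum_{i<=n_k,c} C(n_c, i) p^i (1-p)^(n_c - i).

The same form is applied to each diploid genotype state with control
genotype-state frequencies. A SNP is called associated when the minimum
over all allele and genotype tails falls below alpha (default 0.05); the
allele with the largest positive case-minus-control frequency excess is
the CLL-associated allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENOTYPE_STATES = ("hom_ref", "het", "hom_alt")


@dataclass
class SnpReadCounts:
    """Pooled read-level evidence for one SNP in both classes."""

    snp_id: str
    chrom: str
    pos: int
    case_allele_counts: dict[str, int]
    control_allele_counts: dict[str, int]
    case_genotype_counts: dict[str, int] = field(default_factory=dict)
    control_genotype_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.case_allele_counts, self.control_allele_counts,
                  self.case_genotype_counts, self.control_genotype_counts):
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{self.snp_id}: negative count")

    @property
    def total_reads(self) -> int:
        return sum(self.case_allele_counts.values()) + sum(self.control_allele_counts.values())

    def observed_alleles(self) -> list[str]:
        alleles = {a for a, c in self.case_allele_counts.items() if c > 0}
        alleles |= {a for a, c in self.control_allele_counts.items() if c > 0}
        return sorted(alleles)


@dataclass
class SnpAssociationResult:
    snp_id: str
    allele_p: dict[str, float]
    genotype_p: dict[str, float]
    min_p: float
    is_cll_associated: bool
    cll_allele: str | None
    wt_allele: str | None
    zero_control_support: bool  # some tested category absent from controls


def classify_assay_status(counts: SnpReadCounts, min_reads: int = 10) -> str:
    """assayed_polymorphic (>= 2 alleles in pooled reads), non_assayed
    (monomorphic, < min_reads pooled reads) or non_mutated (monomorphic,
    >= min_reads)."""
    if len(counts.observed_alleles()) >= 2:
        return "assayed_polymorphic"
    return "non_assayed" if counts.total_reads < min_reads else "non_mutated"


def allele_tail_probability(n_kc: int, n_c: int, p_kn: float) -> float:
    """Strict upper-tail binomial probability Pr(X > n_kc), X ~ Bin(n_c, p_kn)."""
    if not 0 <= p_kn <= 1:
        raise ValueError("p_kn must be in [0, 1]")
    if not 0 <= n_kc <= n_c:
        raise ValueError("need 0 <= n_kc <= n_c")
    return float(stats.binom.sf(n_kc, n_c, p_kn))


def call_cll_associated(counts: SnpReadCounts, alpha: float = 0.05) -> SnpAssociationResult:
    """Minimum-tail association call over alleles and genotype states.

    Control frequencies are pooled read (or genotype) counts without
    pseudocounts; a category unobserved in controls has p = 0, making any
    case observation a zero tail — flagged via ``zero_control_support`` so
    callers can require minimum control depth.
    """
    if classify_assay_status(counts) != "assayed_polymorphic":
        raise ValueError(f"{counts.snp_id}: association requires a polymorphic, assayed SNP")
    n_c = sum(counts.case_allele_counts.values())
    n_ctrl = sum(counts.control_allele_counts.values())
    if n_ctrl == 0:
        raise ValueError(f"{counts.snp_id}: control class empty")
    zero_support = False
    allele_p: dict[str, float] = {}
    for allele in counts.observed_alleles():
        p_kn = counts.control_allele_counts.get(allele, 0) / n_ctrl
        if p_kn == 0:
            zero_support = True
        allele_p[allele] = allele_tail_probability(
            counts.case_allele_counts.get(allele, 0), n_c, p_kn)
    genotype_p: dict[str, float] = {}
    n_geno_case = sum(counts.case_genotype_counts.values())
    n_geno_ctrl = sum(counts.control_genotype_counts.values())
    if n_geno_case and n_geno_ctrl:
        states = [s for s in GENOTYPE_STATES
                  if counts.case_genotype_counts.get(s, 0)
                  or counts.control_genotype_counts.get(s, 0)]
        for state in states:
            p = counts.control_genotype_counts.get(state, 0) / n_geno_ctrl
            if p == 0:
                zero_support = True
            genotype_p[state] = allele_tail_probability(
                counts.case_genotype_counts.get(state, 0), n_geno_case, p)
    min_p = min([*allele_p.values(), *genotype_p.values()])
    associated = min_p < alpha
    cll_allele = wt_allele = None
    if associated:
        excess = {
            a: counts.case_allele_counts.get(a, 0) / n_c
            - counts.control_allele_counts.get(a, 0) / n_ctrl
            for a in counts.observed_alleles()
        }
        best = max(sorted(excess), key=lambda a: excess[a])
        if excess[best] > 0:
            cll_allele = best
            others = [a for a in counts.observed_alleles() if a != best]
            wt_allele = max(others, key=lambda a: counts.control_allele_counts.get(a, 0)) if others else None
        else:
            associated = False
    return SnpAssociationResult(counts.snp_id, allele_p, genotype_p, min_p,
                                associated, cll_allele, wt_allele, zero_support)


def association_table(all_counts: list[SnpReadCounts], alpha: float = 0.05,
                      min_reads: int = 10) -> pd.DataFrame:
    """Batch call over a SNP list; non-assayable SNPs carry status only."""
    rows = []
    for c in all_counts:
        status = classify_assay_status(c, min_reads=min_reads)
        row = {"snp_id": c.snp_id, "chrom": c.chrom, "pos": c.pos, "status": status,
               "min_p": None, "is_cll_associated": False,
               "cll_allele": None, "wt_allele": None}
        if status == "assayed_polymorphic" and sum(c.control_allele_counts.values()) > 0:
            res = call_cll_associated(c, alpha=alpha)
            row.update(min_p=res.min_p, is_cll_associated=res.is_cll_associated,
                       cll_allele=res.cll_allele, wt_allele=res.wt_allele)
        rows.append(row)
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: pd.Series, alpha: float = 0.05) -> pd.Series:
    """Optional FDR control over the min-p column (off by default in the
    pipeline, which uses the raw alpha rule)."""
    from statsmodels.stats.multitest import multipletests

    mask = p_values.notna()
    out = pd.Series(False, index=p_values.index)
    if mask.any():
        rejected, *_ = multipletests(p_values[mask], alpha=alpha, method="fdr_bh")
        out[mask] = rejected
    return out
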