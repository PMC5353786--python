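"""GWAS catalog LD expansion, trait agglomeration and permutation enrichment.

Tag SNPs from a GWAS catalog are expanded to all panel SNPs in tight LD
(r^2 > 0.8 within 500 kb, in at least one supplied panel). Traits are
agglomerated by keyword into the categories CLL > lymphoma (excluding
CLL) > cancer > irrelevant, the last serving as baseline. The association
of a trait-SNP set with a region class is the count of trait SNPs inside
that class, tested by shuffling class labels among the fixed region
coordinates and recounting.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel
from .regions import RegulatoryRegion

logger = logging.getLogger(__name__)

DEFAULT_KEYWORD_RULES: dict[str, list[str]] = {
    # precedence order: CLL > lymphoma > cancer; anything else is irrelevant
    "CLL": [r"chronic lymphocytic leuk", r"\bcll\b"],
    "lymphoma": [r"lymphoma"],
    "cancer": [r"cancer", r"carcinoma", r"leuk[ae]mia", r"tumou?r",
               r"melanoma", r"glioma", r"myeloma", r"sarcoma", r"neoplas"],
}
CATEGORY_ORDER = ("CLL", "lymphoma", "cancer", "irrelevant")


def compute_r2(panel: HaplotypePanel, snp_a: str, snp_b: str) -> float:
    """Squared allelic correlation from phased haplotypes.

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)); nan (with a
    warning) when either SNP is monomorphic in the panel. Symmetric in its
    arguments and invariant to swapping allele labels at either SNP.
    """
    a = panel.column(snp_a).astype(float)
    b = panel.column(snp_b).astype(float)
    p_a, p_b = a.mean(), b.mean()
    var = p_a * (1 - p_a) * p_b * (1 - p_b)
    if var == 0:
        warnings.warn(f"monomorphic SNP in r2({snp_a}, {snp_b}); undefined")
        return float("nan")
    p_ab = np.mean(a * b)
    return float((p_ab - p_a * p_b) ** 2 / var)


@dataclass
class TraitSnpSet:
    trait: str
    snps: set[str]
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "tag_snp", "r2", "panel"])
    )


def expand_ld(catalog: pd.DataFrame, panels: dict[str, HaplotypePanel],
              r2_min: float = 0.8, max_dist: int = 500_000) -> dict[str, TraitSnpSet]:
    """Per trait, the tag SNPs plus every panel SNP in tight LD with one.

    A partner joins when r^2 > r2_min and |pos difference| < max_dist in
    at least one panel. Tags absent from all panels keep only themselves.
    """
    if not panels:
        raise ValueError("need at least one haplotype panel")
    out: dict[str, TraitSnpSet] = {}
    for trait, grp in catalog.groupby("trait"):
        snps: set[str] = set(grp["snp_id"])
        prov_rows = []
        for tag_row in grp.itertuples(index=False):
            tag = tag_row.snp_id
            found = False
            for panel_name, panel in panels.items():
                if tag not in panel:
                    continue
                found = True
                tag_pos = int(panel.snps.iloc[panel.row(tag)]["pos"])
                tag_chrom = panel.snps.iloc[panel.row(tag)]["chrom"]
                near = panel.snps[
                    (panel.snps["chrom"] == tag_chrom)
                    & (abs(panel.snps["pos"] - tag_pos) < max_dist)
                    & (panel.snps["snp_id"] != tag)
                ]
                for cand in near["snp_id"]:
                    r2 = compute_r2(panel, tag, cand)
                    if np.isfinite(r2) and r2 > r2_min:
                        snps.add(cand)
                        prov_rows.append((cand, tag, r2, panel_name))
            if not found:
                logger.info("tag SNP %s absent from all panels; trait %s keeps tag only",
                            tag, trait)
        prov = pd.DataFrame(prov_rows, columns=["snp_id", "tag_snp", "r2", "panel"])
        out[trait] = TraitSnpSet(trait, snps, prov)
    return out


def agglomerate_traits(catalog: pd.DataFrame,
                       keyword_rules: dict[str, list[str]] | None = None,
                       trait_sets: dict[str, TraitSnpSet] | None = None) -> dict[str, TraitSnpSet]:
    """Merge traits into CLL / lymphoma / cancer / irrelevant categories.

    Precedence CLL > lymphoma > cancer: a trait matching a CLL keyword
    never lands in lymphoma or cancer. Category SNP sets are disjoint
    (a SNP follows its highest-precedence trait) and cover the catalog.
    """
    rules = keyword_rules if keyword_rules is not None else DEFAULT_KEYWORD_RULES
    compiled = {cat: [re.compile(p, re.IGNORECASE) for p in pats]
                for cat, pats in rules.items()}

    def categorize(trait: str) -> str:
        for cat in CATEGORY_ORDER[:-1]:
            if any(p.search(trait) for p in compiled.get(cat, [])):
                return cat
        return "irrelevant"

    cat_snps: dict[str, set[str]] = {c: set() for c in CATEGORY_ORDER}
    traits = (trait_sets.keys() if trait_sets is not None
              else catalog["trait"].unique())
    for trait in traits:
        cat = categorize(trait)
        if trait_sets is not None:
            cat_snps[cat] |= trait_sets[trait].snps
        else:
            cat_snps[cat] |= set(catalog.loc[catalog["trait"] == trait, "snp_id"])
    # precedence: strip lower categories of SNPs claimed by higher ones
    claimed: set[str] = set()
    out: dict[str, TraitSnpSet] = {}
    for cat in CATEGORY_ORDER:
        snps = cat_snps[cat] - claimed
        claimed |= snps
        out[cat] = TraitSnpSet(cat, snps)
    return out


@dataclass
class EnrichmentTest:
    observed_count: int
    density_per_1000: float
    p_value: float        # add-one permutation p
    p_raw: float          # raw exceedance fraction
    n_perm: int
    seed: int
    n_class_snps: int


def snps_in_regions(positions: pd.DataFrame, regions: list[RegulatoryRegion]) -> np.ndarray:
    """Boolean mask over a SNP table (chrom, pos) for membership in any of
    the regions (half-open; a SNP exactly at ``end`` is outside)."""
    mask = np.zeros(len(positions), dtype=bool)
    by_chrom: dict[str, list[RegulatoryRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, group in by_chrom.items():
        rows = positions["chrom"] == chrom
        if not rows.any():
            continue
        pos = positions.loc[rows, "pos"].to_numpy()
        sub = np.zeros(len(pos), dtype=bool)
        for r in group:
            sub |= (pos >= r.start) & (pos < r.end)
        mask[rows.to_numpy()] = sub
    return mask


def permutation_enrichment(regions: list[RegulatoryRegion], labels: list[str],
                           panel_positions: pd.DataFrame, trait_snp_ids: set[str],
                           target_label: str = "gained", n_perm: int = 1000,
                           seed: int = 0) -> EnrichmentTest:
    """Permutation test of trait-SNP overlap with one region class.

    ``panel_positions`` holds every panel SNP (snp_id, chrom, pos); trait
    SNPs are the subset in ``trait_snp_ids``. Labels are shuffled over the
    fixed regions n_perm times; p = (1 + #{perm >= observed}) / (n_perm + 1)
    with the raw exceedance fraction also reported. Density is trait SNPs
    per 1,000 panel SNPs inside the class.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels_arr = np.asarray(labels)
    if len(labels_arr) != len(regions):
        raise ValueError("labels and regions length mismatch")
    # per-region SNP counts, so a label permutation is a vector gather
    is_trait = panel_positions["snp_id"].isin(trait_snp_ids).to_numpy()
    trait_per_region = np.empty(len(regions), dtype=np.int64)
    panel_per_region = np.empty(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        inside = snps_in_regions(panel_positions, [r])
        panel_per_region[i] = inside.sum()
        trait_per_region[i] = (inside & is_trait).sum()
    target_mask = labels_arr == target_label
    observed = int(trait_per_region[target_mask].sum())
    n_class_snps = int(panel_per_region[target_mask].sum())
    if n_class_snps == 0:
        warnings.warn("no panel SNPs in target class; density undefined")
        density = float("nan")
    else:
        density = 1000 * observed / n_class_snps
    rng = np.random.default_rng(seed)
    n_target = int(target_mask.sum())
    exceed = 0
    idx = np.arange(len(regions))
    for _ in range(n_perm):
        chosen = rng.permutation(idx)[:n_target]
        if trait_per_region[chosen].sum() >= observed:
            exceed += 1
    return EnrichmentTest(
        observed_count=observed,
        density_per_1000=density,
        p_value=(1 + exceed) / (n_perm + 1),
        p_raw=exceed / n_perm,
        n_perm=n_perm,
        seed=seed,
        n_class_snps=n_class_snps,
    )
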