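"""Gene linkage of regulatory regions and expression-based enrichment.

Each region is assigned to the single gene with the closest TSS. Gene
expression fold change (case mean / control mean) ranks genes; the top
percentile up- or down-regulated set G is tested for enrichment among
dREs (R) against the shared-element baseline (S):

    enrichment = fract(R, G) / fract(S, G)

with fract(X, G) the fraction of X regions linked to G among X regions
linked to any expression-measured gene. Significance is a one-sided
binomial tail with n = n_R trials and success probability fract(S, G).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegulatoryRegion

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    fract_R_G: float
    fract_S_G: float
    enrichment: float
    p_value: float          # tail in the observed direction
    p_enrichment: float     # P(X >= observed)
    p_depletion: float      # P(X <= observed)
    direction: str          # "enrichment" or "depletion"
    n_R: int
    n_S: int
    observed: int


def _region_tss_distance(region: RegulatoryRegion, tss: int) -> int:
    """0 when the TSS lies inside the half-open region, else distance to
    the nearest end base."""
    return max(region.start - tss, tss - (region.end - 1), 0)


def assign_to_nearest_tss(region: RegulatoryRegion, tss_table: pd.DataFrame) -> tuple[str | None, int | None]:
    """(gene_id, distance) of the closest-TSS gene on the region's
    chromosome; ties go to the lexicographically smaller gene id."""
    genes = tss_table[tss_table["chrom"] == region.chrom]
    if not len(genes):
        logger.warning("no TSS on %s; region %s unassigned", region.chrom, region)
        return None, None
    dist = np.array([_region_tss_distance(region, t) for t in genes["tss"]])
    best = dist.min()
    candidates = sorted(genes.loc[dist == best, "gene_id"])
    return candidates[0], int(best)


def assign_regions(regions: list[RegulatoryRegion], tss_table: pd.DataFrame) -> pd.DataFrame:
    """Vector assignment: one row per region (chrom, start, end, gene_id, distance)."""
    rows = []
    for r in regions:
        gene, dist = assign_to_nearest_tss(r, tss_table)
        rows.append((r.chrom, r.start, r.end, gene, dist))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "distance"])


def compute_fold_change(expr_table: pd.DataFrame, min_expr: float = 0.1) -> pd.DataFrame:
    """Fold change = case mean / control mean for genes whose average
    expression reaches ``min_expr`` in both classes; others are flagged
    excluded and carry no fold change."""
    if (expr_table[["case_mean", "control_mean"]] < 0).any().any():
        raise ValueError("expression must be nonnegative")
    out = expr_table[["gene_id", "case_mean", "control_mean"]].copy()
    out["excluded"] = (out["case_mean"] < min_expr) | (out["control_mean"] < min_expr)
    out["fold_change"] = np.where(
        out["excluded"], np.nan, out["case_mean"] / out["control_mean"].where(out["control_mean"] > 0)
    )
    return out


def rank_de_genes(fold_changes: pd.DataFrame, top_percent: float, direction: str) -> set[str]:
    """Top-percentile genes by fold change among the expression-passing
    universe. direction "up" ranks by descending fold change, "down" by
    ascending. Ties at the cutoff break deterministically by gene id."""
    if not 0 < top_percent <= 100:
        raise ValueError("top_percent must be in (0, 100]")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    passing = fold_changes[~fold_changes["excluded"]].copy()
    if not len(passing):
        return set()
    ascending = direction == "down"
    passing = passing.sort_values(["fold_change", "gene_id"],
                                  ascending=[ascending, True], kind="mergesort")
    k = max(1, math.ceil(len(passing) * top_percent / 100))
    return set(passing["gene_id"].head(k))


def dre_gene_enrichment(dre_assignments: pd.DataFrame, sre_assignments: pd.DataFrame,
                        gene_set: set[str], measured_genes: set[str]) -> EnrichmentResult:
    """Enrichment of gene set G near dREs relative to the sRE baseline.

    Denominators are restricted to regions whose nearest gene has a
    reliable expression measurement.
    """
    dre = dre_assignments[dre_assignments["gene_id"].isin(measured_genes)]
    sre = sre_assignments[sre_assignments["gene_id"].isin(measured_genes)]
    n_R, n_S = len(dre), len(sre)
    if n_R == 0 or n_S == 0:
        raise ValueError("no regions linked to expression-measured genes")
    observed = int(dre["gene_id"].isin(gene_set).sum())
    fract_R_G = observed / n_R
    fract_S_G = float(sre["gene_id"].isin(gene_set).mean())
    if fract_S_G == 0:
        enrichment = math.inf if fract_R_G > 0 else float("nan")
        p_enr = 0.0 if observed > 0 else 1.0
        p_dep = 1.0
    else:
        enrichment = fract_R_G / fract_S_G
        p_enr = float(stats.binom.sf(observed - 1, n_R, fract_S_G))
        p_dep = float(stats.binom.cdf(observed, n_R, fract_S_G))
    direction = "enrichment" if fract_R_G >= fract_S_G else "depletion"
    p_value = p_enr if direction == "enrichment" else p_dep
    return EnrichmentResult(fract_R_G, fract_S_G, enrichment, p_value,
                            p_enr, p_dep, direction, n_R, n_S, observed)


def find_multi_lost_genes(lost_assignments: pd.DataFrame,
                          gained_assignments: pd.DataFrame,
                          min_count: int = 2) -> pd.DataFrame:
    """Genes linked to >= min_count lost dREs and zero gained dREs."""
    if not len(lost_assignments):
        return pd.DataFrame(columns=["gene_id", "n_lost", "n_gained"])
    lost_counts = lost_assignments.groupby("gene_id").size().rename("n_lost")
    gained_counts = gained_assignments.groupby("gene_id").size() if len(gained_assignments) else pd.Series(dtype=int)
    out = lost_counts.reset_index()
    out["n_gained"] = out["gene_id"].map(gained_counts).fillna(0).astype(int)
    out = out[(out["n_lost"] >= min_count) & (out["n_gained"] == 0)]
    return out.reset_index(drop=True)
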