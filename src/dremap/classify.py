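"""Contrast case and control region maps into gained/lost/shared/hiMR.

A case hypomethylated region that overlaps (>= min_overlap_bp) any control
hypomethylated region becomes part of a shared element (sRE) whose
coordinates are the union of the overlapping pair; transitive chains merge
into one shared region. A case region with no such overlap is a gained dRE
(active in cancer only); an unmatched control region is a lost dRE. hiMRs
are the interval intersections of the case and control hypermethylated
maps, with the minimum-CpG requirement re-checked on the intersection when
consensus profiles are supplied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneAnnotation, interval_overlap_bp, track_index
from .consensus import CombinedProfile
from .regions import RegulatoryRegion

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "exonic", "intronic", "intergenic")


@dataclass
class ReClassMap:
    """Partition of regulatory regions by activity change."""

    gained: list[RegulatoryRegion] = field(default_factory=list)
    lost: list[RegulatoryRegion] = field(default_factory=list)
    shared: list[RegulatoryRegion] = field(default_factory=list)
    himr: list[RegulatoryRegion] = field(default_factory=list)

    def classes(self) -> dict[str, list[RegulatoryRegion]]:
        return {"gained": self.gained, "lost": self.lost,
                "shared": self.shared, "himr": self.himr}

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.classes().items()}

    def labeled_regions(self) -> tuple[list[RegulatoryRegion], list[str]]:
        regions, labels = [], []
        for name, group in self.classes().items():
            regions.extend(group)
            labels.extend([name] * len(group))
        return regions, labels


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _merged_component(members: list[tuple[str, RegulatoryRegion]]) -> RegulatoryRegion:
    chrom = members[0][1].chrom
    start = min(r.start for _, r in members)
    end = max(r.end for _, r in members)
    n_cpg = sum(r.n_cpg for _, r in members)
    total = sum(r.length for _, r in members)
    mean_meth = sum(r.mean_meth * r.length for _, r in members) / total
    return RegulatoryRegion(chrom, start, end, n_cpg, mean_meth, "hypo",
                            provenance=tuple(side for side, _ in members))


def _count_cpgs(profile: CombinedProfile | None, chrom: str, start: int, end: int) -> int | None:
    if profile is None:
        return None
    sub = profile.sites
    sub = sub[(sub["chrom"] == chrom) & (sub["pos"] >= start) & (sub["pos"] < end)]
    return len(sub)


def _intersect_hyper(case_hyper: list[RegulatoryRegion],
                     lost_hyper: list[RegulatoryRegion],
                     min_overlap_bp: int,
                     n_cpg_cutoff: int,
                     case_profile: CombinedProfile | None,
                     control_profile: CombinedProfile | None) -> list[RegulatoryRegion]:
    by_chrom: dict[str, IntervalTree] = {}
    for r in lost_hyper:
        by_chrom.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    out = []
    for a in case_hyper:
        tree = by_chrom.get(a.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(a.start, a.end)):
            b = iv.data
            s, e = max(a.start, b.start), min(a.end, b.end)
            if e - s < min_overlap_bp:
                continue
            nc_case = _count_cpgs(case_profile, a.chrom, s, e)
            nc_ctrl = _count_cpgs(control_profile, a.chrom, s, e)
            counted = [c for c in (nc_case, nc_ctrl) if c is not None]
            if counted and min(counted) < n_cpg_cutoff:
                continue
            n_cpg = min(counted) if counted else min(a.n_cpg, b.n_cpg)
            mean_meth = (a.mean_meth + b.mean_meth) / 2
            out.append(RegulatoryRegion(a.chrom, s, e, n_cpg, mean_meth, "hyper"))
    return out


def classify_regions(case_hypo: list[RegulatoryRegion],
                     control_hypo: list[RegulatoryRegion],
                     case_hyper: list[RegulatoryRegion],
                     control_hyper: list[RegulatoryRegion],
                     min_overlap_bp: int = 1,
                     n_cpg_cutoff: int = 3,
                     case_profile: CombinedProfile | None = None,
                     control_profile: CombinedProfile | None = None) -> ReClassMap:
    """Partition case/control hypo maps into gained/lost/shared and build hiMRs.

    Exactly antisymmetric: swapping the case and control arguments swaps
    gained with lost and leaves shared and hiMR coordinates unchanged.
    """
    tagged = [("case", r) for r in case_hypo] + [("control", r) for r in control_hypo]
    uf = _UnionFind(len(tagged))
    by_chrom: dict[str, IntervalTree] = {}
    for idx, (_, r) in enumerate(tagged):
        if tagged[idx][0] == "control":
            by_chrom.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, idx)
    for idx, (side, r) in enumerate(tagged):
        if side != "case":
            continue
        tree = by_chrom.get(r.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(r.start, r.end):
            other = tagged[iv.data][1]
            if r.overlap_bp(other) >= min_overlap_bp:
                uf.union(idx, iv.data)

    components: dict[int, list[tuple[str, RegulatoryRegion]]] = {}
    for idx, (side, r) in enumerate(tagged):
        components.setdefault(uf.find(idx), []).append((side, r))

    result = ReClassMap()
    for members in components.values():
        sides = {side for side, _ in members}
        if sides == {"case"}:
            for _, r in members:
                result.gained.append(r)
        elif sides == {"control"}:
            for _, r in members:
                result.lost.append(r)
        else:
            result.shared.append(_merged_component(members))
    result.himr = _intersect_hyper(case_hyper, control_hyper, min_overlap_bp,
                                   n_cpg_cutoff, case_profile, control_profile)
    for group in result.classes().values():
        group.sort(key=lambda r: (r.chrom, r.start, r.end))
    return result


def annotate_genomic_category(region: RegulatoryRegion,
                              annotation: GeneAnnotation,
                              promoter_window: tuple[int, int] = (1000, 500)) -> str:
    """Categorize a region: promoter > exonic > intronic > intergenic.

    The promoter window spans ``upstream_bp`` before to ``downstream_bp``
    after the TSS, strand-aware.
    """
    if annotation.chrom_lengths:
        limit = annotation.chrom_lengths.get(region.chrom)
        if limit is None or region.start < 0 or region.end > limit:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} outside chromosome bounds"
            )
    up, down = promoter_window
    genes = annotation.genes[annotation.genes["chrom"] == region.chrom]
    for tss, strand in zip(genes["tss"], genes["strand"]):
        if strand == "-":
            w_start, w_end = tss - down + 1, tss + up + 1
        else:
            w_start, w_end = tss - up, tss + down
        if min(region.end, w_end) > max(region.start, w_start):
            return "promoter"
    exons = annotation.exons[annotation.exons["chrom"] == region.chrom]
    for s, e in zip(exons["start"], exons["end"]):
        if min(region.end, e) > max(region.start, s):
            return "exonic"
    for s, e in zip(genes["start"], genes["end"]):
        if min(region.end, e) > max(region.start, s):
            return "intronic"
    return "intergenic"


def annotate_classmap(classmap: ReClassMap, annotation: GeneAnnotation,
                      promoter_window: tuple[int, int] = (1000, 500)) -> None:
    """Assign genomic_category in place for every region in the map."""
    for group in classmap.classes().values():
        for r in group:
            r.genomic_category = annotate_genomic_category(r, annotation, promoter_window)


def repeat_fraction(regions: list[RegulatoryRegion], repeat_track: pd.DataFrame) -> float:
    """Fraction of the group's base pairs covered by the (merged) track."""
    if not regions:
        warnings.warn("repeat_fraction of an empty region group is undefined")
        return float("nan")
    idx = track_index(repeat_track)
    covered = sum(interval_overlap_bp(r.chrom, r.start, r.end, idx) for r in regions)
    total = sum(r.length for r in regions)
    return covered / total


def cgi_overlap_fraction(regions: list[RegulatoryRegion], cgi_track: pd.DataFrame,
                         by_category: bool = False):
    """Fraction of regions with >= 1 bp CpG-island overlap.

    With ``by_category`` the fraction is reported per genomic category
    (regions must be annotated first).
    """
    if not regions:
        warnings.warn("cgi_overlap_fraction of an empty region list is undefined")
        return float("nan")
    idx = track_index(cgi_track)
    hits = np.array([
        interval_overlap_bp(r.chrom, r.start, r.end, idx) > 0 for r in regions
    ])
    if not by_category:
        return float(hits.mean())
    cats = pd.Series([r.genomic_category for r in regions])
    return {cat: float(hits[(cats == cat).to_numpy()].mean())
            for cat in cats.dropna().unique()}


def classmap_summary(classmap: ReClassMap, repeat_track: pd.DataFrame | None = None,
                     cgi_track: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-class counts plus optional repeat/CGI composition."""
    rows = []
    for name, group in classmap.classes().items():
        row: dict = {"class": name, "n": len(group)}
        for cat in CATEGORIES:
            row[cat] = sum(1 for r in group if r.genomic_category == cat)
        if repeat_track is not None and group:
            row["repeat_fraction"] = repeat_fraction(group, repeat_track)
        if cgi_track is not None and group:
            row["cgi_fraction"] = cgi_overlap_fraction(group, cgi_track)
        rows.append(row)
    return pd.DataFrame(rows)
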