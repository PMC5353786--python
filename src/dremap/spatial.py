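"""Spatial statistics of regulatory regions.

Within-class nearest-neighbor distances (edge-to-edge, same chromosome,
overlap counts as 0) characterize clustering of gained and lost elements;
cross-class distances measure how gained elements sit relative to lost
ones. The null keeps region coordinates fixed and shuffles the class
labels, preserving class sizes; the observed distance distribution is
compared with the pooled permutation distances by a one-sided rank-sum
test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .regions import RegulatoryRegion

logger = logging.getLogger(__name__)


def _nearest_within(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Nearest edge-to-edge distance to another interval of the same set.

    Intervals sorted by start. For each i the nearest neighbor to the right
    (by start) is the next interval; to the left it is the interval with the
    largest end among predecessors. Overlap gives distance 0.
    """
    n = len(starts)
    out = np.full(n, np.inf)
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    # right neighbor: next start minus own end
    right = np.maximum(s[1:] - e[:-1], 0)
    out_sorted = np.full(n, np.inf)
    out_sorted[:-1] = right
    # left neighbor: own start minus running max of predecessor ends
    run_max = np.maximum.accumulate(e[:-1]) if n > 1 else np.array([])
    left = np.maximum(s[1:] - run_max, 0)
    out_sorted[1:] = np.minimum(out_sorted[1:], left)
    out[order] = out_sorted
    return out


def within_class_distances(regions: list[RegulatoryRegion]) -> np.ndarray:
    """Per region, distance to the nearest same-class region on the same
    chromosome; regions alone on their chromosome are excluded."""
    if len(regions) < 2:
        warnings.warn("fewer than 2 regions; no within-class distances")
        return np.array([])
    by_chrom: dict[str, list[RegulatoryRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    dists = []
    for chrom, group in sorted(by_chrom.items()):
        if len(group) < 2:
            logger.info("region alone on %s excluded from distances", chrom)
            continue
        starts = np.array([r.start for r in group])
        ends = np.array([r.end for r in group])
        dists.append(_nearest_within(starts, ends))
    return np.concatenate(dists) if dists else np.array([])


def _nearest_to_set(q_starts, q_ends, t_starts, t_ends) -> np.ndarray:
    """For each query interval, edge-to-edge distance to nearest target."""
    order = np.argsort(t_starts, kind="mergesort")
    ts, te = t_starts[order], t_ends[order]
    te_runmax = np.maximum.accumulate(te)
    out = np.empty(len(q_starts))
    for i, (qs, qe) in enumerate(zip(q_starts, q_ends)):
        # right candidates: targets with start >= qe; nearest is the smallest start
        j = np.searchsorted(ts, qe, side="left")
        d_right = max(ts[j] - qe, 0) if j < len(ts) else np.inf
        # left candidates: targets with start < qe → overlap or left gap
        d_left = np.inf
        if j > 0:
            d_left = max(qs - te_runmax[j - 1], 0)
        out[i] = min(d_right, d_left)
    return out


def cross_class_distances(gained: list[RegulatoryRegion],
                          lost: list[RegulatoryRegion]) -> np.ndarray:
    """For each gained region, distance to the nearest lost region on the
    same chromosome; gained regions on chromosomes without lost regions are
    excluded."""
    if not gained or not lost:
        warnings.warn("empty region class; no cross-class distances")
        return np.array([])
    lost_by_chrom: dict[str, list[RegulatoryRegion]] = {}
    for r in lost:
        lost_by_chrom.setdefault(r.chrom, []).append(r)
    dists = []
    for chrom in sorted({r.chrom for r in gained}):
        targets = lost_by_chrom.get(chrom)
        queries = [r for r in gained if r.chrom == chrom]
        if not targets:
            logger.info("no lost regions on %s; %d gained excluded", chrom, len(queries))
            continue
        dists.append(_nearest_to_set(
            np.array([r.start for r in queries]), np.array([r.end for r in queries]),
            np.array([r.start for r in targets]), np.array([r.end for r in targets]),
        ))
    return np.concatenate(dists) if dists else np.array([])


@dataclass
class DistanceDistribution:
    observed: np.ndarray
    background_pooled: np.ndarray
    background_mean_quantiles: np.ndarray  # averaged distribution over perms
    quantile_grid: np.ndarray
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str = "less"


def shuffle_label_background(regions: list[RegulatoryRegion], labels: list[str],
                             target_label: str, n_perm: int = 1000, seed: int = 0,
                             cross_label: str | None = None,
                             alternative: str = "less") -> DistanceDistribution:
    """Label-shuffle null for the distance distribution of one class.

    Coordinates stay fixed; labels are permuted uniformly n_perm times.
    Without ``cross_label`` the statistic is the within-class distance set
    of ``target_label``; with it, distances from target regions to the
    nearest ``cross_label`` region. The observed distribution is compared
    against the pooled permutation distances with a one-sided
    Mann-Whitney rank-sum test (default direction: observed shorter).
    The per-permutation distributions are also averaged on a fixed
    quantile grid.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(labels) != len(regions):
        raise ValueError("labels and regions length mismatch")
    labels_arr = np.asarray(labels)

    def statistic_for(lab: np.ndarray) -> np.ndarray:
        target = [r for r, l in zip(regions, lab) if l == target_label]
        if cross_label is None:
            return within_class_distances(target)
        other = [r for r, l in zip(regions, lab) if l == cross_label]
        return cross_class_distances(target, other)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = statistic_for(labels_arr)
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 1, 101)
        pooled = []
        quantiles = []
        for _ in range(n_perm):
            perm = rng.permutation(labels_arr)
            d = statistic_for(perm)
            if len(d):
                pooled.append(d)
                quantiles.append(np.quantile(d, grid))
    background = np.concatenate(pooled) if pooled else np.array([])
    mean_q = np.mean(quantiles, axis=0) if quantiles else np.full_like(grid, np.nan)
    if len(observed) and len(background):
        stat, p = stats.mannwhitneyu(observed, background, alternative=alternative)
    else:
        stat, p = float("nan"), float("nan")
    return DistanceDistribution(observed, background, mean_q, grid,
                                float(stat), float(p), n_perm, seed, alternative)


@dataclass
class LostDreClusters:
    selected: list[RegulatoryRegion]
    clusters: list[list[RegulatoryRegion]]


def cluster_lost_dres(lost: list[RegulatoryRegion], max_gap: int = 10_000) -> LostDreClusters:
    """Lost dREs whose nearest within-class neighbor is closer than
    ``max_gap``, grouped into single-linkage chains at that gap."""
    if not lost:
        return LostDreClusters([], [])
    dists_all = np.full(len(lost), np.inf)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(lost):
        by_chrom.setdefault(r.chrom, []).append(i)
    for idxs in by_chrom.values():
        if len(idxs) < 2:
            continue
        starts = np.array([lost[i].start for i in idxs])
        ends = np.array([lost[i].end for i in idxs])
        dists_all[idxs] = _nearest_within(starts, ends)
    selected_idx = [i for i in range(len(lost)) if dists_all[i] < max_gap]
    selected = [lost[i] for i in selected_idx]
    clusters: list[list[RegulatoryRegion]] = []
    for chrom in sorted({r.chrom for r in selected}):
        group = sorted((r for r in selected if r.chrom == chrom),
                       key=lambda r: (r.start, r.end))
        current = [group[0]]
        max_end = group[0].end
        for r in group[1:]:
            if r.start - max_end < max_gap:
                current.append(r)
                max_end = max(max_end, r.end)
            else:
                clusters.append(current)
                current = [r]
                max_end = r.end
        clusters.append(current)
    return LostDreClusters(selected, clusters)
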