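"""Run-based segmentation of a consensus methylation profile.

A hypomethylated region is a maximal run of consecutive assayed CpGs whose
consensus methylation is below ``meth_cutoff`` (default 0.5), broken where
the gap between consecutive CpGs exceeds ``max_gap_bp``, and kept only when
the run holds at least ``n_cpg_cutoff`` CpGs (default 3). Hypermethylated
regions use the complementary predicate meth >= cutoff; a site exactly at
the cutoff is hyper. Region coordinates span the first CpG to the last CpG
position + 2 (half-open, covering the final dinucleotide).
"""

from __future__ import annotations

import numpy as np

from .consensus import CombinedProfile
from .regions import RegulatoryRegion


def _segment_mask(pos: np.ndarray, meth: np.ndarray, mask: np.ndarray,
                  chrom: str, n_cpg_cutoff: int, max_gap_bp: int,
                  state: str) -> list[RegulatoryRegion]:
    regions: list[RegulatoryRegion] = []
    n = len(pos)
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and mask[j + 1]
            and pos[j + 1] - pos[j] <= max_gap_bp
        ):
            j += 1
        n_cpg = j - i + 1
        if n_cpg >= n_cpg_cutoff:
            regions.append(
                RegulatoryRegion(
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]) + 2,
                    n_cpg=n_cpg,
                    mean_meth=float(np.mean(meth[i : j + 1])),
                    state=state,
                )
            )
        i = j + 1
    return regions


def segment(profile: CombinedProfile, meth_cutoff: float = 0.5,
            n_cpg_cutoff: int = 3, max_gap_bp: int = 500) -> list[RegulatoryRegion]:
    """Hypomethylated regions: maximal runs with meth < meth_cutoff."""
    if n_cpg_cutoff < 1:
        raise ValueError("n_cpg_cutoff must be >= 1")
    out: list[RegulatoryRegion] = []
    for chrom, grp in profile.per_chromosome():
        pos = grp["pos"].to_numpy()
        meth = grp["meth"].to_numpy()
        out.extend(_segment_mask(pos, meth, meth < meth_cutoff, chrom,
                                 n_cpg_cutoff, max_gap_bp, "hypo"))
    return out


def segment_himr(profile: CombinedProfile, meth_cutoff: float = 0.5,
                 n_cpg_cutoff: int = 3, max_gap_bp: int = 500) -> list[RegulatoryRegion]:
    """Hypermethylated regions: maximal runs with meth >= meth_cutoff."""
    if n_cpg_cutoff < 1:
        raise ValueError("n_cpg_cutoff must be >= 1")
    out: list[RegulatoryRegion] = []
    for chrom, grp in profile.per_chromosome():
        pos = grp["pos"].to_numpy()
        meth = grp["meth"].to_numpy()
        out.extend(_segment_mask(pos, meth, meth >= meth_cutoff, chrom,
                                 n_cpg_cutoff, max_gap_bp, "hyper"))
    return out
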