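"""Genomic region containers shared across the pipeline.

Coordinates are 0-based, half-open throughout: a region ``[start, end)``
covers ``end - start`` base pairs. A region built from a CpG run spans the
first CpG position to the last CpG position + 2 (covering the dinucleotide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class RegulatoryRegion:
    """A contiguous CpG segment with a methylation state.

    state is "hypo" (every member CpG methylation < cutoff) or "hyper"
    (every member CpG methylation >= cutoff).
    """

    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_meth: float
    state: str
    genomic_category: str | None = None
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty region {self.chrom}:{self.start}-{self.end}"
            )
        if self.state not in ("hypo", "hyper"):
            raise ValueError(f"unknown region state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "RegulatoryRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def regions_to_frame(regions: list[RegulatoryRegion]) -> pd.DataFrame:
    """Tabulate regions (chrom, start, end, n_cpg, mean_meth, state, category)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_cpg": [r.n_cpg for r in regions],
            "mean_meth": [r.mean_meth for r in regions],
            "state": [r.state for r in regions],
            "genomic_category": [r.genomic_category for r in regions],
        }
    )


def write_bed(regions: list[RegulatoryRegion], path) -> None:
    """BED6-style output: name=state, score=round(1000*mean_meth)."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            score = int(round(1000 * r.mean_meth))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\t{score}\t.\n")
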