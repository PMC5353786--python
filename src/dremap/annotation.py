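"""Gene annotation and interval-track containers.

Tracks (repeats, CpG islands) are plain interval tables with columns
chrom, start, end in 0-based half-open coordinates. Gene annotation carries
per-gene body coordinates, strand, TSS and exon intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["chrom", "start", "end"]


def merge_intervals(track: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    if not len(track):
        return pd.DataFrame(columns=TRACK_COLUMNS)
    rows = []
    for chrom, grp in track.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def interval_overlap_bp(chrom: str, start: int, end: int,
                        merged: dict[str, tuple[np.ndarray, np.ndarray]]) -> int:
    """Base pairs of [start, end) covered by a merged per-chrom track."""
    if chrom not in merged:
        return 0
    starts, ends = merged[chrom]
    lo = np.searchsorted(ends, start, side="right")
    hi = np.searchsorted(starts, end, side="left")
    if hi <= lo:
        return 0
    s = np.maximum(starts[lo:hi], start)
    e = np.minimum(ends[lo:hi], end)
    return int(np.maximum(e - s, 0).sum())


def track_index(track: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) arrays of a merged track for fast overlap."""
    merged = merge_intervals(track)
    out = {}
    for chrom, grp in merged.groupby("chrom"):
        out[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def read_bed(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    df = df.iloc[:, :3]
    df.columns = TRACK_COLUMNS
    return df


def write_bed_track(track: pd.DataFrame, path) -> None:
    track[TRACK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GeneAnnotation:
    """Gene models: body intervals, strand, TSS, exons, chromosome sizes."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, tss
    exons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", *TRACK_COLUMNS])
    )
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"gene_id", "chrom", "start", "end", "strand", "tss"}
        missing = need - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns {sorted(missing)}")

    @property
    def tss_table(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "tss"]]

    def write_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)
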