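"""Per-sample CpG profiles and the read-weighted class consensus.

RRBS yields, per sample and CpG site, a total read count and a methylated
(bisulfite-unconverted) read count. Samples differ widely in sequencing
depth, so a class-level consensus weights each sample by the reciprocal of
its total aligned read count: at site k,

    R(k)  = sum_i w_i * r_ik  / sum_i w_i,      w_i = 1 / total_i
    MR(k) = sum_i w_i * mr_ik / sum_i w_i,
    meth(k) = MR(k) / R(k),

where the sums run over the samples that retain a measurement at k after
the per-sample coverage filter (sites with fewer than ``min_reads`` aligned
reads are dropped per sample before combining).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["chrom", "pos", "strand", "total_reads", "meth_reads"]


@dataclass
class SampleProfile:
    """One sample's CpG counts plus the weight-defining total read count."""

    sample_id: str
    total_aligned_reads: int
    sites: pd.DataFrame  # columns PROFILE_COLUMNS, sorted by (chrom, pos)

    def __post_init__(self) -> None:
        if self.total_aligned_reads < 0:
            raise ValueError("total_aligned_reads must be >= 0")
        missing = [c for c in PROFILE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"profile missing columns {missing}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class CombinedProfile:
    """Class-level weighted consensus: per site R, MR, meth, n_samples."""

    sites: pd.DataFrame  # columns chrom, pos, R, MR, meth, n_samples

    def per_chromosome(self):
        for chrom, grp in self.sites.groupby("chrom", sort=True):
            yield chrom, grp.sort_values("pos").reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CombinedProfile":
        return cls(pd.read_csv(path, sep="\t"))


def load_cpg_profile(path, total_aligned_reads: int, sample_id: str | None = None) -> SampleProfile:
    """Parse a per-sample CpG TSV (chrom, pos, strand, total_reads, meth_reads).

    Rows with meth_reads > total_reads raise with the offending line number.
    Unsorted input is sorted with a warning. An empty file yields an empty
    profile.
    """
    sample_id = sample_id if sample_id is not None else str(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=PROFILE_COLUMNS,
                         comment="#", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=PROFILE_COLUMNS)
    if len(df):
        bad = df.index[df["meth_reads"] > df["total_reads"]]
        if len(bad):
            line = int(bad[0]) + 1  # 1-based data line
            raise ValueError(
                f"{path}: line {line}: meth_reads exceeds total_reads"
            )
        if (df["total_reads"] < 0).any() or (df["meth_reads"] < 0).any():
            raise ValueError(f"{path}: negative read counts")
        sorted_df = df.sort_values(["chrom", "pos"], kind="mergesort")
        if not sorted_df.index.equals(df.index):
            warnings.warn(f"{path}: input not sorted by (chrom, pos); sorting")
            df = sorted_df.reset_index(drop=True)
    return SampleProfile(sample_id=sample_id, total_aligned_reads=total_aligned_reads,
                         sites=df.reset_index(drop=True))


def filter_low_coverage(profile: SampleProfile, min_reads: int = 5) -> SampleProfile:
    """Drop sites with fewer than ``min_reads`` aligned reads (default 5)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    kept = profile.sites[profile.sites["total_reads"] >= min_reads]
    return SampleProfile(
        sample_id=profile.sample_id,
        total_aligned_reads=profile.total_aligned_reads,
        sites=kept.reset_index(drop=True),
    )


def collapse_strands(profile: SampleProfile) -> SampleProfile:
    """Merge the two strands of each CpG dinucleotide by summing reads.

    The minus-strand C of a CpG sits one base downstream of the plus-strand
    C; merging maps minus-strand sites to pos - 1 and sums counts. Off by
    default in the pipeline: strand measurements are kept distinct.
    """
    sites = profile.sites.copy()
    minus = sites["strand"] == "-"
    sites.loc[minus, "pos"] = sites.loc[minus, "pos"] - 1
    merged = (
        sites.groupby(["chrom", "pos"], sort=True)[["total_reads", "meth_reads"]]
        .sum()
        .reset_index()
    )
    merged["strand"] = "+"
    merged = merged[PROFILE_COLUMNS]
    return SampleProfile(profile.sample_id, profile.total_aligned_reads, merged)


def combine_profiles(profiles: list[SampleProfile]) -> CombinedProfile:
    """Weighted consensus over samples; the normalizer runs per site over
    the samples contributing at that site."""
    if not profiles:
        raise ValueError("need at least one profile")
    for p in profiles:
        if p.total_aligned_reads == 0:
            raise ValueError(
                f"sample {p.sample_id}: total_aligned_reads is 0, weight undefined"
            )
    frames = []
    for p in profiles:
        if not len(p.sites):
            continue
        w = 1.0 / p.total_aligned_reads
        f = p.sites[["chrom", "pos", "total_reads", "meth_reads"]].copy()
        f["w"] = w
        f["wr"] = w * f.pop("total_reads")
        f["wmr"] = w * f.pop("meth_reads")
        frames.append(f)
    if not frames:
        return CombinedProfile(pd.DataFrame(
            columns=["chrom", "pos", "R", "MR", "meth", "n_samples"]))
    stacked = pd.concat(frames, ignore_index=True)
    agg = stacked.groupby(["chrom", "pos"], sort=True).agg(
        wr=("wr", "sum"), wmr=("wmr", "sum"), w=("w", "sum"), n_samples=("w", "size")
    )
    out = pd.DataFrame({
        "R": agg["wr"] / agg["w"],
        "MR": agg["wmr"] / agg["w"],
        "n_samples": agg["n_samples"].astype(int),
    })
    out["meth"] = np.where(out["R"] > 0, out["MR"] / out["R"], 0.0)
    out = out.reset_index()[["chrom", "pos", "R", "MR", "meth", "n_samples"]]
    return CombinedProfile(out)
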