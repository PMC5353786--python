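"""Synthetic study-condition generator with planted ground truth.

Emulates the statistical structure of the study inputs: 32 case (CLL) and
10 control RRBS methylation profiles with binomial sampling noise around
planted hypo/hyper-methylated segments; read-level allele counts with
class-specific frequency shifts at planted SNPs; a phased haplotype panel
with LD blocks linking planted SNPs to catalog tag SNPs; a trait catalog
spanning the agglomeration categories; PWMs with planted consensus sites
and site-destroying/creating substitutions; and a two-class expression
table coupled to the planted regions.

All randomness flows from one integer seed; each generator draws from a
deterministically derived sub-stream, so a fixed configuration reproduces
byte-identical outputs. Ground-truth manifests accompany every fixture.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation
from .consensus import PROFILE_COLUMNS, SampleProfile
from .panel import HaplotypePanel
from .snp import SnpReadCounts
from .tfbs import BASES, Pwm

# sub-stream tags, one per generator
_S_GENOME, _S_METH, _S_SNP, _S_PANEL, _S_CATALOG, _S_PWM, _S_EXPR = range(7)

TRUTH_CLASSES = ("gained", "lost", "shared", "himr")


@dataclass
class PlantedRegion:
    chrom: str
    start: int
    end: int
    truth_class: str
    n_cpg: int = 10
    meth_low: float = 0.05
    meth_high: float = 0.9

    def __post_init__(self) -> None:
        if self.truth_class not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth class {self.truth_class}")
        if self.n_cpg < 3:
            raise ValueError("planted regions need n_cpg >= 3")
        if not (0 <= self.meth_low < 0.5 <= self.meth_high <= 1):
            raise ValueError("need meth_low < 0.5 <= meth_high")

    def cpg_positions(self) -> np.ndarray:
        return np.linspace(self.start, self.end - 2, self.n_cpg).astype(int)


@dataclass
class PlantedSnp:
    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    case_alt_freq: float
    control_alt_freq: float
    ld_tag_id: str | None = None
    ld_r2_target: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("alleles must differ")
        for f in (self.case_alt_freq, self.control_alt_freq, self.ld_r2_target):
            if not 0 <= f <= 1:
                raise ValueError("frequencies must be in [0, 1]")


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 200
    n_cpg: int = 2000          # background CpGs (outside planted regions)
    n_case_samples: int = 32   # study: 32 CLL B-cell samples
    n_control_samples: int = 10  # study: 10 normal CD19+ B-cell samples
    mean_coverage: float = 30.0
    planted_regions: list[PlantedRegion] | None = None
    planted_snps: list[PlantedSnp] | None = None
    n_haplotypes: int = 1000
    n_panel_snps: int = 300
    n_traits: int = 8
    n_pwms: int = 5

    def __post_init__(self) -> None:
        positive = {"n_chromosomes": self.n_chromosomes,
                    "chrom_length_bp": self.chrom_length_bp,
                    "n_case_samples": self.n_case_samples,
                    "n_control_samples": self.n_control_samples,
                    "n_haplotypes": self.n_haplotypes}
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.n_genes, self.n_cpg, self.n_traits, self.n_pwms, self.n_panel_snps) < 0:
            raise ValueError("counts must be nonnegative")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.planted_regions is None:
            self.planted_regions = default_planted_regions(
                self.n_chromosomes, self.chrom_length_bp)
        if self.planted_snps is None:
            self.planted_snps = default_planted_snps(
                self.n_chromosomes, self.chrom_length_bp)
        self._validate_regions()

    def _validate_regions(self) -> None:
        chroms = {f"chr{i+1}" for i in range(self.n_chromosomes)}
        by_chrom: dict[str, list[PlantedRegion]] = {}
        for r in self.planted_regions:
            if r.chrom not in chroms:
                raise ValueError(f"planted region on unknown chromosome {r.chrom}")
            if r.start < 0 or r.end > self.chrom_length_bp:
                raise ValueError(
                    f"planted region {r.chrom}:{r.start}-{r.end} exceeds chromosome length")
            by_chrom.setdefault(r.chrom, []).append(r)
        for group in by_chrom.values():
            group = sorted(group, key=lambda r: r.start)
            for a, b in zip(group, group[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"planted regions overlap: {a.chrom}:{a.start}-{a.end} and "
                        f"{b.chrom}:{b.start}-{b.end}")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


def default_planted_regions(n_chromosomes: int, chrom_length_bp: int,
                            n_per_class: dict[str, int] | None = None,
                            n_cpg: int = 10, pitch: int = 12_000,
                            first_start: int = 20_000) -> list[PlantedRegion]:
    """Regular layout: regions of n_cpg CpGs (~40 bp spacing) laid out
    round-robin across chromosomes, well separated."""
    counts = n_per_class or {"gained": 20, "lost": 20, "shared": 10, "himr": 10}
    regions: list[PlantedRegion] = []
    slot = 0
    span = (n_cpg - 1) * 40 + 2
    per_chrom_slots = max(1, (chrom_length_bp - 2 * first_start) // pitch)
    for cls, n in counts.items():
        for _ in range(n):
            chrom = f"chr{slot % n_chromosomes + 1}"
            local = slot // n_chromosomes
            if local >= per_chrom_slots:
                raise ValueError("chromosome too short for default planted regions")
            start = first_start + local * pitch
            regions.append(PlantedRegion(chrom, start, start + span, cls, n_cpg=n_cpg))
            slot += 1
    return regions


def default_planted_snps(n_chromosomes: int, chrom_length_bp: int) -> list[PlantedSnp]:
    """Associated, null and LD-linked SNPs exercising every downstream rule."""
    snps = []

    # slot layout must mirror default_planted_regions: slot s sits on
    # chr(s % n + 1) at 20_000 + (s // n) * 12_000; slots 0-19 are gained,
    # 20-39 lost
    def slot_pos(slot: int, offset: int) -> tuple[str, int]:
        chrom = f"chr{slot % n_chromosomes + 1}"
        return chrom, 20_000 + (slot // n_chromosomes) * 12_000 + offset

    # strongly associated SNPs inside gained regions (case-enriched alt)
    for i in range(10):
        chrom, pos = slot_pos(i, 301)
        snps.append(PlantedSnp(f"snp_assoc{i}", chrom, pos, "A", "G", 0.8, 0.2))
    # null SNPs (equal frequencies) inside lost regions
    for i in range(10):
        chrom, pos = slot_pos(20 + i, 301)
        snps.append(PlantedSnp(f"snp_null{i}", chrom, pos, "C", "T", 0.5, 0.5))
    # LD partners of catalog tags (tag positions fixed by the catalog layout)
    snps.append(PlantedSnp("snp_ld_near", "chr1", 112_000, "A", "C", 0.7, 0.3,
                           ld_tag_id="rs_tag0", ld_r2_target=0.95))
    snps.append(PlantedSnp("snp_ld_far", "chr1", 700_000 - 1, "G", "T", 0.6, 0.4,
                           ld_tag_id="rs_tag0", ld_r2_target=0.95))
    snps.append(PlantedSnp("snp_ld_null", "chr2", 130_000, "T", "A", 0.5, 0.5,
                           ld_tag_id="rs_tag1", ld_r2_target=0.0))
    return snps


@dataclass
class GenomeFixture:
    config: SyntheticConfig
    sequences: dict[str, str]
    annotation: GeneAnnotation
    repeat_track: pd.DataFrame
    cgi_track: pd.DataFrame
    cpg_table: pd.DataFrame  # chrom, pos, region_idx (-1 = background)
    truth_regions: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.annotation.chrom_lengths


def _random_disjoint_track(rng: np.random.Generator, chroms: dict[str, int],
                           mean_len: int, mean_gap: int) -> pd.DataFrame:
    rows = []
    for chrom, length in chroms.items():
        pos = int(rng.integers(0, mean_gap))
        while pos < length:
            span = max(20, int(rng.exponential(mean_len)))
            end = min(pos + span, length)
            rows.append((chrom, pos, end))
            pos = end + max(50, int(rng.exponential(mean_gap)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate_genome_fixture(config: SyntheticConfig) -> GenomeFixture:
    """Genome sequence, gene annotation, repeat/CGI tracks and CpG layout."""
    rng = config.rng(_S_GENOME)
    chroms = {f"chr{i+1}": config.chrom_length_bp for i in range(config.n_chromosomes)}
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {}
    for chrom, length in chroms.items():
        codes = rng.integers(0, 4, size=length)
        sequences[chrom] = bytes(base_bytes[codes]).decode()

    # genes: random bodies, strand-aware TSS, 2-4 exons each
    gene_rows, exon_rows = [], []
    for g in range(config.n_genes):
        chrom = f"chr{rng.integers(1, config.n_chromosomes + 1)}"
        body = int(rng.integers(5_000, 50_000))
        start = int(rng.integers(0, chroms[chrom] - body))
        end = start + body
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end - 1
        gene_id = f"gene{g:04d}"
        gene_rows.append((gene_id, chrom, start, end, strand, tss))
        n_exons = int(rng.integers(2, 5))
        exon_starts = np.sort(rng.integers(start, end - 200, size=n_exons))
        for es in exon_starts:
            exon_rows.append((gene_id, chrom, int(es), int(min(es + int(rng.integers(80, 300)), end))))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    annotation = GeneAnnotation(genes, exons, dict(chroms))

    repeat_track = _random_disjoint_track(rng, chroms, mean_len=300, mean_gap=1_200)
    # CGIs: around a subset of TSSs plus random islands
    cgi_rows = []
    for _, g in genes.iterrows():
        if rng.random() < 0.4:
            s = max(0, g["tss"] - int(rng.integers(200, 600)))
            cgi_rows.append((g["chrom"], s, min(s + int(rng.integers(400, 1_500)), chroms[g["chrom"]])))
    cgi_random = _random_disjoint_track(rng, chroms, mean_len=600, mean_gap=40_000)
    cgi_track = pd.concat([pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]),
                           cgi_random], ignore_index=True)

    # CpG layout: planted-region CpGs plus background CpGs outside regions
    cpg_rows = []
    for idx, region in enumerate(config.planted_regions):
        for p in region.cpg_positions():
            cpg_rows.append((region.chrom, int(p), idx))
    planted_by_chrom: dict[str, list[PlantedRegion]] = {}
    for r in config.planted_regions:
        planted_by_chrom.setdefault(r.chrom, []).append(r)
    n_bg = config.n_cpg
    placed = 0
    occupied = {(c, p) for c, p, _ in cpg_rows}
    while placed < n_bg:
        chrom = f"chr{rng.integers(1, config.n_chromosomes + 1)}"
        pos = int(rng.integers(0, chroms[chrom] - 2))
        if any(r.start - 500 <= pos < r.end + 500 for r in planted_by_chrom.get(chrom, [])):
            continue
        if (chrom, pos) in occupied:
            continue
        occupied.add((chrom, pos))
        cpg_rows.append((chrom, pos, -1))
        placed += 1
    cpg_table = (pd.DataFrame(cpg_rows, columns=["chrom", "pos", "region_idx"])
                 .sort_values(["chrom", "pos"]).reset_index(drop=True))
    # write CG dinucleotides into the sequence at every CpG site
    seq_arrays = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    for chrom, pos in zip(cpg_table["chrom"], cpg_table["pos"]):
        seq_arrays[chrom][pos : pos + 2] = b"CG"
    sequences = {c: a.decode() for c, a in seq_arrays.items()}

    truth_regions = pd.DataFrame(
        [(i, r.chrom, r.start, r.end, r.truth_class, r.n_cpg, r.meth_low, r.meth_high)
         for i, r in enumerate(config.planted_regions)],
        columns=["region_idx", "chrom", "start", "end", "truth_class",
                 "n_cpg", "meth_low", "meth_high"])
    return GenomeFixture(config, sequences, annotation, repeat_track,
                         cgi_track, cpg_table, truth_regions)


_CLASS_METH = {
    # (case_p_key, control_p_key): which of meth_low/meth_high applies
    "gained": ("meth_low", "meth_high"),
    "lost": ("meth_high", "meth_low"),
    "shared": ("meth_low", "meth_low"),
    "himr": ("meth_high", "meth_high"),
}


def _site_probabilities(config: SyntheticConfig, fixture: GenomeFixture,
                        is_case: bool) -> np.ndarray:
    p = np.full(len(fixture.cpg_table), 0.9)  # background CpGs: highly methylated
    region_idx = fixture.cpg_table["region_idx"].to_numpy()
    for idx, region in enumerate(config.planted_regions):
        case_key, control_key = _CLASS_METH[region.truth_class]
        key = case_key if is_case else control_key
        p[region_idx == idx] = getattr(region, key)
    return p


def generate_methylation_samples(config: SyntheticConfig, fixture: GenomeFixture
                                 ) -> tuple[list[SampleProfile], list[SampleProfile]]:
    """Per-sample CpG count profiles for the case and control classes.

    Coverage per site is Poisson(mean_coverage) truncated at >= 1;
    methylated reads are binomial with the planted class-specific success
    probability. The per-sample total aligned read count (the weight
    denominator) is the summed site coverage scaled by a sample-specific
    library-size factor.
    """
    rng = config.rng(_S_METH)
    chrom = fixture.cpg_table["chrom"].to_numpy()
    pos = fixture.cpg_table["pos"].to_numpy()
    n_sites = len(pos)

    def make_class(n_samples: int, is_case: bool, tag: str) -> list[SampleProfile]:
        p = _site_probabilities(config, fixture, is_case)
        profiles = []
        for s in range(n_samples):
            cov = np.maximum(rng.poisson(config.mean_coverage, size=n_sites), 1)
            meth = rng.binomial(cov, p)
            total = int(cov.sum() * rng.uniform(5, 15))
            sites = pd.DataFrame({
                "chrom": chrom, "pos": pos, "strand": "+",
                "total_reads": cov, "meth_reads": meth,
            })[PROFILE_COLUMNS]
            profiles.append(SampleProfile(f"{tag}{s:02d}", total, sites))
        return profiles

    case = make_class(config.n_case_samples, True, "cll")
    control = make_class(config.n_control_samples, False, "ctl")
    return case, control


def motif_substitution_snps(pwm_manifest: pd.DataFrame) -> list[PlantedSnp]:
    """Planted SNPs at the motif destroy/create substitutions, strongly
    case-enriched so the association stage recovers them and feeds the
    TFBS change statistics."""
    out = []
    subs = pwm_manifest[pwm_manifest["kind"].isin(["destroy", "create"])]
    for i, row in enumerate(subs.itertuples(index=False)):
        out.append(PlantedSnp(f"snp_{row.kind}_{row.motif_id}", row.chrom, row.pos,
                              row.wt_allele, row.mu_allele, 0.85, 0.05))
    return out


def generate_snp_reads(config: SyntheticConfig,
                       extra_snps: list[PlantedSnp] | None = None
                       ) -> tuple[list[SnpReadCounts], pd.DataFrame]:
    """Read-level allele and genotype-state counts per planted SNP.

    Per sample, a diploid genotype is drawn from Hardy-Weinberg proportions
    at the class allele frequency; allele reads are binomial in the alt
    dosage. Two status-control SNPs are appended: a monomorphic SNP under
    10 pooled reads (non-assayed) and one over 10 (non-mutated).
    """
    rng = config.rng(_S_SNP)
    counts_list: list[SnpReadCounts] = []
    truth_rows = []

    def class_counts(freq: float, n_samples: int) -> tuple[dict, dict]:
        alleles = {"ref": 0, "alt": 0}
        genos = {"hom_ref": 0, "het": 0, "hom_alt": 0}
        for _ in range(n_samples):
            dosage = rng.binomial(2, freq)
            genos[("hom_ref", "het", "hom_alt")[dosage]] += 1
            cov = max(1, int(rng.poisson(config.mean_coverage)))
            # read-level draw at the class frequency keeps pooled counts
            # binomial, matching the read-pooling association model
            alt_reads = rng.binomial(cov, freq)
            alleles["alt"] += int(alt_reads)
            alleles["ref"] += int(cov - alt_reads)
        return alleles, genos

    for snp in list(config.planted_snps) + list(extra_snps or []):
        case_a, case_g = class_counts(snp.case_alt_freq, config.n_case_samples)
        ctrl_a, ctrl_g = class_counts(snp.control_alt_freq, config.n_control_samples)
        counts_list.append(SnpReadCounts(
            snp.snp_id, snp.chrom, snp.pos,
            {snp.ref_allele: case_a["ref"], snp.alt_allele: case_a["alt"]},
            {snp.ref_allele: ctrl_a["ref"], snp.alt_allele: ctrl_a["alt"]},
            dict(case_g), dict(ctrl_g)))
        truth_rows.append((snp.snp_id, snp.chrom, snp.pos, snp.case_alt_freq,
                           snp.control_alt_freq, snp.alt_allele,
                           snp.case_alt_freq != snp.control_alt_freq))
    # status-control SNPs: monomorphic, below/above the 10-read rule
    counts_list.append(SnpReadCounts("snp_mono_low", "chr1", 999_001,
                                     {"A": 5}, {"A": 3}))
    counts_list.append(SnpReadCounts("snp_mono_high", "chr1", 999_101,
                                     {"C": 15}, {"C": 10}))
    truth_rows.append(("snp_mono_low", "chr1", 999_001, 0.0, 0.0, None, False))
    truth_rows.append(("snp_mono_high", "chr1", 999_101, 0.0, 0.0, None, False))
    truth = pd.DataFrame(truth_rows, columns=[
        "snp_id", "chrom", "pos", "case_alt_freq", "control_alt_freq",
        "alt_allele", "expect_associated"])
    return counts_list, truth


def generate_gwas_catalog(config: SyntheticConfig) -> pd.DataFrame:
    """Trait-SNP-risk-allele table spanning all agglomeration categories.

    Trait names cycle through the CLL / lymphoma / cancer / irrelevant
    keyword families; some traits carry fewer than five SNPs (flagged
    small, mirroring the long tail of the real catalog).
    """
    rng = config.rng(_S_CATALOG)
    trait_names = ["chronic lymphocytic leukemia", "Hodgkin's lymphoma",
                   "breast cancer", "height", "non-Hodgkin lymphoma",
                   "colorectal cancer", "body mass index", "type 2 diabetes"]
    names = [trait_names[i % len(trait_names)] + ("" if i < len(trait_names) else f" study {i}")
             for i in range(config.n_traits)]
    gained = [r for r in config.planted_regions if r.truth_class == "gained"]
    rows = []
    snp_counter = 0
    for t, trait in enumerate(names):
        n_snps = 3 if t % 4 == 3 else int(rng.integers(6, 15))  # some small traits
        cll_trait = t == 0
        for j in range(n_snps):
            if snp_counter == 0:
                snp_id, chrom, pos = "rs_tag0", "chr1", 100_000
            elif snp_counter == 1:
                snp_id, chrom, pos = "rs_tag1", "chr2", 120_000
            elif cll_trait and gained:
                # CLL-trait SNPs concentrate inside gained elements,
                # planting the enrichment the permutation test measures
                host = gained[j % len(gained)]
                snp_id, chrom, pos = f"rs{snp_counter:05d}", host.chrom, host.start + 311
            else:
                snp_id = f"rs{snp_counter:05d}"
                chrom = f"chr{rng.integers(1, config.n_chromosomes + 1)}"
                pos = int(rng.integers(0, config.chrom_length_bp))
            risk = BASES[rng.integers(0, 4)]
            rows.append((snp_id, chrom, pos, trait, risk))
            snp_counter += 1
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "trait", "risk_allele"])
    sizes = df.groupby("trait")["snp_id"].transform("size")
    df["small_trait"] = sizes < 5
    return df


def generate_haplotype_panel(config: SyntheticConfig, catalog: pd.DataFrame
                             ) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Phased panel over catalog tags, planted LD partners and filler SNPs.

    An LD partner column is built by copying its tag column and replacing
    each entry with an independent draw with probability 1 - sqrt(r2);
    the expected allelic correlation is then sqrt(r2), hitting the target
    r^2. Unattainable targets fall back to best effort with a warning.
    """
    rng = config.rng(_S_PANEL)
    n_hap = config.n_haplotypes
    meta_rows, hap_rows = [], []
    col_of: dict[str, int] = {}

    def add_snp(snp_id, chrom, pos, ref, alt, column) -> None:
        col_of[snp_id] = len(meta_rows)
        meta_rows.append((snp_id, chrom, pos, ref, alt))
        hap_rows.append(column.astype(np.int8))

    for row in catalog.drop_duplicates("snp_id").itertuples(index=False):
        freq = rng.uniform(0.2, 0.8)
        ref = "A" if row.risk_allele != "A" else "G"
        add_snp(row.snp_id, row.chrom, row.pos, ref, row.risk_allele,
                (rng.random(n_hap) < freq).astype(np.int8))
    ld_truth_rows = []
    for snp in config.planted_snps:
        if snp.snp_id in col_of:
            continue
        if snp.ld_tag_id and snp.ld_tag_id in col_of:
            tag_col = hap_rows[col_of[snp.ld_tag_id]]
            keep = np.sqrt(snp.ld_r2_target)
            freq = tag_col.mean()
            if freq in (0.0, 1.0) and snp.ld_r2_target > 0:
                warnings.warn(f"{snp.snp_id}: target r2 unattainable with monomorphic tag")
            replace = rng.random(n_hap) >= keep
            fresh = (rng.random(n_hap) < freq).astype(np.int8)
            column = np.where(replace, fresh, tag_col)
            ld_truth_rows.append((snp.snp_id, snp.ld_tag_id, snp.ld_r2_target,
                                  abs(snp.pos - int(catalog.loc[
                                      catalog["snp_id"] == snp.ld_tag_id, "pos"].iloc[0]))))
        else:
            column = (rng.random(n_hap) < snp.case_alt_freq).astype(np.int8)
        add_snp(snp.snp_id, snp.chrom, snp.pos, snp.ref_allele, snp.alt_allele, column)
    # filler SNPs: two inside every planted region (so every region class
    # carries panel SNPs, the density denominator) plus genome-wide scatter
    filler = 0
    for region in config.planted_regions:
        for offset in (157, 251):
            freq = rng.uniform(0.05, 0.95)
            ref, alt = rng.choice(list(BASES), size=2, replace=False)
            add_snp(f"pan{filler:05d}", region.chrom, region.start + offset,
                    ref, alt, (rng.random(n_hap) < freq).astype(np.int8))
            filler += 1
    for i in range(config.n_panel_snps):
        chrom = f"chr{rng.integers(1, config.n_chromosomes + 1)}"
        pos = int(rng.integers(0, config.chrom_length_bp))
        freq = rng.uniform(0.05, 0.95)
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        add_snp(f"pan{filler + i:05d}", chrom, pos, ref, alt,
                (rng.random(n_hap) < freq).astype(np.int8))
    snps = pd.DataFrame(meta_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    panel = HaplotypePanel(snps, np.vstack(hap_rows))
    ld_truth = pd.DataFrame(ld_truth_rows,
                            columns=["snp_id", "tag_snp", "r2_target", "distance"])
    return panel, ld_truth


def generate_pwm_set(config: SyntheticConfig, fixture: GenomeFixture
                     ) -> tuple[list[Pwm], pd.DataFrame]:
    """High-information PWMs with consensus sites planted into selected
    planted regions, plus substitutions that destroy or create a site.

    Mutates ``fixture.sequences`` to carry the planted sites. The manifest
    lists planted sites (kind="site") and allele substitutions
    (kind="destroy"/"create") with WT/MU alleles.
    """
    rng = config.rng(_S_PWM)
    pwms: list[Pwm] = []
    for m in range(config.n_pwms):
        # moderate widths: one substitution in a strong site of this width
        # moves its tail probability above the default 1e-4 scan threshold,
        # so planted destroy/create substitutions genuinely flip hits
        width = int(rng.integers(7, 9))
        consensus = rng.integers(0, 4, size=width)
        probs = np.full((width, 4), 0.1 / 3)
        probs[np.arange(width), consensus] = 0.9
        pwms.append(Pwm(f"motif{m:02d}", probs))

    seq_arrays = {c: bytearray(s, "ascii") for c, s in fixture.sequences.items()}
    gained_hosts = [r for r in config.planted_regions if r.truth_class == "gained"]
    lost_hosts = [r for r in config.planted_regions if r.truth_class == "lost"]
    if not gained_hosts or not lost_hosts:
        raise ValueError("PWM planting needs gained and lost planted regions")
    manifest_rows = []
    for m, pwm in enumerate(pwms):
        cons = pwm.consensus
        col = pwm.width // 2
        wt = cons[col]
        mu = BASES[int(pwm.probs[col].argmin())]
        # destroyable site in a lost region (plus its destroy substitution)
        host = lost_hosts[m % len(lost_hosts)]
        start = host.start + 5
        seq_arrays[host.chrom][start : start + len(cons)] = cons.encode()
        manifest_rows.append(("site", pwm.motif_id, host.chrom, start,
                              None, None, host.truth_class))
        manifest_rows.append(("destroy", pwm.motif_id, host.chrom, start + col,
                              wt, mu, host.truth_class))
        # intact sites in gained regions (TFBS-density signal)
        for k in range(2):
            host = gained_hosts[(2 * m + k) % len(gained_hosts)]
            start = host.start + 50 + 40 * k
            seq_arrays[host.chrom][start : start + len(cons)] = cons.encode()
            manifest_rows.append(("site", pwm.motif_id, host.chrom, start,
                                  None, None, host.truth_class))
        # create substitution in a gained region: a one-mismatch site whose
        # MU allele restores the consensus
        host = gained_hosts[(2 * m) % len(gained_hosts)]
        start = host.start + 180 + 13 * (m % 10)
        site = bytearray(cons.encode())
        site[col] = ord(mu)
        seq_arrays[host.chrom][start : start + len(site)] = site
        manifest_rows.append(("create", pwm.motif_id, host.chrom, start + col,
                              mu, wt, host.truth_class))
    fixture.sequences = {c: a.decode() for c, a in seq_arrays.items()}
    manifest = pd.DataFrame(manifest_rows, columns=[
        "kind", "motif_id", "chrom", "pos", "wt_allele", "mu_allele", "region_class"])
    return pwms, manifest


def generate_expression_table(config: SyntheticConfig, fixture: GenomeFixture
                              ) -> pd.DataFrame:
    """Two-class per-gene expression coupled to the planted regions.

    Genes whose TSS is the nearest to a planted gained region are
    up-regulated in the case class (fold 4), near lost regions
    down-regulated (fold 1/4); a small fraction fall below the 0.1
    reliability floor in both classes.
    """
    rng = config.rng(_S_EXPR)
    genes = fixture.annotation.genes
    rows = []
    region_tss: dict[str, str] = {}
    for r in config.planted_regions:
        if r.truth_class not in ("gained", "lost"):
            continue
        on_chrom = genes[genes["chrom"] == r.chrom]
        if not len(on_chrom):
            continue
        center = (r.start + r.end) // 2
        nearest = on_chrom.iloc[(on_chrom["tss"] - center).abs().argmin()]
        region_tss.setdefault(nearest["gene_id"], r.truth_class)
    for _, g in genes.iterrows():
        base = float(rng.lognormal(0.5, 0.8))
        cls = region_tss.get(g["gene_id"])
        if rng.random() < 0.05:
            case = control = 0.05  # below the reliability floor
        elif cls == "gained":
            control, case = base, base * 4
        elif cls == "lost":
            control, case = base, base / 4
        else:
            control = base
            case = base * float(rng.lognormal(0, 0.15))
        rows.append((g["gene_id"], case, control, cls or "none"))
    return pd.DataFrame(rows, columns=["gene_id", "case_mean", "control_mean",
                                       "linked_truth_class"])


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, with ground truth."""

    config: SyntheticConfig
    fixture: GenomeFixture
    case_profiles: list[SampleProfile]
    control_profiles: list[SampleProfile]
    snp_counts: list[SnpReadCounts]
    snp_truth: pd.DataFrame
    catalog: pd.DataFrame
    panel: HaplotypePanel
    ld_truth: pd.DataFrame
    pwms: list[Pwm]
    pwm_manifest: pd.DataFrame
    expression: pd.DataFrame


def generate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Run every generator in dependency order under one seed."""
    fixture = generate_genome_fixture(config)
    catalog = generate_gwas_catalog(config)
    pwms, pwm_manifest = generate_pwm_set(config, fixture)
    case, control = generate_methylation_samples(config, fixture)
    snp_counts, snp_truth = generate_snp_reads(
        config, extra_snps=motif_substitution_snps(pwm_manifest))
    panel, ld_truth = generate_haplotype_panel(config, catalog)
    expression = generate_expression_table(config, fixture)
    return SyntheticDataset(config, fixture, case, control, snp_counts,
                            snp_truth, catalog, panel, ld_truth, pwms,
                            pwm_manifest, expression)


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Serialize every fixture in its standard text format."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .annotation import write_bed_track
    from .tfbs import write_meme

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in ds.fixture.sequences.items()]
    SeqIO.write(records, out / "genome.fa", "fasta")
    ds.fixture.annotation.write_tsv(out / "genes.tsv")
    ds.fixture.annotation.exons.to_csv(out / "exons.tsv", sep="\t", index=False)
    write_bed_track(ds.fixture.repeat_track, out / "repeats.bed")
    write_bed_track(ds.fixture.cgi_track, out / "cgi.bed")
    ds.fixture.truth_regions.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    totals = {}
    for p in ds.case_profiles + ds.control_profiles:
        p.sites.to_csv(out / f"profile_{p.sample_id}.tsv", sep="\t",
                       index=False, header=False)
        totals[p.sample_id] = p.total_aligned_reads
    (out / "totals.json").write_text(json.dumps(totals, indent=0, sort_keys=True))
    snp_rows = [
        {"snp_id": c.snp_id, "chrom": c.chrom, "pos": c.pos,
         "case_allele_counts": c.case_allele_counts,
         "control_allele_counts": c.control_allele_counts,
         "case_genotype_counts": c.case_genotype_counts,
         "control_genotype_counts": c.control_genotype_counts}
        for c in ds.snp_counts]
    (out / "snp_counts.json").write_text(json.dumps(snp_rows, indent=0))
    ds.snp_truth.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
    ds.catalog.to_csv(out / "gwas_catalog.tsv", sep="\t", index=False)
    ds.panel.write_vcf(out / "panel.vcf")
    ds.ld_truth.to_csv(out / "truth_ld.tsv", sep="\t", index=False)
    write_meme(ds.pwms, out / "motifs.meme")
    ds.pwm_manifest.to_csv(out / "truth_motifs.tsv", sep="\t", index=False)
    ds.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
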