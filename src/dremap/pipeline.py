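"""End-to-end pipeline driver.

Runs the stages in dependency order on a synthetic dataset (or one loaded
from disk by the caller): class consensus → segmentation → region
classification → {gene linkage, spatial statistics, GWAS enrichment} and
{SNP association → haplotype association, TFBS change statistics}. Every
stage writes its table under the run directory; a manifest records
parameters, seeds and SHA-256 digests of all outputs, so identical
configurations produce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, consensus, genes, gwas, haplotype, segmentation, snp, spatial, tfbs
from .regions import regions_to_frame, write_bed
from .synthetic import SyntheticConfig, SyntheticDataset, generate_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds, at their study defaults."""

    seed: int = 0
    min_reads: int = 5            # per-sample CpG coverage filter
    meth_cutoff: float = 0.5
    n_cpg_cutoff: int = 3
    max_gap_bp: int = 500
    min_overlap_bp: int = 1
    promoter_window: tuple[int, int] = (1000, 500)
    snp_min_reads: int = 10
    alpha: float = 0.05
    r2_min: float = 0.8
    ld_max_dist: int = 500_000
    n_perm: int = 1000
    n_background: int = 30        # background positions per associated SNP
    n_controls: int = 10          # matched control sequences per region
    cluster_gap: int = 10_000
    min_expr: float = 0.1
    top_percent: float = 10.0
    gc_tol: float = 0.05
    repeat_tol: float = 0.05
    p_threshold: float = 1e-4     # PWM scan hit threshold
    stages: tuple[str, ...] = ("classify", "genes", "spatial", "gwas", "snp",
                               "haplotype", "tfbs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "promoter_window" in data:
            data["promoter_window"] = tuple(data["promoter_window"])
        return cls(**data)


_STAGE_DEPS = {
    "classify": (),
    "genes": ("classify",),
    "spatial": ("classify",),
    "gwas": ("classify",),
    "snp": (),
    "haplotype": ("snp",),
    "tfbs": ("classify", "snp"),
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunResult:
    out_dir: Path
    classmap: classify.ReClassMap | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _region_sequence(dataset: SyntheticDataset, region) -> str:
    return dataset.fixture.sequences[region.chrom][region.start:region.end]


def run(config: RunConfig, out_dir, dataset: SyntheticDataset | None = None,
        synthetic_config: SyntheticConfig | None = None) -> RunResult:
    """Execute the enabled stages and write outputs plus a digest manifest."""
    for stage in config.stages:
        for dep in _STAGE_DEPS[stage]:
            if dep not in config.stages:
                raise ValueError(f"stage '{stage}' requires disabled stage '{dep}'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        syn = synthetic_config or SyntheticConfig(seed=config.seed)
        dataset = generate_all(syn)
    result = RunResult(out_dir=out)
    stage_log: list[str] = []

    # consensus + segmentation always run (everything depends on them)
    def class_profile(profiles):
        filtered = [consensus.filter_low_coverage(p, config.min_reads) for p in profiles]
        return consensus.combine_profiles(filtered)

    case_prof = class_profile(dataset.case_profiles)
    ctrl_prof = class_profile(dataset.control_profiles)
    case_prof.write_tsv(out / "combined_case.tsv")
    ctrl_prof.write_tsv(out / "combined_control.tsv")
    seg = dict(meth_cutoff=config.meth_cutoff, n_cpg_cutoff=config.n_cpg_cutoff,
               max_gap_bp=config.max_gap_bp)
    case_hypo = segmentation.segment(case_prof, **seg)
    ctrl_hypo = segmentation.segment(ctrl_prof, **seg)
    case_hyper = segmentation.segment_himr(case_prof, **seg)
    ctrl_hyper = segmentation.segment_himr(ctrl_prof, **seg)
    stage_log.append("consensus+segmentation")

    classmap = None
    if "classify" in config.stages:
        classmap = classify.classify_regions(
            case_hypo, ctrl_hypo, case_hyper, ctrl_hyper,
            min_overlap_bp=config.min_overlap_bp, n_cpg_cutoff=config.n_cpg_cutoff,
            case_profile=case_prof, control_profile=ctrl_prof)
        classify.annotate_classmap(classmap, dataset.fixture.annotation,
                                   config.promoter_window)
        for name, group in classmap.classes().items():
            write_bed(group, out / f"{name}.bed")
        summary = classify.classmap_summary(classmap, dataset.fixture.repeat_track,
                                            dataset.fixture.cgi_track)
        summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
        result.classmap = classmap
        result.tables["class_summary"] = summary
        stage_log.append("classify")

    if "genes" in config.stages:
        tss = dataset.fixture.annotation.tss_table
        fc = genes.compute_fold_change(dataset.expression, config.min_expr)
        measured = set(fc.loc[~fc["excluded"], "gene_id"])
        gained_assign = genes.assign_regions(classmap.gained, tss)
        lost_assign = genes.assign_regions(classmap.lost, tss)
        sre_assign = genes.assign_regions(classmap.shared, tss)
        enr_rows = []
        for dre_class, assign in (("gained", gained_assign), ("lost", lost_assign)):
            for direction in ("up", "down"):
                for pct in (1, 2, 5, 10):
                    gene_set = genes.rank_de_genes(fc, pct, direction)
                    enr = genes.dre_gene_enrichment(assign, sre_assign, gene_set, measured)
                    enr_rows.append({"dre_class": dre_class, "rank_direction": direction,
                                     "top_percent": pct, **asdict(enr)})
        enr_table = pd.DataFrame(enr_rows)
        enr_table.to_csv(out / "gene_enrichment.tsv", sep="\t", index=False)
        multi = genes.find_multi_lost_genes(lost_assign, gained_assign)
        multi.to_csv(out / "multi_lost_genes.tsv", sep="\t", index=False)
        fc.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
        result.tables["gene_enrichment"] = enr_table
        result.tables["multi_lost_genes"] = multi
        stage_log.append("genes")

    if "spatial" in config.stages:
        regions, labels = classmap.labeled_regions()
        dist = spatial.shuffle_label_background(
            regions, labels, "gained", n_perm=min(config.n_perm, 200),
            seed=config.seed + 1)
        clusters = spatial.cluster_lost_dres(classmap.lost, config.cluster_gap)
        spatial_summary = pd.DataFrame([{
            "observed_median": float(np.median(dist.observed)) if len(dist.observed) else np.nan,
            "background_median": float(np.median(dist.background_pooled)) if len(dist.background_pooled) else np.nan,
            "rank_sum_p": dist.p_value,
            "n_perm": dist.n_permutations,
            "n_clustered_lost": len(clusters.selected),
            "n_clusters": len(clusters.clusters),
        }])
        spatial_summary.to_csv(out / "spatial_summary.tsv", sep="\t", index=False)
        result.tables["spatial_summary"] = spatial_summary
        stage_log.append("spatial")

    if "gwas" in config.stages:
        panels = {"panel": dataset.panel}
        trait_sets = gwas.expand_ld(dataset.catalog, panels,
                                    r2_min=config.r2_min, max_dist=config.ld_max_dist)
        categories = gwas.agglomerate_traits(dataset.catalog, trait_sets=trait_sets)
        regions, labels = classmap.labeled_regions()
        rows = []
        for cat, tset in categories.items():
            test = gwas.permutation_enrichment(
                regions, labels, dataset.panel.snps, tset.snps,
                target_label="gained", n_perm=min(config.n_perm, 200),
                seed=config.seed + 2)
            rows.append({"category": cat, "n_snps": len(tset.snps),
                         "observed": test.observed_count,
                         "density_per_1000": test.density_per_1000,
                         "p_value": test.p_value})
        gwas_table = pd.DataFrame(rows)
        gwas_table.to_csv(out / "gwas_enrichment.tsv", sep="\t", index=False)
        result.tables["gwas_enrichment"] = gwas_table
        stage_log.append("gwas")

    assoc = None
    if "snp" in config.stages:
        assoc = snp.association_table(dataset.snp_counts, alpha=config.alpha,
                                      min_reads=config.snp_min_reads)
        assoc.to_csv(out / "snp_association.tsv", sep="\t", index=False)
        result.tables["snp_association"] = assoc
        stage_log.append("snp")

    if "haplotype" in config.stages:
        rows = []
        hits = assoc[assoc["is_cll_associated"]]
        tag_rows = dataset.catalog.drop_duplicates("snp_id")
        for _, a in hits.iterrows():
            if a["snp_id"] not in dataset.panel:
                continue
            for _, tag in tag_rows.iterrows():
                if tag["snp_id"] not in dataset.panel:
                    continue
                if tag["chrom"] != a["chrom"] or \
                        abs(int(tag["pos"]) - int(a["pos"])) >= config.ld_max_dist:
                    continue
                r2 = gwas.compute_r2(dataset.panel, a["snp_id"], tag["snp_id"])
                if not (r2 > config.r2_min):
                    continue
                ref, alt = dataset.panel.alleles(a["snp_id"])
                cll_allele = a["cll_allele"] if a["cll_allele"] in (ref, alt) else alt
                table = haplotype.build_contingency(
                    dataset.panel, a["snp_id"], cll_allele,
                    tag["snp_id"], tag["risk_allele"])
                rows.append({
                    "snp": a["snp_id"], "tag": tag["snp_id"], "r2": r2,
                    "D11": table.D11, "D12": table.D12,
                    "D21": table.D21, "D22": table.D22,
                    "odds_ratio": haplotype.odds_ratio(table),
                    "fisher_p": haplotype.fisher_exact_p(table)})
        hap_table = pd.DataFrame(rows)
        hap_table.to_csv(out / "haplotype_association.tsv", sep="\t", index=False)
        result.tables["haplotype_association"] = hap_table
        stage_log.append("haplotype")

    if "tfbs" in config.stages:
        # associated SNPs embedded in their host dREs, split by class:
        # loss statistics for lost-dRE SNPs, gain statistics for gained-dRE
        contexts: dict[str, list[tfbs.SnpContext]] = {"gained": [], "lost": []}
        hosts = [("gained", r) for r in classmap.gained] + \
                [("lost", r) for r in classmap.lost]
        for _, a in assoc[assoc["is_cll_associated"]].iterrows():
            hit = next(((cls, r) for cls, r in hosts
                        if r.chrom == a["chrom"] and r.start <= a["pos"] < r.end), None)
            if hit is None:
                continue
            cls, host = hit
            seq = _region_sequence(dataset, host)
            offset = a["pos"] - host.start
            wt = seq[offset]
            mu = a["cll_allele"] if a["cll_allele"] != wt else a["wt_allele"]
            if mu is None or mu == wt:
                continue
            contexts[cls].append(tfbs.SnpContext(a["snp_id"], seq, offset, wt, mu))
        stats_rows = []
        for direction, cls in (("lost", "lost"), ("gained", "gained")):
            backgrounds = []
            for i, ctx in enumerate(contexts[cls]):
                backgrounds.extend(tfbs.sample_background_positions(
                    ctx, n=config.n_background, seed=config.seed + 100 + i))
            for st in tfbs.motif_change_stats(contexts[cls], dataset.pwms, direction,
                                              backgrounds, config.p_threshold):
                stats_rows.append(asdict(st))
        tfbs_table = pd.DataFrame(stats_rows)
        tfbs_table.to_csv(out / "tfbs_change.tsv", sep="\t", index=False)
        result.tables["tfbs_change"] = tfbs_table
        stage_log.append("tfbs")

    digests = {p.name: _digest(p) for p in sorted(out.iterdir()) if p.is_file()
               and p.name != "manifest.json"}
    manifest = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": stage_log,
        "digests": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str,
                                                  sort_keys=True))
    result.manifest = manifest
    return result
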