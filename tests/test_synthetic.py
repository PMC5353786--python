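"""Synthetic study-condition generator: determinism, bounds, planted truth."""

import numpy as np
import pandas as pd
import pytest

from dremap.gwas import compute_r2
from dremap.synthetic import (PlantedRegion, PlantedSnp, SyntheticConfig,
                              generate_all, generate_genome_fixture,
                              generate_gwas_catalog, generate_haplotype_panel,
                              generate_methylation_samples, generate_pwm_set,
                              generate_snp_reads, generate_expression_table,
                              write_dataset)
from dremap.tfbs import scan_sequence


def small_config(**kw):
    defaults = dict(seed=5, n_cpg=400, n_genes=60, n_haplotypes=400,
                    n_panel_snps=50)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            small_config(mean_coverage=0)

    def test_region_overflow_rejected(self):
        with pytest.raises(ValueError, match="chromosome length"):
            SyntheticConfig(seed=0, chrom_length_bp=10_000, planted_regions=[
                PlantedRegion("chr1", 9_000, 11_000, "gained")])

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            small_config(planted_regions=[
                PlantedRegion("chr1", 1000, 2000, "gained"),
                PlantedRegion("chr1", 1500, 2500, "lost")])

    def test_planted_region_invariants(self):
        with pytest.raises(ValueError):
            PlantedRegion("chr1", 0, 100, "gained", n_cpg=2)
        with pytest.raises(ValueError):
            PlantedRegion("chr1", 0, 100, "gained", meth_low=0.7)
        with pytest.raises(ValueError):
            PlantedSnp("s", "chr1", 0, "A", "A", 0.5, 0.5)


class TestGenomeFixture:
    def test_genes_within_bounds(self):
        cfg = small_config(n_genes=10, n_chromosomes=1)
        fx = generate_genome_fixture(cfg)
        assert len(fx.annotation.genes) == 10
        assert (fx.annotation.genes["tss"] >= 0).all()
        assert (fx.annotation.genes["tss"] < cfg.chrom_length_bp).all()

    def test_zero_genes_empty_annotation(self):
        fx = generate_genome_fixture(small_config(n_genes=0))
        assert len(fx.annotation.genes) == 0

    def test_tracks_disjoint_within_bounds(self):
        fx = generate_genome_fixture(small_config())
        for track in (fx.repeat_track,):
            for chrom, grp in track.groupby("chrom"):
                grp = grp.sort_values("start")
                assert (grp["start"] >= 0).all()
                assert (grp["end"] <= fx.chrom_lengths[chrom]).all()
                assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            write_dataset(generate_all(small_config()), tmp_path / sub)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name


class TestMethylationSamples:
    def test_class_specific_region_methylation(self):
        cfg = small_config()
        fx = generate_genome_fixture(cfg)
        case, control = generate_methylation_samples(cfg, fx)
        assert len(case) == 32 and len(control) == 10
        truth = fx.truth_regions.set_index("region_idx")
        for profiles, is_case in ((case, True), (control, False)):
            merged = pd.concat([p.sites for p in profiles])
            merged = merged.merge(fx.cpg_table, on=["chrom", "pos"])
            for idx, row in truth.iterrows():
                sub = merged[merged["region_idx"] == idx]
                frac = sub["meth_reads"].sum() / sub["total_reads"].sum()
                low_case = row["truth_class"] in ("gained", "shared")
                low = low_case if is_case else row["truth_class"] in ("lost", "shared")
                expected = row["meth_low"] if low else row["meth_high"]
                assert frac == pytest.approx(expected, abs=0.05)

    def test_background_mean_methylation_concentrates(self):
        cfg = small_config(n_cpg=1000)
        fx = generate_genome_fixture(cfg)
        case, _ = generate_methylation_samples(cfg, fx)
        merged = pd.concat([p.sites for p in case]).merge(
            fx.cpg_table, on=["chrom", "pos"])
        bg = merged[merged["region_idx"] == -1]
        mean = bg["meth_reads"].sum() / bg["total_reads"].sum()
        assert 0.88 <= mean <= 0.92


class TestSnpReads:
    def test_status_control_snps_present(self):
        counts, truth = generate_snp_reads(small_config())
        by_id = {c.snp_id: c for c in counts}
        low = by_id["snp_mono_low"]
        assert low.total_reads < 10 and len(low.observed_alleles()) == 1
        high = by_id["snp_mono_high"]
        assert high.total_reads >= 10 and len(high.observed_alleles()) == 1

    def test_counts_track_planted_frequencies(self):
        counts, truth = generate_snp_reads(small_config())
        by_id = {c.snp_id: c for c in counts}
        for _, row in truth.iterrows():
            if row["alt_allele"] is None or not row["expect_associated"]:
                continue
            c = by_id[row["snp_id"]]
            case_total = sum(c.case_allele_counts.values())
            case_alt = c.case_allele_counts.get(row["alt_allele"], 0)
            assert case_alt / case_total == pytest.approx(row["case_alt_freq"], abs=0.1)

    def test_fixed_seed_identical_tables(self):
        a, _ = generate_snp_reads(small_config())
        b, _ = generate_snp_reads(small_config())
        assert [(c.snp_id, c.case_allele_counts) for c in a] == \
               [(c.snp_id, c.case_allele_counts) for c in b]


class TestHaplotypePanel:
    def test_planted_r2_within_tolerance(self):
        cfg = small_config(n_haplotypes=2000)
        catalog = generate_gwas_catalog(cfg)
        panel, ld_truth = generate_haplotype_panel(cfg, catalog)
        for _, row in ld_truth.iterrows():
            r2 = compute_r2(panel, row["snp_id"], row["tag_snp"])
            assert abs(r2 - row["r2_target"]) <= 0.1

    def test_perfect_ld_identical_columns(self):
        cfg = small_config(planted_snps=[
            PlantedSnp("dup", "chr1", 112_000, "A", "C", 0.5, 0.5,
                       ld_tag_id="rs_tag0", ld_r2_target=1.0)])
        catalog = generate_gwas_catalog(cfg)
        panel, _ = generate_haplotype_panel(cfg, catalog)
        assert np.array_equal(panel.column("dup"), panel.column("rs_tag0"))

    def test_zero_target_independent(self):
        cfg = small_config(n_haplotypes=4000, planted_snps=[
            PlantedSnp("ind", "chr2", 130_000, "T", "A", 0.5, 0.5,
                       ld_tag_id="rs_tag1", ld_r2_target=0.0)])
        catalog = generate_gwas_catalog(cfg)
        panel, _ = generate_haplotype_panel(cfg, catalog)
        assert compute_r2(panel, "ind", "rs_tag1") < 0.05


class TestCatalogAndPwms:
    def test_four_categories_recoverable(self):
        catalog = generate_gwas_catalog(small_config(n_traits=4))
        from dremap.gwas import agglomerate_traits
        cats = agglomerate_traits(catalog)
        assert all(len(cats[c].snps) > 0
                   for c in ("CLL", "lymphoma", "cancer", "irrelevant"))

    def test_small_traits_flagged(self):
        catalog = generate_gwas_catalog(small_config())
        sizes = catalog.groupby("trait").size()
        flagged = catalog[catalog["small_trait"]]["trait"].unique()
        assert all(sizes[t] < 5 for t in flagged)
        assert len(flagged) > 0

    def test_pwm_columns_stochastic(self):
        cfg = small_config()
        fx = generate_genome_fixture(cfg)
        pwms, _ = generate_pwm_set(cfg, fx)
        for pwm in pwms:
            assert np.allclose(pwm.probs.sum(axis=1), 1, atol=1e-9)
            assert 6 <= pwm.width <= 15

    def test_planted_site_detected_by_scanner(self):
        cfg = small_config()
        fx = generate_genome_fixture(cfg)
        pwms, manifest = generate_pwm_set(cfg, fx)
        by_id = {p.motif_id: p for p in pwms}
        sites = manifest[manifest["kind"] == "site"]
        for _, row in sites.iterrows():
            pwm = by_id[row["motif_id"]]
            seq = fx.sequences[row["chrom"]][row["pos"]: row["pos"] + pwm.width]
            hits = scan_sequence(pwm, seq)
            assert any(h.offset == 0 and h.strand == "+" for h in hits), row["motif_id"]

    def test_destroy_snp_flips_hit(self):
        cfg = small_config()
        fx = generate_genome_fixture(cfg)
        pwms, manifest = generate_pwm_set(cfg, fx)
        by_id = {p.motif_id: p for p in pwms}
        for _, row in manifest[manifest["kind"] == "destroy"].iterrows():
            pwm = by_id[row["motif_id"]]
            w = pwm.width
            lo = row["pos"] - (w - 1)
            wt_win = fx.sequences[row["chrom"]][lo : row["pos"] + w]
            assert wt_win[w - 1] == row["wt_allele"]
            mu_win = wt_win[: w - 1] + row["mu_allele"] + wt_win[w:]
            assert len(scan_sequence(pwm, wt_win)) > 0
            assert len(scan_sequence(pwm, mu_win)) == 0


class TestExpression:
    def test_gained_adjacent_genes_upregulated(self):
        cfg = small_config(n_genes=150)
        fx = generate_genome_fixture(cfg)
        expr = generate_expression_table(cfg, fx)
        linked = expr[expr["linked_truth_class"] == "gained"]
        passing = linked[(linked["case_mean"] >= 0.1) & (linked["control_mean"] >= 0.1)]
        fc = passing["case_mean"] / passing["control_mean"]
        assert fc.median() > 1

    def test_low_expression_genes_exist(self):
        cfg = small_config(n_genes=200)
        fx = generate_genome_fixture(cfg)
        expr = generate_expression_table(cfg, fx)
        assert ((expr["case_mean"] < 0.1) & (expr["control_mean"] < 0.1)).any()
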