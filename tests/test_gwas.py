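"""LD expansion, trait agglomeration, and permutation enrichment."""

import numpy as np
import pandas as pd
import pytest

from dremap.gwas import (agglomerate_traits, compute_r2, expand_ld,
                         permutation_enrichment, snps_in_regions)
from dremap.panel import HaplotypePanel
from dremap.regions import RegulatoryRegion


def panel_of(cols: dict[str, tuple[str, int, np.ndarray]]):
    meta = pd.DataFrame(
        [(s, c, p, "A", "G") for s, (c, p, _) in cols.items()],
        columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return HaplotypePanel(meta, np.vstack([v for _, _, v in cols.values()]).astype(np.int8))


def reg(start, end, chrom="chr1"):
    return RegulatoryRegion(chrom, start, end, 3, 0.1, "hypo")


class TestR2:
    def test_identical_columns_r2_one(self):
        col = np.array([1, 0, 1, 0, 1, 1], dtype=np.int8)
        panel = panel_of({"a": ("chr1", 0, col), "b": ("chr1", 10, col.copy())})
        assert compute_r2(panel, "a", "b") == pytest.approx(1.0)

    def test_worked_four_haplotype_panel(self):
        # haplotypes AB/AB/ab/aB: p_A=0.5, p_B=0.75, p_AB=0.5 -> r2 = 1/3
        a = np.array([1, 1, 0, 0], dtype=np.int8)
        b = np.array([1, 1, 0, 1], dtype=np.int8)
        panel = panel_of({"a": ("chr1", 0, a), "b": ("chr1", 10, b)})
        assert compute_r2(panel, "a", "b") == pytest.approx(1 / 3, rel=1e-12)

    def test_independent_columns_near_zero(self, rng):
        a = (rng.random(20_000) < 0.4).astype(np.int8)
        b = (rng.random(20_000) < 0.6).astype(np.int8)
        panel = panel_of({"a": ("chr1", 0, a), "b": ("chr1", 10, b)})
        assert compute_r2(panel, "a", "b") < 0.01

    def test_symmetric_and_label_swap_invariant(self, rng):
        a = (rng.random(500) < 0.3).astype(np.int8)
        b = np.where(rng.random(500) < 0.8, a, (rng.random(500) < 0.3)).astype(np.int8)
        panel = panel_of({"a": ("chr1", 0, a), "b": ("chr1", 10, b),
                          "a_swapped": ("chr1", 20, 1 - a)})
        r_ab = compute_r2(panel, "a", "b")
        assert compute_r2(panel, "b", "a") == pytest.approx(r_ab)
        assert compute_r2(panel, "a_swapped", "b") == pytest.approx(r_ab)

    def test_monomorphic_flagged_nan(self):
        a = np.ones(10, dtype=np.int8)
        b = np.array([1, 0] * 5, dtype=np.int8)
        panel = panel_of({"a": ("chr1", 0, a), "b": ("chr1", 10, b)})
        with pytest.warns(UserWarning, match="monomorphic"):
            assert np.isnan(compute_r2(panel, "a", "b"))


class TestExpandLd:
    def catalog(self):
        return pd.DataFrame({
            "snp_id": ["tag"], "chrom": ["chr1"], "pos": [100_000],
            "trait": ["breast cancer"], "risk_allele": ["G"]})

    def test_no_partners_keeps_tag_only(self, rng):
        tag = (rng.random(800) < 0.5).astype(np.int8)
        other = (rng.random(800) < 0.5).astype(np.int8)
        panel = panel_of({"tag": ("chr1", 100_000, tag),
                          "other": ("chr1", 110_000, other)})
        sets = expand_ld(self.catalog(), {"p": panel})
        assert sets["breast cancer"].snps == {"tag"}

    def test_tight_partner_included_with_provenance(self, rng):
        tag = (rng.random(2000) < 0.5).astype(np.int8)
        partner = np.where(rng.random(2000) < 0.99, tag,
                           (rng.random(2000) < 0.5)).astype(np.int8)
        panel = panel_of({"tag": ("chr1", 100_000, tag),
                          "partner": ("chr1", 112_000, partner)})
        sets = expand_ld(self.catalog(), {"p": panel})
        assert sets["breast cancer"].snps == {"tag", "partner"}
        prov = sets["breast cancer"].provenance
        assert prov["r2"].iloc[0] > 0.8

    def test_distance_rule_excludes_distant_partner(self, rng):
        tag = (rng.random(2000) < 0.5).astype(np.int8)
        panel = panel_of({"tag": ("chr1", 100_000, tag),
                          "far": ("chr1", 700_000, tag.copy())})
        sets = expand_ld(self.catalog(), {"p": panel}, max_dist=500_000)
        assert "far" not in sets["breast cancer"].snps

    def test_union_over_panels(self, rng):
        tag = (rng.random(2000) < 0.5).astype(np.int8)
        partner = tag.copy()
        panel_with = panel_of({"tag": ("chr1", 100_000, tag),
                               "partner": ("chr1", 112_000, partner)})
        indep = (rng.random(2000) < 0.5).astype(np.int8)
        panel_without = panel_of({"tag": ("chr1", 100_000, tag),
                                  "partner": ("chr1", 112_000, indep)})
        sets = expand_ld(self.catalog(), {"a": panel_without, "b": panel_with})
        assert "partner" in sets["breast cancer"].snps


class TestAgglomeration:
    def catalog(self):
        return pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(5)],
            "chrom": "chr1", "pos": range(5),
            "trait": ["chronic lymphocytic leukemia", "Hodgkin's lymphoma",
                      "breast cancer", "height", "acute myeloid leukemia"],
            "risk_allele": "G"})

    def test_keyword_routing(self):
        cats = agglomerate_traits(self.catalog())
        assert cats["CLL"].snps == {"rs0"}
        assert cats["lymphoma"].snps == {"rs1"}
        assert cats["cancer"].snps == {"rs2", "rs4"}
        assert cats["irrelevant"].snps == {"rs3"}

    def test_cll_precedence_over_lymphoma(self):
        cat = pd.DataFrame({
            "snp_id": ["rs0"], "chrom": ["chr1"], "pos": [0],
            "trait": ["chronic lymphocytic leukemia (a lymphoma)"],
            "risk_allele": ["G"]})
        cats = agglomerate_traits(cat)
        assert cats["CLL"].snps == {"rs0"} and not cats["lymphoma"].snps

    def test_disjoint_and_covering(self):
        cats = agglomerate_traits(self.catalog())
        all_snps = [s for c in cats.values() for s in c.snps]
        assert len(all_snps) == len(set(all_snps)) == 5


class TestPermutationEnrichment:
    def setup_fixture(self, rng, n_regions=60, n_snps=300):
        regions = []
        for i in range(n_regions):
            s = 1000 * i
            regions.append(reg(s, s + 500))
        labels = (["gained"] * 20 + ["lost"] * 20 + ["shared"] * 10 + ["himr"] * 10)
        positions = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(n_snps)],
            "chrom": "chr1",
            "pos": rng.integers(0, 1000 * n_regions, n_snps)})
        return regions, labels, positions

    def test_membership_half_open(self):
        regions = [reg(100, 200)]
        pos = pd.DataFrame({"snp_id": ["a", "b", "c"], "chrom": "chr1",
                            "pos": [100, 199, 200]})
        mask = snps_in_regions(pos, regions)
        assert list(mask) == [True, True, False]

    def test_empty_trait_p_one(self, rng):
        regions, labels, positions = self.setup_fixture(rng)
        test = permutation_enrichment(regions, labels, positions, set(),
                                      n_perm=50, seed=0)
        assert test.observed_count == 0 and test.p_value == 1.0

    def test_single_class_degenerate(self, rng):
        regions, _, positions = self.setup_fixture(rng)
        labels = ["gained"] * len(regions)
        trait = set(positions["snp_id"].iloc[:20])
        test = permutation_enrichment(regions, labels, positions, trait,
                                      n_perm=50, seed=0)
        assert test.p_value == 1.0

    def test_add_one_correction_bounds(self, rng):
        regions, labels, positions = self.setup_fixture(rng)
        trait = set(positions["snp_id"].iloc[:30])
        test = permutation_enrichment(regions, labels, positions, trait,
                                      n_perm=99, seed=1)
        assert 1 / 100 <= test.p_value <= 1.0
        assert test.p_value > 0

    def test_planted_enrichment_detected(self, rng):
        regions, labels, positions = self.setup_fixture(rng)
        # trait SNPs concentrated inside gained regions (first 20 regions)
        inside = positions[positions["pos"] < 20_000]
        inside = inside[inside["pos"] % 1000 < 500]
        trait = set(inside["snp_id"])
        assert len(trait) >= 3  # deterministic fixture carries enough signal
        test = permutation_enrichment(regions, labels, positions, trait,
                                      n_perm=200, seed=2)
        assert test.p_value < 0.05
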