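"""DEG filtering, promoters, overlaps, and hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest

import hicarch as h
from hicarch.diffhic import detect_differential, loess_joint_normalize, md_table


@pytest.fixture(scope="module")
def diff_set(sim1):
    t = loess_joint_normalize(md_table(sim1["m1"], sim1["m2"]))
    return detect_differential(t)


class TestFilterDegs:
    @pytest.mark.parametrize(
        "fdr, log2fc, kept",
        [
            (0.04, 1.3, True),   # both thresholds met
            (0.06, 3.0, False),  # FDR fails
            (0.01, -1.0, True),  # 2-fold down counts (two-sided)
            (0.05, 0.9, False),  # fold fails
        ],
    )
    def test_threshold_rules(self, fdr, log2fc, kept):
        t = h.DEGTable(pd.DataFrame({"gene_id": ["g"], "log2fc": [log2fc], "fdr": [fdr]}))
        assert (("g" in h.filter_degs(t)) is kept)

    def test_simulated_degs_pass_and_others_fail(self, sim1):
        kept = h.filter_degs(sim1["degs"])
        assert kept == set(sim1["truth"].deg_ids)


class TestPromoters:
    @pytest.fixture()
    def genome(self):
        return h.BinnedGenome(("chr1",), (100_000,), 10_000)

    def make(self, start, end, strand):
        return h.GeneTable(pd.DataFrame(
            [{"gene_id": "g", "chrom": "chr1", "start": start, "end": end, "strand": strand}]
        ))

    def test_plus_strand_window(self, genome):
        p = h.promoters(self.make(10_000, 20_000, "+"), genome, upstream=2000, downstream=500)
        assert (p.iloc[0]["start"], p.iloc[0]["end"]) == (8_000, 10_500)

    def test_minus_strand_mirrored(self, genome):
        p = h.promoters(self.make(10_000, 20_000, "-"), genome, upstream=2000, downstream=500)
        assert (p.iloc[0]["start"], p.iloc[0]["end"]) == (19_500, 22_000)

    def test_clipped_at_chromosome_start(self, genome):
        p = h.promoters(self.make(500, 2_000, "+"), genome, upstream=2000, downstream=200)
        assert p.iloc[0]["start"] == 0

    def test_empty_window_errors(self, genome):
        with pytest.raises(ValueError, match="empty"):
            h.promoters(self.make(10_000, 20_000, "+"), genome, upstream=0, downstream=0)


def brute_force_overlap(a, b):
    pairs = []
    for ai, ar in a.iterrows():
        for bi, br in b.iterrows():
            if ar["chrom"] == br["chrom"] and ar["start"] < br["end"] and br["start"] < ar["end"]:
                pairs.append((ai, bi))
    return pairs


class TestOverlapCount:
    def test_half_open_boundary_is_not_an_overlap(self):
        a = pd.DataFrame([{"chrom": "c", "start": 0, "end": 10}])
        b = pd.DataFrame([{"chrom": "c", "start": 10, "end": 20}])
        assert h.overlap_count(a, b)[0] == 0

    def test_one_bp_overlap_counts(self):
        a = pd.DataFrame([{"chrom": "c", "start": 0, "end": 10}])
        b = pd.DataFrame([{"chrom": "c", "start": 9, "end": 20}])
        na, nb, pairs = h.overlap_count(a, b)
        assert (na, nb, pairs) == (1, 1, [(0, 0)])

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            a = pd.DataFrame({
                "chrom": rng.choice(["c1", "c2"], 30),
                "start": rng.integers(0, 1000, 30),
            })
            a["end"] = a["start"] + rng.integers(1, 100, 30)
            b = pd.DataFrame({
                "chrom": rng.choice(["c1", "c2"], 30),
                "start": rng.integers(0, 1000, 30),
            })
            b["end"] = b["start"] + rng.integers(1, 100, 30)
            _, _, pairs = h.overlap_count(a, b)
            assert sorted(pairs) == sorted(brute_force_overlap(a, b))


class TestEnrichment:
    def test_whole_universe_gene_set_has_unit_fold(self, sim1, class_map):
        universe = sim1["genes"]
        res = h.enrich_genes_in_classes(set(universe.df["gene_id"]), universe, class_map)
        assert np.allclose(res["fold"], 1.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_degs_enriched_in_changed_compartments(self, sim1, class_map):
        res = h.enrich_genes_in_classes(h.filter_degs(sim1["degs"]), sim1["genes"], class_map)
        p = res.loc[(res["dimension"] == "compartment") & (res["class"] == "changed"), "pvalue"]
        assert float(p.iloc[0]) < 1e-3

    def test_two_class_fold_symmetry(self):
        # with only two classes, enrichment in one implies depletion in the other
        r1 = h.hypergeom_enrichment(100, 40, 30, 20)
        r2 = h.hypergeom_enrichment(100, 60, 30, 10)
        assert (r1.fold - 1) * (r2.fold - 1) < 0

    def test_anchor_bins_fully_inside_one_class(self, sim1, class_map):
        pixels = pd.DataFrame({"chrom": ["chr1"] * 3, "bin_i": [210, 220, 230],
                               "bin_j": [250, 260, 270]})
        from hicarch.diffhic import DifferentialContactSet

        dc = DifferentialContactSet(class_map.genome, pixels, fdr=0.05, regions={})
        res = h.enrich_pixels_in_classes(dc, class_map, dimensions=("domain",))
        non_tad = res[res["class"] == "non-TAD"].iloc[0]
        assert non_tad["k"] == non_tad["n"]

    def test_differential_anchors_enriched_in_changed_classes(self, sim1, class_map, diff_set):
        res = h.enrich_pixels_in_classes(diff_set, class_map)
        p = res.loc[(res["dimension"] == "compartment") & (res["class"] == "changed"), "pvalue"]
        assert float(p.iloc[0]) < 1e-2

    def test_uniform_gene_sets_give_calibrated_pvalues(self, sim1, class_map):
        from scipy import stats as sps

        ids = list(sim1["genes"].df["gene_id"])
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(100):
            gs = set(rng.choice(ids, size=200, replace=False))
            res = h.enrich_genes_in_classes(gs, sim1["genes"], class_map,
                                            dimensions=("compartment",))
            ps.append(float(res.loc[res["class"] == "changed", "pvalue"].iloc[0]))
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_gene_outside_universe_errors(self, sim1, class_map):
        with pytest.raises(ValueError, match="outside the universe"):
            h.enrich_genes_in_classes({"nope"}, sim1["genes"], class_map)


class TestPromoterDensity:
    def test_deg_promoters_denser_in_differential_regions(self, sim1, diff_set):
        genome = sim1["cfg"].genome()
        prom = h.promoters(sim1["genes"], genome)
        deg_prom = prom[prom["gene_id"].isin(list(h.filter_degs(sim1["degs"])))]
        res = h.promoter_density_contrast(deg_prom.reset_index(drop=True), diff_set, genome)
        assert res["ratio"] >= 1.5

    def test_all_promoters_inside_gives_infinite_ratio(self, sim1, diff_set):
        genome = sim1["cfg"].genome()
        chrom, (s, e) = next(
            (c, r[0]) for c, r in diff_set.regions.items() if r
        )
        prom = pd.DataFrame([{"gene_id": "g", "chrom": chrom,
                              "start": s * 10_000, "end": s * 10_000 + 100}])
        res = h.promoter_density_contrast(prom, diff_set, genome)
        assert res["ratio"] == np.inf

    def test_empty_region_set_errors(self, sim1):
        from hicarch.diffhic import DifferentialContactSet

        genome = sim1["cfg"].genome()
        dc = DifferentialContactSet(genome, pd.DataFrame(), fdr=0.05, regions={})
        with pytest.raises(ValueError, match="empty"):
            h.promoter_density_contrast(pd.DataFrame(columns=["chrom", "start", "end"]), dc, genome)


class TestGeneInteractionProfile:
    def test_profile_peaks_at_loop_partner(self, sim1):
        # place a synthetic gene on a loop anchor and look for the partner peak
        chrom, i, j = sim1["truth"].loops[1][0]
        genes = h.GeneTable(pd.DataFrame([{
            "gene_id": "anchor_gene", "chrom": chrom,
            "start": i * 10_000 + 100, "end": i * 10_000 + 900, "strand": "+",
        }]))
        offsets, values = h.gene_interaction_profile(
            "anchor_gene", sim1["oe1"], genes, flank=500_000
        )
        partner_offset = (j - i) * 10_000
        k = np.where(offsets == partner_offset)[0][0]
        far = np.abs(offsets) > 50_000
        assert values[k] > 2 * np.nanmean(values[far & (values > 0)])

    def test_decay_only_profile_near_unity(self, decay_sim):
        b = decay_sim["b1"]
        oe = h.oe_transform(b, decay_sim["e1"])
        genes = h.GeneTable(pd.DataFrame([{
            "gene_id": "g", "chrom": "chr1", "start": 2_000_100,
            "end": 2_000_900, "strand": "+",
        }]))
        offsets, values = h.gene_interaction_profile("g", oe, genes, flank=300_000)
        assert abs(np.nanmean(values[np.abs(offsets) > 20_000]) - 1.0) < 0.2

    def test_flank_smaller_than_bin_errors(self, sim1):
        genes = h.GeneTable(pd.DataFrame([{
            "gene_id": "g", "chrom": "chr1", "start": 100_000, "end": 101_000, "strand": "+",
        }]))
        with pytest.raises(ValueError, match="smaller than one bin"):
            h.gene_interaction_profile("g", sim1["oe1"], genes, flank=5_000)

    def test_unknown_gene_errors(self, sim1):
        with pytest.raises(ValueError, match="not in gene table"):
            h.gene_interaction_profile("missing", sim1["oe1"], sim1["genes"], flank=100_000)
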