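"""Permutation-null enrichment, promoter contacts, and genomic partitions."""

import numpy as np
import pytest

import te4c
from te4c import FeatureSet, GenomicInterval, Interaction

CHROM_SIZES = {"c": 10_000_000, "d": 8_000_000}


def make_interaction(c1, s1, c2, s2, score=12.0, width=100):
    return Interaction(
        GenomicInterval(c1, s1, s1 + width),
        GenomicInterval(c2, s2, s2 + width),
        score,
    )


def random_interactions(rng, n=60, anchor_chrom="c"):
    out = []
    for _ in range(n):
        chrom = str(rng.choice(list(CHROM_SIZES)))
        s2 = int(rng.integers(0, CHROM_SIZES[chrom] - 200))
        out.append(make_interaction(anchor_chrom, 1000, chrom, s2))
    return out


class TestOverlapEnrichment:
    def test_features_equal_to_ends_give_p_zero(self):
        rng = np.random.default_rng(0)
        ints = random_interactions(rng, 40)
        features = FeatureSet("self", [i.other_end for i in ints])
        res = te4c.overlap_enrichment(ints, features, CHROM_SIZES, 200, seed=1)
        assert res.observed_overlap == 40
        assert res.empirical_p == 0.0

    def test_flank_extends_reach(self):
        ints = [make_interaction("c", 1000, "c", 100_000)]
        features = FeatureSet("near", [GenomicInterval("c", 101_000, 101_050)])
        # other end [100000,100100); feature 900 bp away; 1 kb flank bridges it
        res = te4c.overlap_enrichment(
            ints, features, CHROM_SIZES, 10, interaction_flank=1000, seed=2
        )
        assert res.observed_overlap == 1
        res0 = te4c.overlap_enrichment(
            ints, features, CHROM_SIZES, 10, interaction_flank=0, seed=2
        )
        assert res0.observed_overlap == 0

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(3)
        ints = random_interactions(rng, 30)
        features = FeatureSet(
            "f", [GenomicInterval("c", int(s), int(s) + 500)
                  for s in rng.integers(0, 9_000_000, 50)]
        )
        a = te4c.overlap_enrichment(ints, features, CHROM_SIZES, 100, seed=7)
        b = te4c.overlap_enrichment(ints, features, CHROM_SIZES, 100, seed=7)
        assert np.array_equal(a.background_overlaps, b.background_overlaps)
        assert a.empirical_p == b.empirical_p

    def test_p_monotone_in_observed(self):
        rng = np.random.default_rng(4)
        ints = random_interactions(rng, 30)
        features = FeatureSet(
            "f", [GenomicInterval("c", int(s), int(s) + 2000)
                  for s in rng.integers(0, 9_000_000, 80)]
        )
        res = te4c.overlap_enrichment(ints, features, CHROM_SIZES, 200, seed=9)
        bg = res.background_overlaps
        pvals = [float(np.mean(bg > obs)) for obs in range(0, 31)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_missing_chrom_errors(self):
        ints = [make_interaction("c", 0, "unknown", 0)]
        with pytest.raises(ValueError):
            te4c.overlap_enrichment(
                ints, FeatureSet("f", []), CHROM_SIZES, 10, seed=1
            )

    def test_seed_required(self):
        with pytest.raises(ValueError):
            te4c.overlap_enrichment([], FeatureSet("f", []), CHROM_SIZES, 10)


class TestPromoterContacts:
    def test_single_qualifying_contact(self):
        ints = [make_interaction("c", 1000, "c", 500_000, score=15.0)]
        tss = [GenomicInterval("c", 501_000, 501_001, name="geneA")]
        per_anchor, per_prom, kept = te4c.promoter_contact_map(ints, tss)
        assert list(per_anchor.values()) == [1]
        assert per_prom == {"geneA": 1}
        assert kept == ints

    def test_anchor_contacting_two_promoters(self):
        ints = [
            make_interaction("c", 1000, "c", 500_000, score=15.0),
            make_interaction("c", 1000, "c", 900_000, score=15.0),
        ]
        tss = [
            GenomicInterval("c", 500_500, 500_501, name="g1"),
            GenomicInterval("c", 900_500, 900_501, name="g2"),
        ]
        per_anchor, per_prom, _ = te4c.promoter_contact_map(ints, tss)
        assert list(per_anchor.values()) == [2]
        assert per_prom == {"g1": 1, "g2": 1}

    def test_boundary_score_and_distance_excluded(self):
        tss = [GenomicInterval("c", 500_000, 500_001, name="g")]
        at_score = [make_interaction("c", 1000, "c", 499_900, score=10.0)]
        assert te4c.promoter_contact_map(at_score, tss)[2] == []
        exactly_5mb = [
            Interaction(
                GenomicInterval("c", 0, 100),
                GenomicInterval("c", 5_000_000, 5_000_100),
                15.0,
            )
        ]
        tss2 = [GenomicInterval("c", 5_000_050, 5_000_051, name="g2")]
        assert te4c.promoter_contact_map(exactly_5mb, tss2)[2] == []
        trans = [make_interaction("c", 0, "d", 499_900, score=15.0)]
        tss3 = [GenomicInterval("d", 500_000, 500_001, name="g3")]
        assert te4c.promoter_contact_map(trans, tss3)[2] == []


class TestPartitionedOverlap:
    @pytest.fixture()
    def gene_model(self):
        tss = FeatureSet("tss", [GenomicInterval("c", 100_000, 100_001)], flank=3000)
        genes = FeatureSet("genes", [GenomicInterval("c", 100_000, 150_000)])
        return tss, genes

    def test_tss_precedence_over_gene_body(self, gene_model):
        tss, genes = gene_model
        ints = [make_interaction("c", 0, "c", 101_000)]  # in TSS window AND gene
        table = te4c.partitioned_overlap(ints, tss, genes, [])
        assert table["tss"]["n"] == 1
        assert table["gene_body"]["n"] == 0

    def test_intergenic_assignment(self, gene_model):
        tss, genes = gene_model
        ints = [make_interaction("c", 0, "c", 900_000)]
        table = te4c.partitioned_overlap(ints, tss, genes, [])
        assert table["intergenic"]["n"] == 1

    def test_every_interaction_in_exactly_one_class(self, gene_model):
        tss, genes = gene_model
        rng = np.random.default_rng(5)
        ints = random_interactions(rng, 50)
        feats = [
            FeatureSet("stat", [GenomicInterval("c", 120_000, 121_000)]),
        ]
        table = te4c.partitioned_overlap(ints, tss, genes, feats)
        assert sum(table[p]["n"] for p in table) == len(ints)

    def test_hand_enumerated_feature_table(self, gene_model):
        tss, genes = gene_model
        ints = [
            make_interaction("c", 0, "c", 99_000),    # tss window (flank 3 kb)
            make_interaction("c", 0, "c", 120_000),   # gene body
            make_interaction("c", 0, "c", 140_000),   # gene body
            make_interaction("c", 0, "c", 500_000),   # intergenic
        ]
        feats = [FeatureSet("peak", [GenomicInterval("c", 140_200, 140_300)])]
        table = te4c.partitioned_overlap(ints, tss, genes, feats)
        assert table["tss"] == {"n": 1, "peak": 0}
        assert table["gene_body"] == {"n": 2, "peak": 1}
        assert table["intergenic"] == {"n": 1, "peak": 0}


class TestCalibrationAndPower:
    """Statistical behavior of the permutation test at reduced scale.

    The full-scale calibration/power runs (200 and 100 seeded repetitions)
    live with the acceptance checks; here a smaller version guards the
    machinery during development.
    """

    def test_null_calibration_small(self):
        false_pos = 0
        n_runs = 40
        for run in range(n_runs):
            rng = np.random.default_rng(1000 + run)
            ints = random_interactions(rng, 50)
            features = FeatureSet(
                "f",
                [GenomicInterval("c", int(s), int(s) + 1000)
                 for s in rng.integers(0, 9_000_000, 60)],
            )
            res = te4c.overlap_enrichment(
                ints, features, CHROM_SIZES, 200, seed=2000 + run
            )
            if res.empirical_p <= 0.05:
                false_pos += 1
        assert false_pos / n_runs <= 0.15  # loose guard at this scale

    def test_power_with_planted_overlap(self):
        hits = 0
        n_runs = 20
        for run in range(n_runs):
            rng = np.random.default_rng(3000 + run)
            features = FeatureSet(
                "f",
                [GenomicInterval("c", int(s), int(s) + 1000)
                 for s in rng.integers(0, 9_000_000, 60)],
            )
            ints = random_interactions(rng, 50)
            # plant 5x the null rate of ends inside features
            planted = [
                make_interaction("c", 1000, "c", f.start + 200)
                for f in features.intervals[:15]
            ]
            res = te4c.overlap_enrichment(
                ints + planted, features, CHROM_SIZES, 200, seed=4000 + run
            )
            if res.empirical_p < 0.05:
                hits += 1
        assert hits / n_runs >= 0.9
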