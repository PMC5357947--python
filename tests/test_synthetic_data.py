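import numpy as np
import pandas as pd
import pytest

from faire_memory.region_core import count_reads
from faire_memory.synthetic_data import (
    SyntheticDatasetSpec,
    consensus_pwm,
    generate_expression,
    generate_regions_and_counts,
    generate_reads_for_regions,
    generate_sequences_with_motifs,
    generate_state_segments,
    generate_transcripts,
)
from faire_memory.expression import classify_genes
from faire_memory.motifs import scan_pwm


class TestSpecValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticDatasetSpec(set_proportions={"unchanged": 0.5, "e": 0.4})

    def test_small_effect_fold_rejected_with_plants(self):
        with pytest.raises(ValueError, match="effect_fold"):
            SyntheticDatasetSpec(
                set_proportions={"unchanged": 0.5, "e": 0.5}, effect_fold=1.5
            )

    def test_small_expression_effect_rejected(self):
        with pytest.raises(ValueError, match="expression_effect"):
            SyntheticDatasetSpec(expression_effect=0.3)

    def test_unknown_set_label_rejected(self):
        with pytest.raises(ValueError, match="unknown set label"):
            SyntheticDatasetSpec(set_proportions={"unchanged": 0.5, "zz": 0.5})


class TestCounts:
    def test_no_noise_no_plants_counts_equal_baseline(self):
        spec = SyntheticDatasetSpec(
            seed=3, n_regions=50, set_proportions={"unchanged": 1.0}, nb_dispersion=0.0
        )
        _, counts, truth = generate_regions_and_counts(spec)
        assert (counts.counts.to_numpy() == spec.baseline_mean).all()
        assert (truth["set_label"] == "unchanged").all()

    def test_seed_determinism(self):
        a = generate_regions_and_counts(SyntheticDatasetSpec(seed=7, n_regions=100))
        b = generate_regions_and_counts(SyntheticDatasetSpec(seed=7, n_regions=100))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1].counts, b[1].counts)
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_different_seeds_differ(self):
        a = generate_regions_and_counts(SyntheticDatasetSpec(seed=1, n_regions=100))
        b = generate_regions_and_counts(SyntheticDatasetSpec(seed=2, n_regions=100))
        assert not a[1].counts.equals(b[1].counts)

    def test_planted_fold_matches_generative_mean(self):
        """Mean ST/NS count ratio over set-e plants tracks effect_fold
        within 3 standard errors (Monte-Carlo check)."""
        spec = SyntheticDatasetSpec(
            seed=11, n_regions=1000,
            set_proportions={"unchanged": 0.8, "e": 0.2},
        )
        _, counts, truth = generate_regions_and_counts(spec)
        planted = truth.index[truth["set_label"] == "e"]
        ns = counts.counts.loc[planted, "NS_DMSO"].to_numpy(dtype=float)
        st = counts.counts.loc[planted, "ST_DMSO"].to_numpy(dtype=float)
        ratio = st.mean() / ns.mean()
        # delta-method s.e. of the ratio of means
        n = len(planted)
        se = ratio * np.sqrt(st.var() / st.mean() ** 2 / n + ns.var() / ns.mean() ** 2 / n)
        assert abs(ratio - spec.effect_fold) < 3 * se

    def test_regions_disjoint_and_within_bounds(self, small_dataset):
        regions = small_dataset.regions
        for _, grp in regions.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()
        assert (regions["start"] >= 0).all()
        assert (regions["end"] <= small_dataset.spec.chromosome_length).all()

    def test_library_size_factors_scale_means(self):
        spec = SyntheticDatasetSpec(
            seed=5, n_regions=50, set_proportions={"unchanged": 1.0},
            nb_dispersion=0.0, library_size_factors={"ST_DMSO": 2.0},
        )
        _, counts, _ = generate_regions_and_counts(spec)
        assert (counts.counts["ST_DMSO"] == 2 * counts.counts["NS_DMSO"]).all()


class TestReads:
    def test_round_trip_recovers_count_matrix_exactly(self, small_dataset):
        ds = small_dataset
        recounted = count_reads(
            ds.regions, ds.reads, ds.spec.extension, ds.counts.sample_meta
        )
        got = recounted.counts.loc[ds.counts.counts.index, ds.counts.sample_ids]
        assert (got.to_numpy() == ds.counts.counts.to_numpy()).all()

    def test_zero_count_region_gets_no_overlapping_reads(self):
        spec = SyntheticDatasetSpec(
            seed=9, n_regions=20, set_proportions={"unchanged": 1.0},
            baseline_mean=0.0, nb_dispersion=0.0, background_read_density=1e-4,
        )
        regions, counts, _ = generate_regions_and_counts(spec)
        reads = generate_reads_for_regions(spec, regions, counts)
        recounted = count_reads(regions, reads, spec.extension, counts.sample_meta)
        assert (recounted.counts.to_numpy() == 0).all()
        assert len(reads) > 0  # background reads exist but never overlap

    def test_region_wider_than_chromosome_raises(self):
        spec = SyntheticDatasetSpec(seed=1, n_regions=10)
        regions = pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": spec.chromosome_length + 1,
              "region_id": "r0"}]
        )
        _, counts, _ = generate_regions_and_counts(
            SyntheticDatasetSpec(seed=1, n_regions=1)
        )
        counts.counts.index = ["r0"]
        with pytest.raises(ValueError, match="wider than chromosome"):
            generate_reads_for_regions(spec, regions, counts)


class TestExpression:
    def test_planted_classes_fully_recovered_without_noise(self):
        spec = SyntheticDatasetSpec(seed=2, n_regions=50, n_genes=300,
                                    expression_noise_sd=0.0)
        regions, _, truth = generate_regions_and_counts(spec)
        _, genes = generate_transcripts(spec, regions, truth)
        expr = generate_expression(spec, genes)
        classes = classify_genes(expr)
        assert (classes["gene_class"] == genes["planted_class"]).all()

    def test_no_plants_no_classes_at_zero_noise(self):
        spec = SyntheticDatasetSpec(seed=2, n_regions=50, n_genes=200,
                                    prg_fraction=0.0, mrg_fraction=0.0,
                                    expression_noise_sd=0.0)
        regions, _, truth = generate_regions_and_counts(spec)
        _, genes = generate_transcripts(spec, regions, truth)
        classes = classify_genes(generate_expression(spec, genes))
        assert (classes["gene_class"] == "other").all()

    def test_recovery_with_noise(self):
        """noise sd 0.2, effect 1.0, 500 genes: planted-label recovery
        stays high."""
        spec = SyntheticDatasetSpec(seed=4, n_regions=50, n_genes=500)
        regions, _, truth = generate_regions_and_counts(spec)
        _, genes = generate_transcripts(spec, regions, truth)
        classes = classify_genes(generate_expression(spec, genes))
        assert (classes["gene_class"] == genes["planted_class"]).mean() >= 0.95

    def test_mrg_tss_placed_near_designated_sets(self, small_dataset):
        ds = small_dataset
        from faire_memory.expression import min_distance_to_set

        near_regions = ds.regions.merge(
            ds.truth[ds.truth["set_label"].isin(ds.spec.mrg_near_sets)],
            left_on="region_id", right_index=True,
        )
        mrg = ds.genes[ds.genes["planted_class"] == "MRG"]
        dist = min_distance_to_set(mrg[["chrom", "tss"]], near_regions)
        frac_near = (dist <= ds.spec.proximity_window).mean()
        assert frac_near >= 0.6 * ds.spec.mrg_near_fraction


class TestSequences:
    def test_plant_prob_one_embeds_consensus_everywhere(self):
        spec = SyntheticDatasetSpec(
            seed=6, n_regions=100, region_width_range=(300, 300),
            motif_plant_prob={("NFAT", "c"): 1.0},
            set_proportions={"unchanged": 0.5, "c": 0.5},
        )
        regions, _, truth = generate_regions_and_counts(spec)
        seqs, planted = generate_sequences_with_motifs(spec, regions, truth)
        consensus = "TTTCCA"
        for rid in truth.index[truth["set_label"] == "c"]:
            assert consensus in seqs[rid]

    def test_no_plants_hit_rate_matches_background_expectation(self):
        """Scanner hit rate on plant-free sequences stays within a binomial
        CI of the closed-form background hit probability."""
        spec = SyntheticDatasetSpec(
            seed=8, n_regions=300, region_width_range=(300, 300),
            set_proportions={"unchanged": 1.0},
        )
        regions, _, truth = generate_regions_and_counts(spec)
        seqs, planted = generate_sequences_with_motifs(spec, regions, truth)
        assert len(planted) == 0
        pwm = consensus_pwm("NFAT", "TTTCCA")
        threshold = 0.8 * pwm.max_score
        # closed form: P(window score >= threshold) for iid uniform bases
        lo = pwm.log_odds
        probs = np.ones(1)
        for j in range(pwm.length):
            probs = np.add.outer(probs, lo[:, j]).ravel()
        p_window = (probs >= threshold).mean()
        n_windows = 2 * (300 - pwm.length + 1)
        p_hit = 1 - (1 - p_window) ** n_windows  # approx: windows ~independent
        hits = sum(
            scan_pwm(seqs[rid], pwm, relative_threshold=0.8).count > 0
            for rid in truth.index
        )
        se = np.sqrt(p_hit * (1 - p_hit) * 300)
        assert abs(hits - 300 * p_hit) < 4 * se + 3

    def test_seed_reproducibility(self):
        spec = SyntheticDatasetSpec(seed=10, n_regions=30,
                                    motif_plant_prob={("NFAT", "*"): 0.3})
        regions, _, truth = generate_regions_and_counts(spec)
        a, _ = generate_sequences_with_motifs(spec, regions, truth)
        b, _ = generate_sequences_with_motifs(spec, regions, truth)
        assert a == b

    def test_motif_longer_than_region_raises(self):
        spec = SyntheticDatasetSpec(seed=1, n_regions=10, region_width_range=(200, 200))
        regions, _, truth = generate_regions_and_counts(spec)
        long_pwm = consensus_pwm("LONG", "A" * 300)
        with pytest.raises(ValueError, match="longer than"):
            generate_sequences_with_motifs(spec, regions, truth, [long_pwm])


class TestStateSegments:
    def test_tiling_covers_chromosomes(self):
        spec = SyntheticDatasetSpec(seed=3, n_regions=10)
        segs = generate_state_segments(spec)
        for ct, df in segs.items():
            for chrom, grp in df.groupby("chrom"):
                assert grp["start"].iloc[0] == 0
                assert grp["end"].iloc[-1] == spec.chromosome_length
                assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all()
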