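import numpy as np
import pandas as pd
import pytest

from natheat.chromatin import methylation_profile, peak_association
from natheat.expression import diff_test_all
from natheat.pairs import find_nat_pairs, orient_pairs
from natheat.simulate import (
    ConfigError,
    SimulationConfig,
    enriched_regions,
    generate_annotation,
    simulate_chromatin,
    simulate_expression,
    simulate_promoters,
    simulate_smrna,
)
from natheat.smrna import length_distribution, region_density_ratio, reads_to_frame

TINY = dict(n_gene_loci=25, chrom_sizes={"chr1": 300_000, "chr2": 300_000})


class TestConfigValidation:
    def test_bad_mix_rejected(self):
        with pytest.raises(ConfigError, match="configuration_mix"):
            SimulationConfig(configuration_mix={"enclosed": 0.9, "convergent": 0.3, "divergent": 0.0})

    def test_bad_proportion_rejected(self):
        with pytest.raises(ConfigError, match="frac_with_antisense"):
            SimulationConfig(frac_with_antisense=1.2)

    def test_sub_threshold_effect_rejected(self):
        with pytest.raises(ConfigError, match="log2FC"):
            SimulationConfig(planted_log2fc_range=(0.5, 2.0))

    def test_infeasible_packing(self):
        with pytest.raises(ConfigError, match="packing"):
            generate_annotation(SimulationConfig(n_gene_loci=100, chrom_sizes={"chr1": 50_000}))


class TestDeterminism:
    def test_identical_config_identical_outputs(self):
        cfg_a = SimulationConfig(seed=4, **TINY)
        cfg_b = SimulationConfig(seed=4, **TINY)
        ann_a, truth_a, _ = generate_annotation(cfg_a)
        ann_b, truth_b, _ = generate_annotation(cfg_b)
        assert ann_a == ann_b
        pd.testing.assert_frame_equal(truth_a.pairs, truth_b.pairs)
        pd.testing.assert_frame_equal(truth_a.effects, truth_b.effects)
        ea = simulate_expression(ann_a, truth_a, cfg_a)
        eb = simulate_expression(ann_b, truth_b, cfg_b)
        pd.testing.assert_frame_equal(ea.tpm, eb.tpm)
        ra = reads_to_frame(simulate_smrna(ann_a, truth_a, cfg_a))
        rb = reads_to_frame(simulate_smrna(ann_b, truth_b, cfg_b))
        pd.testing.assert_frame_equal(ra, rb)

    def test_different_seed_differs(self):
        a, _, _ = generate_annotation(SimulationConfig(seed=1, **TINY))
        b, _, _ = generate_annotation(SimulationConfig(seed=2, **TINY))
        assert a != b


class TestAnnotationGeometry:
    def test_no_antisense_no_pairs(self):
        cfg = SimulationConfig(seed=3, frac_with_antisense=0.0, **TINY)
        ann, truth, _ = generate_annotation(cfg)
        assert truth.pairs.empty
        assert find_nat_pairs(ann) == []

    def test_forced_enclosed_configuration(self):
        cfg = SimulationConfig(
            seed=3, configuration_mix={"enclosed": 1.0, "convergent": 0.0, "divergent": 0.0}, **TINY
        )
        ann, truth, _ = generate_annotation(cfg)
        assert (truth.pairs["configuration"] == "enclosed").all()
        for p in orient_pairs(ann, find_nat_pairs(ann)):
            assert p.configuration == "enclosed"

    def test_truth_pair_count_matches_discovery(self, small_world):
        ann, truth, _ = small_world
        found = set(find_nat_pairs(ann))
        planted = {
            tuple(sorted(t)) for t in truth.pairs[["sense_id", "antisense_id"]].itertuples(index=False)
        }
        assert planted == found

    def test_every_overlap_at_least_50(self, small_world):
        _, truth, _ = small_world
        assert ((truth.pairs["overlap_end"] - truth.pairs["overlap_start"]) >= 50).all()


class TestExpressionModel:
    def test_noise_free_fold_change_is_exact(self):
        cfg = SimulationConfig(
            seed=6, replicate_cv=0.0, planted_log2fc_range=(2.0, 2.0), frac_heat_responsive=1.0,
            frac_concordant=1.0, **TINY
        )
        ann, truth, _ = generate_annotation(cfg)
        expr = simulate_expression(ann, truth, cfg)
        eff = truth.effects
        assert not eff.empty
        for row in eff.itertuples(index=False):
            trt = expr.tpm.loc[row.transcript_id, expr.samples_for(row.tissue, row.timepoint_h)]
            ctrl = expr.tpm.loc[row.transcript_id, expr.samples_for(row.tissue, 0)]
            assert trt.mean() / ctrl.mean() == pytest.approx(2.0 ** row.log2fc)

    def test_baseline_mean_recovered(self):
        cfg = SimulationConfig(
            seed=9, n_gene_loci=1500, frac_with_antisense=0.0, frac_heat_responsive=0.0,
            chrom_sizes={"chr1": 16_000_000}, n_lincrna=0, n_incrna=0,
            n_short_decoys=0, n_blacklist_decoys=0, n_coding_decoys=0,
        )
        ann, truth, _ = generate_annotation(cfg)
        expr = simulate_expression(ann, truth, cfg)
        logs = np.log(expr.tpm.iloc[:, 0].to_numpy())
        se = cfg.baseline_log_tpm_sd / np.sqrt(len(logs))
        assert abs(logs.mean() - cfg.baseline_log_tpm_mean) < 3 * se


class TestSmrnaModel:
    def test_no_enrichment_gives_unit_ratio(self, small_cfg):
        cfg = SimulationConfig(seed=12, smrna_overlap_enrichment=1.0, **TINY)
        ann, truth, _ = generate_annotation(cfg)
        reads = simulate_smrna(ann, truth, cfg)
        ratio = region_density_ratio(reads, enriched_regions(ann, truth), sum(cfg.chrom_sizes.values()))
        assert ratio == pytest.approx(1.0, rel=0.25)

    def test_zero_background_all_reads_in_regions(self):
        cfg = SimulationConfig(seed=12, smrna_background_rate=0.0, **TINY)
        ann, truth, _ = generate_annotation(cfg)
        reads = simulate_smrna(ann, truth, cfg)
        regions = enriched_regions(ann, truth)
        assert all(regions.overlaps(r.chrom, r.start, r.end) for r in reads)

    def test_planted_24nt_excess_recovered(self):
        cfg = SimulationConfig(seed=12, smrna_24nt_weight=1.0, **TINY)
        ann, truth, _ = generate_annotation(cfg)
        reads = simulate_smrna(ann, truth, cfg)
        counts = length_distribution(reads)
        assert counts.idxmax() == 24

    def test_uniform_lengths_roughly_flat(self):
        cfg = SimulationConfig(seed=12, **TINY)
        ann, truth, _ = generate_annotation(cfg)
        counts = length_distribution(simulate_smrna(ann, truth, cfg))
        assert counts.min() > 0.6 * counts.max()


class TestChromatinModel:
    @pytest.mark.parametrize("frac,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_marked_fraction_extremes(self, frac, expected):
        cfg = SimulationConfig(seed=13, frac_tss_marked=frac, **TINY)
        ann, truth, _ = generate_annotation(cfg)
        peaks, _ = simulate_chromatin(ann, truth, cfg)
        genes = {"all": list(ann)}
        assoc = peak_association(peaks, genes, chrom_sizes=ann.chrom_sizes)
        assert (assoc["fraction"] == expected).all()

    def test_context_ordering_recovered(self):
        cfg = SimulationConfig(seed=13, **TINY)
        ann, truth, _ = generate_annotation(cfg)
        _, meth = simulate_chromatin(ann, truth, cfg)
        members = set(truth.pairs["sense_id"]) | set(truth.pairs["antisense_id"])
        prof = methylation_profile(meth, [ann[i] for i in sorted(members)])
        means = dict(zip(prof["context"], prof["mean_level"]))
        assert means["CpG"] > means["CHH"] > means["CHG"]


class TestPromoters:
    def test_planted_motif_always_detected(self):
        from natheat.chromatin import scan_hse

        cfg = SimulationConfig(seed=14, **TINY)
        ann, truth, _ = generate_annotation(cfg)
        promoters = simulate_promoters(ann, truth, cfg)
        planted = dict(zip(truth.transcripts["transcript_id"], truth.transcripts["has_hse"]))
        for tid, seq in promoters.items():
            if planted[tid]:
                hits = scan_hse(seq)
                # the exact planted double may be absorbed into a spurious triple
                assert any(
                    (h.kind == "canonical_double" and h.n_mismatches == 0)
                    or h.kind == "canonical_triple"
                    for h in hits
                )
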