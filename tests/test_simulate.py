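"""Synthetic-data generators: determinism, boundary limits, hidden truth."""

import numpy as np
import pytest

from xenopurity.mle import GenotypeClass
from xenopurity.scoring import estimate_scores, hybridize_expression
from xenopurity.simulate import (
    SimConfig,
    gen_expression_cohort,
    gen_score_purity_reference,
    gen_segment_counts,
    gen_syngeneic_sites,
    gen_variant_table,
    make_synthetic_signature,
)
from xenopurity.variants import VariantLabel


class TestSimConfig:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(theta_true=1.2)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sites=0)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(depth_mean=-1)


class TestSyngeneicSites:
    def test_identical_seed_identical_output(self):
        a, _ = gen_syngeneic_sites(SimConfig(seed=42))
        b, _ = gen_syngeneic_sites(SimConfig(seed=42))
        assert a == b

    def test_different_seed_different_output(self):
        a, _ = gen_syngeneic_sites(SimConfig(seed=1))
        b, _ = gen_syngeneic_sites(SimConfig(seed=2))
        assert a != b

    def test_pure_tumor_limit(self):
        sites, _ = gen_syngeneic_sites(SimConfig(seed=0, theta_true=1.0, het_fraction=0.0))
        assert all(s.n_H == 0 for s in sites)

    def test_pure_stroma_limit(self):
        sites, _ = gen_syngeneic_sites(SimConfig(seed=0, theta_true=0.0))
        assert all(s.n_T == 0 for s in sites)

    def test_pooled_fraction_approaches_theta(self):
        cfg = SimConfig(seed=8, theta_true=0.8, het_fraction=0.0, n_sites=10_000, depth_mean=50)
        sites, _ = gen_syngeneic_sites(cfg)
        pooled = sum(s.n_T for s in sites) / sum(s.depth for s in sites)
        assert pooled == pytest.approx(0.8, abs=0.01)

    def test_het_fraction_controls_genotype_mix(self):
        sites, _ = gen_syngeneic_sites(SimConfig(seed=3, het_fraction=1.0))
        assert all(s.genotype_class is GenotypeClass.HET_HT for s in sites)

    def test_counts_non_negative(self):
        sites, _ = gen_syngeneic_sites(SimConfig(seed=4, depth_dispersion=0.5))
        assert all(s.n_H >= 0 and s.n_T >= 0 for s in sites)


class TestSegmentCounts:
    def test_symmetric_fraction(self):
        segments, _ = gen_segment_counts(SimConfig(seed=0, theta_true=0.5))
        fractions = sorted(s.reads_human / s.depth for s in segments)
        median = fractions[len(fractions) // 2]
        assert median == pytest.approx(0.5, abs=0.02)

    def test_single_segment_identity(self):
        segments, f = gen_segment_counts(SimConfig(seed=1, n_segments=1, theta_true=0.9))
        assert len(segments) == 1
        assert segments[0].reads_human / segments[0].depth == pytest.approx(f, abs=0.02)

    def test_depth_conserved(self):
        cfg = SimConfig(seed=2, segment_depth=3000)
        segments, _ = gen_segment_counts(cfg)
        assert all(s.depth == 3000 for s in segments)

    def test_bias_multiplier_distorts_fractions(self):
        clean, _ = gen_segment_counts(SimConfig(seed=5, theta_true=0.7))
        biased, _ = gen_segment_counts(SimConfig(seed=5, theta_true=0.7), bias_sd=0.5)
        spread = lambda segs: np.std([s.reads_human / s.depth for s in segs])  # noqa: E731
        assert spread(biased) > spread(clean)


class TestExpressionCohort:
    def test_pure_tumor_leaves_mouse_signature_at_baseline(self, signature):
        cfg = SimConfig(seed=0, n_samples=3, noise_sd=0.0)
        _, mouse, _ = gen_expression_cohort(cfg, signature, purities=np.array([1.0, 1.0, 1.0]))
        sig_mouse = sorted(signature.mouse_genes(signature.stromal_genes))
        assert (mouse.loc[sig_mouse] <= 6.0 + 1e-9).all().all()  # baseline only

    def test_noise_free_monotonicity(self, signature):
        cfg = SimConfig(seed=1, n_samples=2, noise_sd=0.0)
        _, mouse, _ = gen_expression_cohort(cfg, signature, purities=np.array([0.9, 0.5]))
        sig_mouse = sorted(signature.mouse_genes(signature.stromal_genes))
        low, high = mouse.columns
        assert (mouse.loc[sig_mouse, high] > mouse.loc[sig_mouse, low]).all()

    def test_hybrid_score_negatively_tracks_purity(self, signature):
        cfg = SimConfig(seed=2, n_samples=50, noise_sd=0.2)
        human, mouse, purities = gen_expression_cohort(cfg, signature)
        hybrid = hybridize_expression(human, mouse, signature.ortholog_map)
        scores = estimate_scores(hybrid, signature, version="hybrid")
        from scipy.stats import spearmanr

        rho = spearmanr(scores["estimate_score"], purities).statistic
        assert rho < -0.8

    def test_species_tagged_identifiers(self, signature):
        human, mouse, _ = gen_expression_cohort(SimConfig(seed=3, n_samples=2), signature)
        assert not any(g.startswith("mm-") for g in human.index)
        assert all(g.startswith("mm-") for g in mouse.index)

    def test_values_non_negative_and_deterministic(self, signature):
        cfg = SimConfig(seed=4, n_samples=4)
        h1, m1, p1 = gen_expression_cohort(cfg, signature)
        h2, m2, p2 = gen_expression_cohort(cfg, signature)
        assert (h1.values >= 0).all() and (m1.values >= 0).all()
        assert h1.equals(h2) and m1.equals(m2) and np.array_equal(p1, p2)


class TestVariantTable:
    def test_all_germline_table(self):
        records = gen_variant_table(SimConfig(seed=0, n_sites=200), germline_fraction=1.0)
        assert all(v.label is VariantLabel.GERMLINE for v in records)

    def test_all_somatic_clonal_median_near_half(self):
        import statistics

        records = gen_variant_table(
            SimConfig(seed=1, n_sites=500), germline_fraction=0.0, ensure_separable=False
        )
        med = statistics.median(v.vaf for v in records)
        assert med == pytest.approx(0.5, abs=0.02)

    def test_hidden_labels_stored_for_confusion_matrix(self):
        records = gen_variant_table(SimConfig(seed=2, n_sites=100))
        assert all(v.label in (VariantLabel.GERMLINE, VariantLabel.SOMATIC) for v in records)

    def test_determinism(self):
        a = gen_variant_table(SimConfig(seed=3, n_sites=50))
        b = gen_variant_table(SimConfig(seed=3, n_sites=50))
        assert a == b


class TestScorePurityReference:
    def test_noise_free_pairs_follow_generator(self):
        ref, g = gen_score_purity_reference(SimConfig(seed=0, n_samples=40), noise_sd=0.0)
        assert np.allclose(ref.purities, g(ref.scores))

    def test_generator_is_monotone_decreasing(self):
        ref, g = gen_score_purity_reference(SimConfig(seed=1, n_samples=40), noise_sd=0.0)
        dense = np.linspace(ref.scores.min(), ref.scores.max(), 500)
        assert np.all(np.diff(g(dense)) <= 1e-12)

    def test_purities_clamped_to_unit_interval(self):
        ref, _ = gen_score_purity_reference(SimConfig(seed=2, n_samples=40), noise_sd=0.3)
        assert np.all((ref.purities >= 0) & (ref.purities <= 1))

    def test_minimum_pair_count_enforced(self):
        with pytest.raises(ValueError):
            gen_score_purity_reference(SimConfig(seed=0, n_samples=10))


class TestSignatureFactory:
    def test_mirror_of_real_signature_geometry(self):
        sig = make_synthetic_signature()
        assert len(sig.stromal_genes) == 141
        assert len(sig.immune_genes) == 141
        mapped_stromal = [g for g in sig.stromal_genes if g in sig.ortholog_map]
        mapped_immune = [g for g in sig.immune_genes if g in sig.ortholog_map]
        assert len(mapped_stromal) == 130
        assert len(mapped_immune) == 141
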