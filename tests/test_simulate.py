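"""Synthetic-data generators: determinism, labeled structure, calibration."""

import dataclasses
import math

import numpy as np
import pytest

from ctdnakit import (
    AmpliconSimConfig,
    CohortSimConfig,
    KineticsSimConfig,
    LadderSimConfig,
    expected_base_proportions,
    simulate_amplicon_counts,
    simulate_fragment_profile,
    simulate_kinetics_cohort,
    simulate_variant_cohort,
    wilcoxon_signed_rank,
)


class TestDeterminism:
    def test_cohort_reproducible(self):
        cfg = CohortSimConfig(seed=11)
        a = simulate_variant_cohort(cfg)
        b = simulate_variant_cohort(cfg)
        assert a.calls == b.calls
        assert a.truth.equals(b.truth)

    def test_amplicon_reproducible(self):
        cfg = AmpliconSimConfig(seed=11)
        assert simulate_amplicon_counts(cfg) == simulate_amplicon_counts(cfg)

    def test_profile_reproducible(self):
        cfg = LadderSimConfig(noise_sd=0.1, seed=11)
        a = simulate_fragment_profile(cfg)
        b = simulate_fragment_profile(cfg)
        assert np.array_equal(a.mass_signal, b.mass_signal)

    def test_kinetics_reproducible(self):
        cfg = KineticsSimConfig(seed=11)
        assert simulate_kinetics_cohort(cfg) == simulate_kinetics_cohort(cfg)


class TestVariantCohort:
    def test_pure_germline_when_other_rates_zero(self):
        cfg = CohortSimConfig(germline_rate=0.8, somatic_rate=0.0, artifact_rate=0.0, seed=1)
        cohort = simulate_variant_cohort(cfg)
        assert set(cohort.truth["true_class"]) == {"germline"}

    def test_artifact_sites_shared_by_minimum_fraction(self):
        cfg = CohortSimConfig(
            n_samples=6, n_sites=300, germline_rate=0.0, somatic_rate=0.0,
            artifact_rate=0.3, artifact_sample_fraction=0.5, seed=2,
        )
        cohort = simulate_variant_cohort(cfg)
        per_site = cohort.truth.groupby("pos")["sample_id"].nunique()
        assert len(per_site) > 0
        assert (per_site >= 3).all()

    def test_somatic_sites_private_with_low_aaf(self):
        cfg = CohortSimConfig(
            germline_rate=0.0, somatic_rate=0.5, artifact_rate=0.0,
            somatic_aaf_range=(0.05, 0.30), seed=3,
        )
        cohort = simulate_variant_cohort(cfg)
        per_site = cohort.truth.groupby("pos")["sample_id"].nunique()
        assert (per_site == 1).all()
        for calls in cohort.calls.values():
            for c in calls:
                assert 0.05 <= c.aaf <= 0.30
                assert c.pop_maf is None or c.pop_maf < 0.01

    def test_single_sample_config_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            CohortSimConfig(n_samples=1)


class TestAmpliconCounts:
    def test_no_mutant_source_means_zero_mutant_reads(self):
        cfg = AmpliconSimConfig(ctdna_fraction_pre=0.0, error_rate=0.0, seed=5)
        pair = simulate_amplicon_counts(cfg)
        assert pair.pre.base_counts[cfg.mutant_base] == 0

    def test_totals_equal_depths(self):
        cfg = AmpliconSimConfig(depth_pre=1234, depth_post=4321, seed=5)
        pair = simulate_amplicon_counts(cfg)
        assert pair.pre.total == 1234
        assert sum(pair.pre.base_counts.values()) == 1234
        assert pair.post.total == 4321

    def test_high_depth_proportion_within_binomial_se(self):
        cfg = AmpliconSimConfig(
            ctdna_fraction_pre=0.0, ctdna_fraction_post=0.01, tissue_aaf=0.5,
            error_rate=0.0, depth_post=10**6, seed=6,
        )
        pair = simulate_amplicon_counts(cfg)
        p = 0.005
        se = math.sqrt(p * (1 - p) / 10**6)
        observed = pair.post.base_counts["T"] / pair.post.total
        assert abs(observed - p) < 3 * se

    def test_mean_proportion_unbiased_over_replicates(self):
        """Monte-Carlo mean of the mutant proportion is within 3 SE of the
        closed-form expectation at depth 1e5 over 1000 replicates."""
        cfg = AmpliconSimConfig(
            ctdna_fraction_post=0.04, tissue_aaf=0.5, error_rate=1e-3, depth_post=10**5
        )
        expected = expected_base_proportions(0.02, 1e-3, "T", "C")["T"]
        props = []
        for seed in range(1000):
            pair = simulate_amplicon_counts(dataclasses.replace(cfg, seed=seed))
            props.append(pair.post.base_counts["T"] / pair.post.total)
        props = np.asarray(props)
        se_mc = props.std(ddof=1) / math.sqrt(len(props))
        assert abs(props.mean() - expected) < 3 * se_mc

    def test_expected_proportions_sum_to_one(self):
        props = expected_base_proportions(0.2, 0.01, "G", "A")
        assert sum(props.values()) == pytest.approx(1.0)
        assert props["G"] == pytest.approx(0.2 * 0.99 + 0.8 * 0.01 / 3)


class TestFragmentProfileSim:
    def test_all_zero_amounts_give_flat_trace(self):
        cfg = LadderSimConfig(molar_amounts=(0.0, 0.0, 0.0, 0.0), noise_sd=0.0)
        profile = simulate_fragment_profile(cfg)
        assert np.all(profile.mass_signal == 0.0)

    def test_component_mass_integrates_to_molar_times_length(self):
        cfg = LadderSimConfig(
            peak_orders=(1,), peak_centers=(165.0,), peak_widths=(12.0,),
            molar_amounts=(0.7,), noise_sd=0.0,
        )
        profile = simulate_fragment_profile(cfg)
        mass = np.trapezoid(profile.mass_signal, profile.sizes)
        assert mass == pytest.approx(0.7 * 165.0, rel=1e-6)

    def test_grid_must_cover_peaks(self):
        cfg = LadderSimConfig(size_grid=(25.0, 500.0, 5.0))
        with pytest.raises(ValueError, match="cover"):
            simulate_fragment_profile(cfg)


class TestKinetics:
    def test_zero_release_returns_baseline_everywhere(self):
        cfg = KineticsSimConfig(release_scale=0.0, noise_cv=0.0, seed=4)
        by_patient = {}
        for rec in simulate_kinetics_cohort(cfg):
            by_patient.setdefault(rec.patient_id, set()).add(rec.concentration)
        for values in by_patient.values():
            assert len(values) == 1

    def test_noise_free_course_non_decreasing(self):
        cfg = KineticsSimConfig(noise_cv=0.0, seed=4)
        courses = {}
        for rec in simulate_kinetics_cohort(cfg):
            courses.setdefault(rec.patient_id, []).append((rec.timepoint, rec.concentration))
        for course in courses.values():
            concs = [c for _, c in sorted(course)]
            assert all(b >= a - 1e-12 for a, b in zip(concs, concs[1:]))

    def test_concentrations_strictly_positive(self):
        cfg = KineticsSimConfig(noise_cv=0.5, n_patients=20, seed=5)
        assert all(r.concentration > 0 for r in simulate_kinetics_cohort(cfg))

    def test_default_release_powers_paired_test_at_two_hours(self):
        """With study-default release, the pre vs 120 min Wilcoxon detects the
        increase (p < 0.05) in at least 90% of 200 seeded replicates at n=19."""
        hits = 0
        for seed in range(200):
            cfg = KineticsSimConfig(n_patients=19, seed=seed)
            records = simulate_kinetics_cohort(cfg)
            pre = [r.concentration for r in records if r.timepoint == 0]
            post = [r.concentration for r in records if r.timepoint == 120]
            _, p = wilcoxon_signed_rank(pre, post)
            hits += p < 0.05
        assert hits >= 180


class TestConfigValidation:
    @pytest.mark.parametrize(
        "cfg_call",
        [
            lambda: CohortSimConfig(somatic_aaf_range=(0.1, 0.7)),
            lambda: CohortSimConfig(germline_rate=0.8, somatic_rate=0.3),
            lambda: AmpliconSimConfig(error_rate=0.2),
            lambda: AmpliconSimConfig(depth_pre=0),
            lambda: LadderSimConfig(peak_centers=(200.0, 180.0, 630.0, 870.0)),
            lambda: LadderSimConfig(peak_widths=(0.0, 1.0, 1.0, 1.0)),
            lambda: KineticsSimConfig(timepoints=(10, 0, 30)),
            lambda: KineticsSimConfig(noise_cv=-0.1),
        ],
    )
    def test_invalid_configs_rejected(self, cfg_call):
        with pytest.raises(ValueError):
            cfg_call()
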