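import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from episcore.io import ValidationError
from episcore.reference import inverse_logit, logit
from episcore.synthetic import (
    CohortSpec,
    DiseaseSpec,
    GroundTruthProbeModel,
    apply_effect,
    default_cohort_spec,
    generate_cohort,
    sample_demographics,
    simulate_probe_values,
)


class TestDemographics:
    def test_sex_balance_large_n(self):
        demo = sample_demographics(100_000, seed=0)
        p_male = np.mean([d[1] == "M" for d in demo])
        assert abs(p_male - 0.5) < 0.005

    def test_age_mean_large_n(self):
        demo = sample_demographics(100_000, seed=0)
        mean_years = np.mean([d[0] for d in demo]) / 365.25
        assert abs(mean_years - 42.5) < 1.0

    def test_determinism(self):
        assert sample_demographics(1, seed=42) == sample_demographics(1, seed=42)

    def test_invalid_n(self):
        with pytest.raises(ValidationError):
            sample_demographics(0, seed=0)


class TestSimulateProbeValues:
    def test_degenerate_sigma_concentrates_at_mean(self, rng):
        model = GroundTruthProbeModel(mu0=1.2, sigma0=1e-7)
        demo = sample_demographics(100, rng)
        values = simulate_probe_values(model, demo, rng)
        np.testing.assert_allclose(values, inverse_logit(1.2), atol=1e-5)

    def test_logit_normal_median(self):
        model = GroundTruthProbeModel(mu0=0.0, sigma0=1.0)
        rng = np.random.default_rng(1)
        demo = sample_demographics(100_000, rng)
        values = simulate_probe_values(model, demo, rng)
        assert abs(np.median(values) - 0.5) < 0.01

    def test_determinism(self):
        model = GroundTruthProbeModel(mu0=0.5, sigma0=0.4)
        demo = sample_demographics(10, seed=5)
        a = simulate_probe_values(model, demo, np.random.default_rng(9))
        b = simulate_probe_values(model, demo, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_marginal_moments_match_ground_truth(self):
        """Logit-scale mean/SD at fixed age and sex recover mu and sigma."""
        model = GroundTruthProbeModel(mu0=-0.5, age_coef=0.3, sex_offset=0.6, sigma0=0.4)
        rng = np.random.default_rng(2)
        n = 10_000
        demo = [(3650, "M")] * n
        x = logit(simulate_probe_values(model, demo, rng))
        true_mu = model.mu(3650, 1.0)
        assert abs(np.mean(x) - true_mu) < 3 * 0.4 / np.sqrt(n)
        assert abs(np.std(x, ddof=1) - 0.4) < 3 * 0.4 / np.sqrt(2 * n)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValidationError):
            GroundTruthProbeModel(mu0=0.0, sigma0=0.0)


class TestApplyEffect:
    def test_hyper_effect(self):
        assert apply_effect(0.5, 0.3, "hyper") == pytest.approx(0.8)

    def test_hyper_clipped(self):
        assert apply_effect(0.9, 0.3, "hyper", epsilon=1e-6) == 1 - 1e-6

    def test_hypo_effect(self):
        assert apply_effect(0.4, 0.3, "hypo") == pytest.approx(0.1)

    @given(
        beta=st.floats(0.01, 0.99),
        delta=st.floats(0.001, 0.5),
    )
    def test_effect_conservation_without_clipping(self, beta, delta):
        """hyper then hypo of equal delta is the identity away from the bounds."""
        up = apply_effect(beta, delta, "hyper")
        if up < 1 - 1e-6:  # no clipping occurred
            back = apply_effect(up, delta, "hypo")
            assert back == pytest.approx(beta, abs=1e-12)


class TestGenerateCohort:
    def test_normals_only(self):
        spec = default_cohort_spec(n_normal=20, n_per_disorder=0, n_probes=60, seed=0)
        spec.n_per_class = {"Normal": 20}
        beta, samples = generate_cohort(spec)
        assert beta.shape == (60, 20)
        assert all(s.class_label == "Normal" for s in samples)

    def test_regional_effect_shifts_mean(self):
        """Affected-region probes in affected samples shift by about delta."""
        spec = default_cohort_spec(n_normal=200, n_per_disorder=0, n_probes=60, seed=3)
        spec.n_per_class = {"Normal": 200, "PWS2": 60}
        beta, samples = generate_cohort(spec)
        region = spec.regions["MAGEL2"]  # PWS2: hyper +0.3
        rows = beta.probe_indices(region)
        pws = [i for i, s in enumerate(samples) if s.class_label == "PWS2"]
        nor = [i for i, s in enumerate(samples) if s.class_label == "Normal"]
        shifts = beta.values[np.ix_(rows, pws)].mean(axis=1) - beta.values[
            np.ix_(rows, nor)
        ].mean(axis=1)
        # clipping at the upper bound can only reduce the mean shift
        assert np.all(shifts > 0.1)
        assert np.all(shifts < 0.3 + 0.1)

    def test_global_class_heterogeneity(self):
        """Diffuse SRS-like samples perturb different probe subsets."""
        spec = default_cohort_spec(n_normal=10, n_per_disorder=0, n_probes=200, seed=4)
        spec.n_per_class = {"Normal": 10, "SRS1": 6}
        beta, samples = generate_cohort(spec)
        spec2 = default_cohort_spec(n_normal=10, n_per_disorder=0, n_probes=200, seed=4)
        spec2.n_per_class = {"Normal": 10, "SRS1": 6}
        beta_clean, _ = generate_cohort(
            spec2.__class__(
                n_per_class=spec2.n_per_class,
                n_probes=spec2.n_probes,
                regions=spec2.regions,
                probe_models=spec2.probe_models,
                disease_specs=[],
                seed=spec2.seed,
            )
        )
        srs = [i for i, s in enumerate(samples) if s.class_label == "SRS1"]
        affected_sets = []
        for j in srs:
            affected = np.where(beta.values[:, j] != beta_clean.values[:, j])[0]
            affected_sets.append(frozenset(affected.tolist()))
            assert 10 <= len(affected) <= 20 + 5  # ~10% of 200 probes
        assert len(set(affected_sets)) > 1

    def test_determinism_bit_identical(self):
        a, ra = generate_cohort(default_cohort_spec(n_normal=15, n_per_disorder=3, n_probes=80, seed=9))
        b, rb = generate_cohort(default_cohort_spec(n_normal=15, n_per_disorder=3, n_probes=80, seed=9))
        assert ra == rb
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_region_rejected(self):
        spec = default_cohort_spec(n_normal=5, n_per_disorder=2, n_probes=80, seed=0)
        with pytest.raises(ValidationError):
            CohortSpec(
                n_per_class={"Normal": 5},
                n_probes=spec.n_probes,
                regions=spec.regions,
                probe_models=spec.probe_models,
                disease_specs=[DiseaseSpec("BWS1", "NOPE", "hyper", 0.3)],
                seed=0,
            )
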