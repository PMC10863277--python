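import math

import numpy as np
import pytest

from episcore.io import ValidationError
from episcore.reference import (
    ReferenceModel,
    build_age_grid,
    compute_global_stats,
    fit_probe_model,
    fit_reference_model,
    inverse_logit,
    logit,
    lookup,
    nearest_grid_index,
)
from episcore.scoring import compute_z_panel
from episcore.synthetic import (
    GroundTruthProbeModel,
    sample_demographics,
    simulate_probe_values,
)


def _simulate_fit(gt, n, seed, settings=None):
    rng = np.random.default_rng(seed)
    demo = sample_demographics(n, rng)
    x = logit(simulate_probe_values(gt, demo, rng))
    return fit_probe_model(
        x, [d[0] for d in demo], [d[1] for d in demo], settings=settings
    )


class TestLogit:
    def test_symmetry_point(self):
        assert logit(0.5) == 0.0

    def test_closed_form(self):
        assert logit(0.73) == pytest.approx(math.log(0.73 / 0.27), rel=1e-12)
        assert logit(0.73) == pytest.approx(0.9946, abs=1e-4)

    @pytest.mark.parametrize("x", [-5.0, 0.0, 5.0])
    def test_inverse_identity(self, x):
        assert logit(inverse_logit(x)) == pytest.approx(x, rel=1e-10)

    def test_boundary_rejected(self):
        with pytest.raises(ValidationError):
            logit(0.0)


class TestAgeGrid:
    def test_construction(self):
        grid = build_age_grid()
        assert len(grid) == 461
        assert grid[0] == 0
        assert grid[-1] == round(85 * 365.25)
        assert np.all(np.diff(grid) > 0)

    def test_nearest_lookup_prefers_younger_on_tie(self):
        grid = np.array([0, 10, 20])
        assert nearest_grid_index(grid, 15)[0] == 1  # equidistant -> younger
        assert nearest_grid_index(grid, 16)[0] == 2
        assert nearest_grid_index(grid, 10)[0] == 1

    def test_day_366_maps_to_day_365(self):
        grid = build_age_grid()
        idx = nearest_grid_index(grid, 366)[0]
        assert grid[idx] == 365


class TestGlobalStats:
    def test_hand_computation(self):
        gs = compute_global_stats([-1.0, 1.0])
        assert gs.global_mu == 0.0
        assert gs.global_sigma == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_degenerate_flag(self):
        gs = compute_global_stats([2.0, 2.0, 2.0])
        assert gs.degenerate

    def test_simulation_recovery(self, rng):
        x = rng.normal(2.0, 0.5, size=100_000)
        gs = compute_global_stats(x)
        se_mu = 0.5 / math.sqrt(len(x))
        assert abs(gs.global_mu - 2.0) < 3 * se_mu
        assert abs(gs.global_sigma - 0.5) < 3 * 0.5 / math.sqrt(2 * len(x))


class TestProbeFit:
    def test_no_effect_limit_matches_global(self):
        gt = GroundTruthProbeModel(mu0=0.8, age_coef=0.0, sex_offset=0.0, sigma0=0.4)
        m = _simulate_fit(gt, 400, seed=1)
        se = 0.4 / math.sqrt(400)
        # constant truth: predictions everywhere close to mu0 and to globalMu
        assert np.abs(m.mu - gt.mu0).mean() < 0.1
        assert np.abs(m.mu - gt.mu0).max() < 0.25
        assert abs(m.global_stats.global_mu - gt.mu0) < 3 * se

    def test_parameter_recovery_n500(self):
        """Median max-grid mu error over replicates stays below 0.1."""
        gt = GroundTruthProbeModel(mu0=1.0, age_coef=0.4, sex_offset=0.5, sigma0=0.3)
        errs = []
        for seed in range(5):
            m = _simulate_fit(gt, 500, seed=seed)
            t = np.log1p(m.age_grid / 365.25)
            errs.append(
                max(
                    np.abs(m.mu[:, s] - (gt.mu0 + gt.age_coef * t + gt.sex_offset * s)).max()
                    for s in (0, 1)
                )
            )
        assert np.median(errs) < 0.1

    def test_small_cohort_falls_back_to_global(self):
        gt = GroundTruthProbeModel(mu0=0.0, sigma0=0.5)
        m = _simulate_fit(gt, 5, seed=2)
        assert m.diagnostics.fallback
        assert np.all(m.mu == m.global_stats.global_mu)
        assert np.all(m.sigma == m.global_stats.global_sigma)

    def test_single_sex_falls_back(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 50)
        m = fit_probe_model(x, rng.integers(0, 30000, 50), ["F"] * 50)
        assert m.diagnostics.fallback

    def test_lookup_on_and_off_grid(self):
        gt = GroundTruthProbeModel(mu0=0.5, age_coef=0.3, sigma0=0.3)
        m = _simulate_fit(gt, 200, seed=4)
        idx = 100
        age = int(m.age_grid[idx])
        mu, sigma = lookup(m, age, "F")
        assert mu == m.mu[idx, 0] and sigma == m.sigma[idx, 0]
        mu_m, _ = lookup(m, age, "M")
        assert mu_m == m.mu[idx, 1]

    def test_sigma_positive_everywhere(self):
        gt = GroundTruthProbeModel(mu0=-1.0, age_coef=0.2, sigma0=0.25)
        m = _simulate_fit(gt, 150, seed=5)
        assert np.all(m.sigma > 0)

    def test_monotone_information(self):
        """Recovery error does not get worse with more controls (on average)."""
        gt = GroundTruthProbeModel(mu0=1.0, age_coef=0.4, sex_offset=0.5, sigma0=0.3)
        mean_err = {}
        for n in (50, 200, 1000):
            errs = []
            for rep in range(20):
                m = _simulate_fit(gt, n, seed=1000 * n + rep)
                t = np.log1p(m.age_grid / 365.25)
                errs.append(
                    max(
                        np.abs(
                            m.mu[:, s] - (gt.mu0 + gt.age_coef * t + gt.sex_offset * s)
                        ).max()
                        for s in (0, 1)
                    )
                )
            mean_err[n] = np.mean(errs)
        # allow small Monte-Carlo slack on each step of the ordering
        assert mean_err[200] <= mean_err[50] + 0.02
        assert mean_err[1000] <= mean_err[200] + 0.02


class TestNoEffectEquivalence:
    def test_adjusted_close_to_unadjusted_without_demographic_effects(self):
        """With no age/sex structure the adjusted and unadjusted z-scores agree."""
        from episcore.scoring import z_adjusted, z_unadjusted

        gt = GroundTruthProbeModel(mu0=0.5, age_coef=0.0, sex_offset=0.0, sigma0=0.5)
        replicate_means = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            demo = sample_demographics(200, rng)
            x = logit(simulate_probe_values(gt, demo, rng))
            m = fit_probe_model(x, [d[0] for d in demo], [d[1] for d in demo])
            diffs = [
                abs(z_adjusted(xi, *lookup(m, age, sex)) - z_unadjusted(xi, m.global_stats))
                for xi, (age, sex) in zip(x, demo)
            ]
            replicate_means.append(np.mean(diffs))
        assert np.mean(replicate_means) < 0.15


class TestSerialization:
    def test_save_load_bit_exact(self, tmp_path, small_cohort):
        spec, beta, samples = small_cohort
        sub = beta.probe_ids[:4]
        idx = beta.probe_indices(sub)
        from episcore.io import BetaMatrix

        small = BetaMatrix(sub, beta.sample_ids, beta.values[idx], validate=False)
        model = fit_reference_model(small, samples)
        model.save(tmp_path / "ref.tsv", tmp_path / "ref.json")
        loaded = ReferenceModel.load(tmp_path / "ref.tsv", tmp_path / "ref.json")
        assert loaded.probe_ids == model.probe_ids
        np.testing.assert_array_equal(loaded.mu, model.mu)
        np.testing.assert_array_equal(loaded.sigma, model.sigma)
        np.testing.assert_array_equal(loaded.global_mu, model.global_mu)
        # scoring through the reloaded model is bit-identical
        panel_a = compute_z_panel(small, samples, model)
        panel_b = compute_z_panel(small, samples, loaded)
        np.testing.assert_array_equal(panel_a.z_adjusted, panel_b.z_adjusted)
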