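import numpy as np
import pandas as pd
import pytest

from episcore.features import (
    assemble_features,
    build_features,
    extract_target_features,
    filter_probes_by_z,
    prune_correlated,
    split_train_test,
    umap_global_features,
)
from episcore.io import PipelineConfig, RegionSet, SampleRecord, ValidationError
from episcore.scoring import ZScorePanel


def _panel(z_adj: np.ndarray, probe_ids=None, sample_ids=None) -> ZScorePanel:
    P, S = z_adj.shape
    return ZScorePanel(
        probe_ids=probe_ids or [f"cg{i}" for i in range(P)],
        sample_ids=sample_ids or [f"S{j}" for j in range(S)],
        z_unadjusted=np.zeros_like(z_adj),
        z_adjusted=z_adj,
        z_regularized=z_adj / 2,
    )


def _records(counts: dict[str, int]) -> list[SampleRecord]:
    records = []
    for label, n in counts.items():
        for i in range(n):
            records.append(SampleRecord(f"{label}{i}", 1000 + i, "F", label))
    return records


class TestSplit:
    def test_exact_stratification(self):
        samples = _records({"Normal": 10, "PWS1": 10})
        out = split_train_test(samples, 0.8, seed=0)
        for label in ("Normal", "PWS1"):
            n_train = sum(1 for s in out if s.class_label == label and s.split == "train")
            assert n_train == 8

    def test_rounding_class_of_nine(self):
        samples = _records({"Normal": 9, "FXS": 2})
        out = split_train_test(samples, 0.8, seed=1)
        n_train = sum(1 for s in out if s.class_label == "Normal" and s.split == "train")
        assert n_train == 7  # round(0.8 * 9)

    def test_determinism(self):
        samples = _records({"Normal": 12, "AS2": 5})
        a = split_train_test(samples, 0.8, seed=3)
        b = split_train_test(samples, 0.8, seed=3)
        assert a == b

    def test_singleton_class_rejected(self):
        with pytest.raises(ValidationError):
            split_train_test(_records({"Normal": 5, "FXS": 1}), 0.8, seed=0)


class TestZFilter:
    def test_brute_force_oracle(self, rng):
        z = rng.normal(0, 2, size=(10, 8))
        panel = _panel(z)
        got = filter_probes_by_z(panel, threshold=3.0, min_samples=1)
        expected = [
            panel.probe_ids[i]
            for i in range(10)
            if sum(abs(z[i, j]) >= 3.0 for j in range(8)) >= 1
        ]
        assert got == expected

    def test_all_below_threshold_removed(self):
        panel = _panel(np.full((3, 4), 2.9))
        assert filter_probes_by_z(panel) == []

    def test_single_hit_kept(self):
        z = np.zeros((2, 3))
        z[1, 0] = 3.2
        panel = _panel(z)
        assert filter_probes_by_z(panel, min_samples=1) == ["cg1"]


class TestTargetFeatures:
    def test_dedup_across_regions(self):
        z = np.full((5, 3), 5.0)
        panel = _panel(z)
        regions = RegionSet({"A": ["cg0", "cg1", "cg2"], "B": ["cg2", "cg3", "cg4"]})
        out = extract_target_features(panel, regions, panel.probe_ids)
        assert list(out.columns) == ["cg0", "cg1", "cg2", "cg3", "cg4"]

    def test_failed_filter_probe_excluded(self):
        z = np.full((3, 2), 5.0)
        panel = _panel(z)
        regions = RegionSet({"A": ["cg0", "cg1", "cg2"]})
        out = extract_target_features(panel, regions, ["cg0", "cg2"])
        assert list(out.columns) == ["cg0", "cg2"]

    def test_no_survivors_rejected(self):
        panel = _panel(np.zeros((3, 2)))
        regions = RegionSet({"A": ["cg0"]})
        with pytest.raises(ValidationError):
            extract_target_features(panel, regions, [])


class TestUmap:
    def test_cluster_separation_and_dims(self, rng):
        # three well-separated blobs in 20-d probe space
        centers = np.array([[-8.0], [0.0], [8.0]])
        z = np.repeat(centers, 15, axis=0).T + rng.normal(0, 0.5, size=(1, 45))
        z = np.repeat(z, 20, axis=0) + rng.normal(0, 0.3, size=(20, 45))
        panel = _panel(z)
        emb, reducer = umap_global_features(panel, panel.probe_ids, n_dims=2, seed=0)
        assert emb.shape == (45, 2)
        from sklearn.metrics import silhouette_score

        labels = np.repeat([0, 1, 2], 15)
        assert silhouette_score(emb.to_numpy(), labels) > 0.5

    def test_transform_self_consistency(self, rng):
        from episcore.features import transform_umap

        z = rng.normal(0, 1, size=(30, 40))
        panel = _panel(z)
        emb, reducer = umap_global_features(panel, panel.probe_ids, n_dims=2, seed=1)
        proj = transform_umap(reducer, panel, panel.probe_ids)
        spread = np.linalg.norm(emb.to_numpy().std(axis=0))
        err = np.linalg.norm(proj.to_numpy() - emb.to_numpy(), axis=1).mean()
        assert err < spread  # projected points land near their embedded positions

    def test_too_few_samples_rejected(self, rng):
        panel = _panel(rng.normal(size=(10, 5)))
        with pytest.raises(ValidationError, match="umap_dims"):
            umap_global_features(panel, panel.probe_ids, n_dims=10, seed=0)


class TestPruning:
    def test_duplicate_removed(self, rng):
        a = rng.normal(size=100)
        df = pd.DataFrame({"A": a, "B": a.copy(), "C": rng.normal(size=100)})
        kept = prune_correlated(df, 0.9)
        assert "C" in kept and len(kept) == 2

    def test_brute_force_no_admissible_pair_remains(self, rng):
        base = rng.normal(size=(200, 3))
        df = pd.DataFrame(
            {
                "f1": base[:, 0],
                "f2": base[:, 0] + rng.normal(0, 0.1, 200),
                "f3": base[:, 1],
                "f4": base[:, 1] * -1 + rng.normal(0, 0.05, 200),
                "f5": base[:, 2],
                "f6": base[:, 0] + base[:, 1],
            }
        )
        kept = prune_correlated(df, 0.9)
        corr = df[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.9  # exhaustive scan of survivors
        assert kept == [c for c in df.columns if c in set(kept)]  # original order

    def test_cutoff_one_is_identity_without_perfect_pairs(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        assert prune_correlated(df, 1.0) == list("abcd")

    def test_constant_feature_removed_with_warning(self, rng):
        df = pd.DataFrame({"const": np.ones(50), "x": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            kept = prune_correlated(df, 0.9)
        assert kept == ["x"]


class TestAssemble:
    def test_148_column_composition(self, rng):
        target = pd.DataFrame(
            rng.normal(size=(10, 98)), columns=[f"cg{i}" for i in range(98)]
        )
        umap_cols = pd.DataFrame(
            rng.normal(size=(10, 50)), columns=[f"umap_{i+1}" for i in range(50)]
        )
        combined = assemble_features(target, umap_cols)
        assert combined.shape[1] == 148
        assert list(combined.columns[:98]) == list(target.columns)

    def test_name_collision_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 2)), columns=["x", "y"])
        with pytest.raises(ValidationError):
            assemble_features(df, df)


@pytest.fixture(scope="module")
def scored_cohort(small_cohort):
    from episcore.reference import fit_reference_model
    from episcore.scoring import compute_z_panel

    spec, beta, samples = small_cohort
    samples = split_train_test(samples, 0.8, seed=0)
    model = fit_reference_model(beta, samples)
    panel = compute_z_panel(beta, samples, model)
    return spec, panel, samples


class TestEndToEndFeatureBuild:
    def test_no_leakage(self, scored_cohort):
        """Corrupting the held-out samples' scores changes nothing fitted."""
        spec, panel, samples = scored_cohort
        config = PipelineConfig(seed=0, umap_dims=8)
        _, _, state_a = build_features(panel, samples, spec.regions, config)
        rng = np.random.default_rng(0)
        test_ids = {s.sample_id for s in samples if s.split == "test"}
        cols = [j for j, s in enumerate(panel.sample_ids) if s in test_ids]
        corrupted = ZScorePanel(
            panel.probe_ids,
            panel.sample_ids,
            panel.z_unadjusted.copy(),
            panel.z_adjusted.copy(),
            panel.z_regularized.copy(),
        )
        corrupted.z_adjusted[:, cols] = rng.normal(size=(len(panel.probe_ids), len(cols)))
        _, _, state_b = build_features(corrupted, samples, spec.regions, config)
        assert state_a.passing_probe_ids == state_b.passing_probe_ids
        assert state_a.target_probe_ids == state_b.target_probe_ids
        assert state_a.retained_feature_names == state_b.retained_feature_names
        np.testing.assert_array_equal(
            state_a.umap_reducer.embedding_, state_b.umap_reducer.embedding_
        )

    def test_determinism(self, scored_cohort):
        spec, panel, samples = scored_cohort
        config = PipelineConfig(seed=0, umap_dims=8)
        train_a, test_a, _ = build_features(panel, samples, spec.regions, config)
        train_b, test_b, _ = build_features(panel, samples, spec.regions, config)
        assert train_a.values.equals(train_b.values)
        assert test_a.values.equals(test_b.values)

    def test_train_test_columns_match(self, scored_cohort):
        spec, panel, samples = scored_cohort
        config = PipelineConfig(seed=0, umap_dims=8)
        train, test, state = build_features(panel, samples, spec.regions, config)
        assert train.feature_names == test.feature_names == state.retained_feature_names
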