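"""Classifier feature engineering: split, z-filter, target probes, UMAP, pruning.

The feature matrix combines (a) adjusted z-scores of the disease-locus
("target") probes that survive an outlier-frequency filter with (b) a UMAP
embedding of the remaining genome-wide z-score space into a fixed number of
global features (default 50).  With the published configuration — 98
surviving target probes and 50 UMAP dimensions — this yields 148 columns
before pruning.  Highly correlated columns (|Pearson r| > 0.9) are then
removed by the caret ``findCorrelation`` heuristic: repeatedly take the most
correlated remaining pair and drop the member with the larger mean absolute
correlation.

Everything is fitted on training samples only and applied to the test set as
a frozen transform, so test data never influence probe selection, the UMAP
embedding, or the pruning decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PipelineConfig, RegionSet, SampleRecord, ValidationError
from .scoring import ZScorePanel

__all__ = [
    "split_train_test",
    "filter_probes_by_z",
    "extract_target_features",
    "umap_global_features",
    "prune_correlated",
    "assemble_features",
    "FeatureMatrix",
    "FeatureSelectionState",
    "build_features",
]


def split_train_test(
    samples: Sequence[SampleRecord], fraction: float = 0.8, seed: int = 0
) -> list[SampleRecord]:
    """Stratified train/test assignment: per class, round(fraction * size) to train.

    Rounds half away from zero; remainder goes to test.  Returns new records
    with the ``split`` field set, preserving input order.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_class.setdefault(s.class_label, []).append(i)
    assignment = ["test"] * len(samples)
    for label in sorted(by_class):
        idx = by_class[label]
        if len(idx) < 2:
            raise ValidationError(
                f"class {label!r} has {len(idx)} sample(s); stratified split needs >= 2"
            )
        n_train = int(np.floor(fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        order = rng.permutation(len(idx))
        for k in order[:n_train]:
            assignment[idx[k]] = "train"
    return [
        SampleRecord(s.sample_id, s.age_days, s.sex, s.class_label, split)
        for s, split in zip(samples, assignment)
    ]


def filter_probes_by_z(
    panel: ZScorePanel, threshold: float = 3.0, min_samples: int = 1
) -> list[str]:
    """Probes whose |adjusted z| >= threshold in at least ``min_samples`` samples.

    Applied to the training panel only; probes that are never (or too rarely)
    differentially methylated carry no class signal and are dropped.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    if min_samples < 1:
        raise ValidationError("min_samples must be >= 1")
    hits = (np.abs(panel.z_adjusted) >= threshold).sum(axis=1)
    return [p for p, h in zip(panel.probe_ids, hits) if h >= min_samples]


def extract_target_features(
    panel: ZScorePanel, regions: RegionSet, passing_probe_ids: Sequence[str]
) -> pd.DataFrame:
    """Adjusted z-score columns for filter-surviving disease-locus probes.

    Probes shared between regions are de-duplicated, keeping first occurrence
    order.  Rows are samples, columns are probe ids.
    """
    if len(regions) == 0:
        raise ValidationError("regions must be non-empty")
    passing = set(passing_probe_ids)
    target_ids = [p for p in regions.all_probes() if p in passing]
    if not target_ids:
        raise ValidationError("no target-region probe survived the z filter")
    frame = panel.adjusted_frame()
    return frame.loc[target_ids].T


def umap_global_features(
    panel: ZScorePanel,
    probe_ids: Sequence[str],
    n_dims: int = 50,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
):
    """Fit a UMAP embedding of the non-target z-score space on training samples.

    Returns ``(embedding DataFrame with columns umap_1..umap_k, fitted reducer)``.
    The reducer's ``transform`` projects held-out samples through the frozen
    embedding.  Deterministic given ``seed`` (which forces single-threaded
    UMAP); random initialization is used because spectral initialization is
    unreliable when the embedding dimension approaches the sample count.
    """
    import umap  # deferred: numba-jitted import is slow

    probe_ids = list(probe_ids)
    n_samples = len(panel.sample_ids)
    if n_samples < n_dims + 2:
        raise ValidationError(
            f"{n_samples} samples cannot support a {n_dims}-dimensional embedding; "
            "reduce umap_dims"
        )
    frame = panel.adjusted_frame()
    X = frame.loc[probe_ids].T.to_numpy()
    reducer = umap.UMAP(
        n_components=n_dims,
        n_neighbors=min(n_neighbors, n_samples - 1),
        min_dist=min_dist,
        metric="euclidean",
        random_state=seed,
        init="random",
        transform_seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = reducer.fit_transform(X)
    cols = [f"umap_{i + 1}" for i in range(n_dims)]
    return pd.DataFrame(emb, index=panel.sample_ids, columns=cols), reducer


def transform_umap(reducer, panel: ZScorePanel, probe_ids: Sequence[str]) -> pd.DataFrame:
    """Project samples through a fitted UMAP reducer."""
    frame = panel.adjusted_frame()
    X = frame.loc[list(probe_ids)].T.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = reducer.transform(X)
    cols = [f"umap_{i + 1}" for i in range(emb.shape[1])]
    return pd.DataFrame(emb, index=panel.sample_ids, columns=cols)


def prune_correlated(features: pd.DataFrame, cutoff: float = 0.9) -> list[str]:
    """findCorrelation-style pruning: drop one member of each too-correlated pair.

    While any off-diagonal |Pearson r| > cutoff remains, take the largest such
    pair and remove the member whose mean absolute correlation with all other
    remaining features is larger (ties go to the later column); then
    recompute.  Zero-variance columns are removed first with a warning, since
    their correlations are undefined.  Survivors keep original column order.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValidationError("cutoff must be in (0, 1]")
    cols = list(features.columns)
    variances = features.var(axis=0, ddof=1)
    constant = [c for c in cols if not variances[c] > 0]
    if constant:
        warnings.warn(f"removing {len(constant)} constant feature(s): {constant[:5]}")
        cols = [c for c in cols if c not in set(constant)]
    if len(cols) < 2:
        return cols
    corr = features[cols].corr().abs().to_numpy()
    active = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(active, active)]
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i].sum() / (len(active) - 1)
        mean_j = sub[j].sum() / (len(active) - 1)
        # ties drop the later feature in column order
        drop = i if mean_i > mean_j else j if mean_j > mean_i else max(i, j)
        del active[drop]
        if len(active) < 2:
            break
    return [cols[k] for k in active]


def assemble_features(
    target: pd.DataFrame, umap_cols: pd.DataFrame, retained: Sequence[str] | None = None
) -> pd.DataFrame:
    """Column-concatenate target-probe and UMAP features, optionally restricted.

    Target columns come first.  Name spaces must be disjoint (probe ids vs
    ``umap_k``).
    """
    overlap = set(target.columns) & set(umap_cols.columns)
    if overlap:
        raise ValidationError(f"feature name collision: {sorted(overlap)[:5]}")
    if not target.index.equals(umap_cols.index):
        raise ValidationError("target and UMAP features must cover the same samples")
    combined = pd.concat([target, umap_cols], axis=1)
    if retained is not None:
        missing = [c for c in retained if c not in combined.columns]
        if missing:
            raise ValidationError(f"retained feature(s) absent: {missing[:5]}")
        combined = combined[list(retained)]
    return combined


@dataclass
class FeatureMatrix:
    """Samples x features values with provenance tags per feature."""

    values: pd.DataFrame
    feature_tags: dict[str, str]  # feature name -> "target_probe" | "umap_dim"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FeatureSelectionState:
    """Everything fitted on the training set, reusable on held-out samples."""

    passing_probe_ids: list[str]
    target_probe_ids: list[str]
    umap_probe_ids: list[str]
    umap_reducer: object
    retained_feature_names: list[str]
    n_pre_pruning: int
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def transform(self, panel: ZScorePanel) -> FeatureMatrix:
        """Apply the frozen selection/embedding to any scored samples."""
        frame = panel.adjusted_frame()
        target = frame.loc[self.target_probe_ids].T
        umap_cols = transform_umap(self.umap_reducer, panel, self.umap_probe_ids)
        combined = assemble_features(target, umap_cols, self.retained_feature_names)
        tags = {
            c: ("umap_dim" if c.startswith("umap_") else "target_probe")
            for c in combined.columns
        }
        return FeatureMatrix(combined, tags)


def build_features(
    panel: ZScorePanel,
    samples: Sequence[SampleRecord],
    regions: RegionSet,
    config: PipelineConfig | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureSelectionState]:
    """Fit the full feature pipeline on train samples; transform train and test.

    Returns (train features, test features, fitted state).  Samples must carry
    train/test split assignments.
    """
    config = config or PipelineConfig()
    train = [s for s in samples if s.split == "train"]
    test = [s for s in samples if s.split == "test"]
    if not train or not test:
        raise ValidationError("samples must include both train and test splits")

    train_panel = panel.select_samples([s.sample_id for s in train])
    passing = filter_probes_by_z(
        train_panel, config.z_outlier_threshold, config.z_filter_min_samples
    )
    target_df = extract_target_features(train_panel, regions, passing)
    target_ids = list(target_df.columns)
    target_set = set(regions.all_probes())
    umap_input_ids = [p for p in passing if p not in target_set]
    if len(umap_input_ids) < 2:
        raise ValidationError("too few non-target probes survive the z filter for UMAP")
    umap_train, reducer = umap_global_features(
        train_panel, umap_input_ids, config.umap_dims, config.seed
    )
    combined_train = assemble_features(target_df, umap_train)
    retained = prune_correlated(combined_train, config.correlation_cutoff)
    state = FeatureSelectionState(
        passing_probe_ids=passing,
        target_probe_ids=target_ids,
        umap_probe_ids=umap_input_ids,
        umap_reducer=reducer,
        retained_feature_names=retained,
        n_pre_pruning=combined_train.shape[1],
        config=config,
    )
    tags = {c: ("umap_dim" if c.startswith("umap_") else "target_probe") for c in retained}
    train_features = FeatureMatrix(combined_train[retained], tags)
    test_features = state.transform(panel.select_samples([s.sample_id for s in test]))
    return train_features, test_features, state
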