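"""Outlier z-scores against the age/sex-adjusted reference.

Three variants are computed for every probe x sample cell of a cohort:

* unadjusted — against the cohort-global mean/SD of the control logit betas,
  ``z = (x - globalMu) / globalSigma``;
* adjusted — against the reference model's (mu, sigma) at the nearest grid
  age and matching sex, ``z = (x - mu) / sigma``;
* regularized — against a convex combination of the two references,
  ``mu_reg = lam * mu + (1 - lam) * globalMu`` (likewise sigma), which shrinks
  the age/sex-specific reference toward the global one to control false
  positives when the control cohort is modest.  ``lam = 1`` recovers the
  adjusted score exactly, ``lam = 0`` the unadjusted one.

Two-sided p-values use the standard normal reference.  Outliers are |z| >= 3
by default (inclusive), and region sensitivity counts, per sample, how many
probes of a disease locus are outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import BetaMatrix, RegionSet, SampleRecord, ValidationError
from .reference import GlobalStats, ReferenceModel, logit

__all__ = [
    "z_unadjusted",
    "z_adjusted",
    "z_regularized",
    "p_two_sided",
    "call_outlier",
    "ZScorePanel",
    "compute_z_panel",
    "region_sensitivity",
    "RegionSensitivity",
]

VARIANTS = ("unadjusted", "adjusted", "regularized")


def z_unadjusted(x_logit, global_stats: GlobalStats):
    """Standardize against the cohort-global mean and SD."""
    if global_stats.degenerate:
        raise ValidationError("degenerate global stats (sigma = 0)")
    return (np.asarray(x_logit, dtype=float) - global_stats.global_mu) / global_stats.global_sigma


def z_adjusted(x_logit, mu, sigma):
    """Standardize against the age/sex-specific reference (mu, sigma)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValidationError("sigma must be > 0")
    return (np.asarray(x_logit, dtype=float) - np.asarray(mu, dtype=float)) / sigma


def z_regularized(x_logit, mu, sigma, global_stats: GlobalStats, lam: float):
    """Standardize against the reference shrunk toward the global mean/SD."""
    if not 0.0 <= lam <= 1.0:
        raise ValidationError("regularization weight must be in [0, 1]")
    if global_stats.degenerate:
        raise ValidationError("degenerate global stats (sigma = 0)")
    mu_reg = lam * np.asarray(mu, dtype=float) + (1.0 - lam) * global_stats.global_mu
    sigma_reg = lam * np.asarray(sigma, dtype=float) + (1.0 - lam) * global_stats.global_sigma
    return z_adjusted(x_logit, mu_reg, sigma_reg)


def p_two_sided(z):
    """2 * (1 - Phi(|z|)) under the standard normal reference."""
    return 2.0 * norm.sf(np.abs(np.asarray(z, dtype=float)))


def call_outlier(z, threshold: float = 3.0):
    """Outlier rule: |z| >= threshold (inclusive at the boundary)."""
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    out = np.abs(np.asarray(z, dtype=float)) >= threshold
    return out if out.ndim else bool(out)


@dataclass
class ZScorePanel:
    """Probe x sample z-scores for the three variants, plus p-values on demand."""

    probe_ids: list[str]
    sample_ids: list[str]
    z_unadjusted: np.ndarray
    z_adjusted: np.ndarray
    z_regularized: np.ndarray

    def z(self, variant: str) -> np.ndarray:
        if variant not in VARIANTS:
            raise ValidationError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        return getattr(self, f"z_{variant}")

    def p(self, variant: str) -> np.ndarray:
        return p_two_sided(self.z(variant))

    def adjusted_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z_adjusted, index=self.probe_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "ZScorePanel":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [index[s] for s in sample_ids]
        return ZScorePanel(
            self.probe_ids,
            list(sample_ids),
            self.z_unadjusted[:, idx],
            self.z_adjusted[:, idx],
            self.z_regularized[:, idx],
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (probe_id, sample_id, z and p per variant)."""
        P, S = self.z_adjusted.shape
        return pd.DataFrame(
            {
                "probe_id": np.repeat(self.probe_ids, S),
                "sample_id": np.tile(self.sample_ids, P),
                "z_unadj": self.z_unadjusted.ravel(),
                "z_adj": self.z_adjusted.ravel(),
                "z_reg": self.z_regularized.ravel(),
                "p_unadj": self.p("unadjusted").ravel(),
                "p_adj": self.p("adjusted").ravel(),
                "p_reg": self.p("regularized").ravel(),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def compute_z_panel(
    beta: BetaMatrix,
    samples: Sequence[SampleRecord],
    model: ReferenceModel,
    lam: float = 0.5,
    epsilon: float = 1e-6,
) -> ZScorePanel:
    """Score every probe x sample cell under all three variants."""
    if model.probe_ids != beta.probe_ids:
        idx = beta.probe_indices(model.probe_ids)
        values = beta.values[idx]
    else:
        values = beta.values
    sample_ids = [s.sample_id for s in samples]
    cols = beta.sample_indices(sample_ids)
    x = logit(np.clip(values[:, cols], epsilon, 1.0 - epsilon))
    mu, sigma = model.lookup_samples([s.age_days for s in samples], [s.sex for s in samples])
    gmu = model.global_mu[:, None]
    gsig = model.global_sigma[:, None]
    if np.any(model.global_sigma <= 0):
        raise ValidationError("degenerate global stats for at least one probe")
    z_un = (x - gmu) / gsig
    z_ad = (x - mu) / sigma
    mu_reg = lam * mu + (1.0 - lam) * gmu
    sigma_reg = lam * sigma + (1.0 - lam) * gsig
    z_re = (x - mu_reg) / sigma_reg
    return ZScorePanel(list(model.probe_ids), sample_ids, z_un, z_ad, z_re)


@dataclass
class RegionSensitivity:
    """Per-sample count of disease-locus probes called as outliers."""

    sample_ids: list[str]
    outlier_count: np.ndarray
    n_region_probes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "outlier_count": self.outlier_count,
                "n_region_probes": self.n_region_probes,
            }
        )


def region_sensitivity(
    panel: ZScorePanel,
    region_probes: Sequence[str],
    sample_ids: Sequence[str] | None = None,
    variant: str = "adjusted",
    threshold: float = 3.0,
) -> RegionSensitivity:
    """Count per sample how many region probes exceed the outlier threshold."""
    region_probes = list(region_probes)
    if not region_probes:
        raise ValidationError("region is empty")
    probe_index = {p: i for i, p in enumerate(panel.probe_ids)}
    try:
        rows = [probe_index[p] for p in region_probes]
    except KeyError as exc:
        raise ValidationError(f"region probe {exc.args[0]!r} not in panel") from None
    sub = panel if sample_ids is None else panel.select_samples(list(sample_ids))
    z = sub.z(variant)[rows]
    counts = call_outlier(z, threshold).sum(axis=0)
    return RegionSensitivity(list(sub.sample_ids), counts.astype(int), len(region_probes))


def region_sensitivity_table(
    panel: ZScorePanel,
    regions: RegionSet,
    samples: Sequence[SampleRecord],
    threshold: float = 3.0,
) -> pd.DataFrame:
    """All regions x variants sensitivity counts in one long table."""
    frames = []
    ids = [s.sample_id for s in samples]
    labels = {s.sample_id: s.class_label for s in samples}
    for region in regions:
        for variant in VARIANTS:
            rs = region_sensitivity(panel, regions[region], ids, variant, threshold)
            df = rs.to_frame()
            df.insert(0, "region", region)
            df.insert(1, "variant", variant)
            df["class_label"] = [labels[s] for s in df["sample_id"]]
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
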