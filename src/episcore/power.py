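"""Type-I error and statistical power of the three outlier-detection variants.

Protocol, per iteration at cohort size n:

1. draw n control demographics (sex fair coin, age uniform on [0, 85] years)
   and logit-normal beta values from a ground-truth probe model;
2. fit the age/sex-adjusted reference model to this synthetic control cohort
   (the cohort-global mean/SD come from the same draws);
3. draw one more control point and one abnormal point — the same draw with a
   constant (default 0.3) added on the beta scale (hypermethylation);
4. flag each point under the unadjusted, adjusted and regularized variants,
   by default at two-sided p < alpha (an |z| >= 3 rule is available).

Repeating over many iterations, the control flag rate estimates type-I error
and the abnormal flag rate estimates power, per variant per cohort size.

The default desk-scale profile runs 2,000 iterations at cohort sizes
{10, 25, 50, 100, 200}; the published protocol (10,000 iterations, sizes 5 to
500 in steps of 5) is reachable through ``PowerConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ValidationError
from .reference import FitSettings, fit_probe_model, logit, lookup
from .scoring import VARIANTS, call_outlier, p_two_sided, z_regularized, z_unadjusted
from .synthetic import (
    DEFAULT_POWER_GROUND_TRUTH,
    GroundTruthProbeModel,
    apply_effect,
    sample_demographics,
    simulate_probe_values,
)

__all__ = ["PowerConfig", "PowerResult", "run_iteration", "run_power_analysis"]

DEFAULT_COHORT_SIZES = (10, 25, 50, 100, 200)


@dataclass
class PowerConfig:
    """Simulation settings for the power analysis."""

    cohort_sizes: Sequence[int] = DEFAULT_COHORT_SIZES
    iterations: int = 2000
    effect_delta: float = 0.3
    alpha: float = 0.05
    ground_truth: GroundTruthProbeModel = field(
        default_factory=lambda: DEFAULT_POWER_GROUND_TRUTH
    )
    regularization_weight: float = 0.5
    seed: int = 0
    rule: str = "pvalue"  # "pvalue": p < alpha; "zscore": |z| >= 3
    z_threshold: float = 3.0
    epsilon: float = 1e-6
    fit_settings: FitSettings = field(default_factory=FitSettings)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if any(n < 5 for n in self.cohort_sizes):
            raise ValidationError("cohort sizes must be >= 5")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.rule not in ("pvalue", "zscore"):
            raise ValidationError("rule must be 'pvalue' or 'zscore'")


@dataclass
class PowerResult:
    """Flag rates per variant per cohort size."""

    cohort_sizes: list[int]
    type1_error: dict[str, np.ndarray]  # variant -> rates over cohort sizes
    power: dict[str, np.ndarray]
    iterations_used: int
    fallback_fraction: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for variant in VARIANTS:
            for i, n in enumerate(self.cohort_sizes):
                rows.append(
                    {
                        "method": variant,
                        "cohort_size": n,
                        "type1_error": self.type1_error[variant][i],
                        "power": self.power[variant][i],
                        "iterations": self.iterations_used,
                    }
                )
        return pd.DataFrame(rows)


def _flag(z: np.ndarray, config: PowerConfig) -> np.ndarray:
    if config.rule == "pvalue":
        return p_two_sided(z) < config.alpha
    return call_outlier(z, config.z_threshold)


def run_iteration(
    gt: GroundTruthProbeModel,
    n: int,
    delta: float,
    rng: np.random.Generator,
    config: PowerConfig,
) -> tuple[dict[str, bool], dict[str, bool], bool]:
    """One simulation round; returns per-variant (control flag, abnormal flag)
    plus whether the reference fit fell back to the constant model."""
    if n < 5:
        raise ValidationError("cohort size must be >= 5")
    demo = sample_demographics(n, rng)
    betas = np.clip(simulate_probe_values(gt, demo, rng), config.epsilon, 1 - config.epsilon)
    x = logit(betas)
    model = fit_probe_model(
        x, [d[0] for d in demo], [d[1] for d in demo], settings=config.fit_settings
    )
    gstats = model.global_stats

    # paired design: the abnormal point is the control draw plus the effect,
    # so power at delta = 0 equals type-I error exactly (common random numbers)
    test_demo = sample_demographics(1, rng)
    test_beta = np.clip(
        simulate_probe_values(gt, test_demo, rng), config.epsilon, 1 - config.epsilon
    )
    control_beta = float(test_beta[0])
    abnormal_beta = (
        apply_effect(control_beta, delta, "hyper", config.epsilon) if delta > 0 else control_beta
    )

    control_flags: dict[str, bool] = {}
    abnormal_flags: dict[str, bool] = {}
    for beta_val, flags, (age, sex) in (
        (control_beta, control_flags, test_demo[0]),
        (abnormal_beta, abnormal_flags, test_demo[0]),
    ):
        xv = float(logit(np.array([beta_val]))[0])
        mu, sigma = lookup(model, age, sex)
        z_un = float(z_unadjusted(xv, gstats))
        z_ad = (xv - mu) / sigma
        z_re = float(z_regularized(xv, mu, sigma, gstats, config.regularization_weight))
        flags["unadjusted"] = bool(_flag(np.array(z_un), config))
        flags["adjusted"] = bool(_flag(np.array(z_ad), config))
        flags["regularized"] = bool(_flag(np.array(z_re), config))
    return control_flags, abnormal_flags, model.diagnostics.fallback


def run_power_analysis(config: PowerConfig) -> PowerResult:
    """Estimate type-I error and power per variant over the cohort-size sweep.

    Deterministic given ``config.seed``; each (cohort size, iteration) pair
    uses an independent child RNG stream so results are invariant to the
    order of cohort sizes.
    """
    sizes = list(config.cohort_sizes)
    type1 = {v: np.zeros(len(sizes)) for v in VARIANTS}
    power = {v: np.zeros(len(sizes)) for v in VARIANTS}
    fallback = np.zeros(len(sizes))
    root = np.random.SeedSequence(config.seed)
    size_seeds = root.spawn(len(sizes))
    for i, n in enumerate(sizes):
        rng = np.random.default_rng(size_seeds[i])
        ctrl_counts = {v: 0 for v in VARIANTS}
        abn_counts = {v: 0 for v in VARIANTS}
        n_fallback = 0
        for _ in range(config.iterations):
            ctrl, abn, fell_back = run_iteration(
                config.ground_truth, n, config.effect_delta, rng, config
            )
            n_fallback += fell_back
            for v in VARIANTS:
                ctrl_counts[v] += ctrl[v]
                abn_counts[v] += abn[v]
        for v in VARIANTS:
            type1[v][i] = ctrl_counts[v] / config.iterations
            power[v][i] = abn_counts[v] / config.iterations
        fallback[i] = n_fallback / config.iterations
    return PowerResult(sizes, type1, power, config.iterations, fallback)
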