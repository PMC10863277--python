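"""Synthetic methylation cohorts with age trends, sex offsets and disease effects.

The generator emulates the statistical structure the reference model assumes:
each probe has a ground-truth logit-scale mean that drifts with log(1 + age)
and may shift by sex, plus a logit-scale SD that may itself depend on age.
Individual beta values are logit-normal draws — Normal(mu, sigma) on the
logit scale, inverse-logit transformed — which is the natural generative
inverse of a model fit to logit-transformed betas.

Disorder classes overlay effects on top of healthy draws: regional classes
add/subtract a constant on the beta scale (default 0.3) over every probe of
their disease locus; the diffuse SRS-like class perturbs a per-sample random
fraction of all probes in random directions, emulating the heterogeneous
genome-wide signature of Silver-Russell syndrome.

Demographics follow the power-analysis protocol: sex Bernoulli(1/2), age
uniform on [0, 85] years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import (
    CLASS_LABELS,
    DAYS_PER_YEAR,
    BetaMatrix,
    RegionSet,
    SampleRecord,
    ValidationError,
)
from .reference import inverse_logit

__all__ = [
    "GroundTruthProbeModel",
    "DiseaseSpec",
    "CohortSpec",
    "DEFAULT_POWER_GROUND_TRUTH",
    "sample_demographics",
    "simulate_probe_values",
    "apply_effect",
    "generate_cohort",
    "random_probe_models",
    "default_cohort_spec",
]


@dataclass(frozen=True)
class GroundTruthProbeModel:
    """True generating distribution for one probe.

    mu(age, sex) = mu0 + age_coef * log(1 + age_years) + sex_offset * 1[M]
    log sigma(age) = log(sigma0) + sigma_age_coef * log(1 + age_years)
    """

    mu0: float
    age_coef: float = 0.0
    sex_offset: float = 0.0
    sigma0: float = 0.5
    sigma_age_coef: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ValidationError("sigma0 must be > 0")
        # sigma must stay positive over the supported age range; on the log
        # scale that is automatic, but guard against absurd underflow
        t_max = np.log1p(85.0)
        if self.sigma0 * np.exp(min(0.0, self.sigma_age_coef * t_max)) < 1e-8:
            raise ValidationError("implied sigma(age) underflows over [0, 85] years")

    def mu(self, age_days, sex_is_male) -> np.ndarray:
        t = np.log1p(np.asarray(age_days, dtype=float) / DAYS_PER_YEAR)
        return self.mu0 + self.age_coef * t + self.sex_offset * np.asarray(
            sex_is_male, dtype=float
        )

    def sigma(self, age_days) -> np.ndarray:
        t = np.log1p(np.asarray(age_days, dtype=float) / DAYS_PER_YEAR)
        return self.sigma0 * np.exp(self.sigma_age_coef * t)


#: Ground truth for the power analysis: a probe with a strong age trend and a
#: sex shift, with a mid-low baseline methylation so that the +0.3 beta-scale
#: hypermethylation effect moves values within the global range rather than
#: saturating at 1 (which would make all detection variants trivially perfect).
DEFAULT_POWER_GROUND_TRUTH = GroundTruthProbeModel(
    mu0=-1.5, age_coef=0.6, sex_offset=0.4, sigma0=0.35, sigma_age_coef=0.0
)


@dataclass(frozen=True)
class DiseaseSpec:
    """One methylation aberration: region (or 'global'), direction, effect size.

    ``direction`` is 'hyper', 'hypo', or 'random' (per-probe random direction;
    used by the diffuse global signature).  ``fraction_probes_affected`` < 1
    draws a fresh random probe subset per sample, modeling heterogeneity.
    """

    class_label: str
    region_name: str
    direction: str
    effect_delta: float = 0.3
    fraction_probes_affected: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo", "random"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if not 0.0 < self.effect_delta < 1.0:
            raise ValidationError("effect_delta must be in (0, 1)")
        if not 0.0 < self.fraction_probes_affected <= 1.0:
            raise ValidationError("fraction_probes_affected must be in (0, 1]")


@dataclass
class CohortSpec:
    """Full recipe for a synthetic cohort."""

    n_per_class: Mapping[str, int]
    n_probes: int
    regions: RegionSet
    probe_models: Mapping[str, GroundTruthProbeModel]
    disease_specs: Sequence[DiseaseSpec] = field(default_factory=list)
    age_range_years: tuple[float, float] = (0.0, 85.0)
    sex_probability: float = 0.5
    seed: int = 0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        for label, n in self.n_per_class.items():
            if label not in CLASS_LABELS:
                raise ValidationError(f"unknown class label {label!r}")
            if n < 0:
                raise ValidationError("class counts must be >= 0")
        for spec in self.disease_specs:
            if spec.region_name != "global" and spec.region_name not in self.regions:
                raise ValidationError(
                    f"disease spec for {spec.class_label!r} references unknown "
                    f"region {spec.region_name!r}"
                )


def sample_demographics(
    n: int, seed: int | np.random.Generator, age_range_years: tuple[float, float] = (0.0, 85.0)
) -> list[tuple[int, str]]:
    """Draw (age_days, sex) pairs: age uniform over the range, sex fair coin."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = age_range_years
    ages_years = rng.uniform(lo, hi, size=n)
    ages_days = np.floor(ages_years * DAYS_PER_YEAR + 0.5).astype(int)
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    return list(zip(ages_days.tolist(), sexes.tolist()))


def simulate_probe_values(
    model: GroundTruthProbeModel,
    demographics: Sequence[tuple[int, str]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Logit-normal beta draws for each individual given the probe's ground truth."""
    if len(demographics) == 0:
        raise ValidationError("demographics must be non-empty")
    ages = np.array([d[0] for d in demographics], dtype=float)
    male = np.array([d[1] == "M" for d in demographics], dtype=float)
    mu = model.mu(ages, male)
    sigma = model.sigma(ages)
    return inverse_logit(rng.normal(mu, sigma))


def apply_effect(beta, delta: float, direction: str, epsilon: float = 1e-6):
    """Shift a beta value by ``delta`` on the beta scale, clipping to (0, 1).

    Hypermethylation adds, hypomethylation subtracts; results are clipped to
    [epsilon, 1 - epsilon] to stay in the logit domain.
    """
    if delta <= 0:
        raise ValidationError("delta must be > 0")
    beta = np.asarray(beta, dtype=float)
    if direction == "hyper":
        out = np.minimum(beta + delta, 1.0 - epsilon)
    elif direction == "hypo":
        out = np.maximum(beta - delta, epsilon)
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    return out if out.ndim else float(out)


def random_probe_models(
    probe_ids: Sequence[str], seed: int | np.random.Generator
) -> dict[str, GroundTruthProbeModel]:
    """Random but realistic ground-truth models, one per probe.

    Baselines span the beta range, age trends are moderate, and 70% of probes
    have no sex effect — probes may or may not carry age/sex structure, as
    observed on real arrays.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    models = {}
    for pid in probe_ids:
        has_sex = rng.random() >= 0.7
        models[pid] = GroundTruthProbeModel(
            mu0=float(rng.uniform(-3.0, 3.0)),
            age_coef=float(rng.uniform(-0.5, 0.5)),
            sex_offset=float(rng.uniform(-1.0, 1.0)) if has_sex else 0.0,
            sigma0=float(rng.uniform(0.2, 0.8)),
            sigma_age_coef=0.0,
        )
    return models


def generate_cohort(spec: CohortSpec) -> tuple[BetaMatrix, list[SampleRecord]]:
    """Simulate a full cohort: healthy draws plus per-class disease overlays.

    Deterministic given ``spec.seed``: identical specs produce bit-identical
    matrices.
    """
    rng = np.random.default_rng(spec.seed)
    probe_ids = list(spec.probe_models)
    if len(probe_ids) != spec.n_probes:
        raise ValidationError(
            f"probe_models has {len(probe_ids)} entries but n_probes = {spec.n_probes}"
        )
    for region, probes in spec.regions.items():
        missing = [p for p in probes if p not in spec.probe_models]
        if missing:
            raise ValidationError(f"region {region!r} probes not in probe_models: {missing[:3]}")

    specs_by_class: dict[str, list[DiseaseSpec]] = {}
    for d in spec.disease_specs:
        specs_by_class.setdefault(d.class_label, []).append(d)

    records: list[SampleRecord] = []
    for label in CLASS_LABELS:
        n = int(spec.n_per_class.get(label, 0))
        if n == 0:
            continue
        demo = sample_demographics(n, rng, spec.age_range_years)
        for age_days, sex in demo:
            records.append(
                SampleRecord(
                    sample_id=f"{label}_{len(records):04d}",
                    age_days=age_days,
                    sex=sex,
                    class_label=label,
                )
            )

    demo_all = [(r.age_days, r.sex) for r in records]
    values = np.empty((spec.n_probes, len(records)))
    for i, pid in enumerate(probe_ids):
        values[i] = simulate_probe_values(spec.probe_models[pid], demo_all, rng)

    probe_row = {p: i for i, p in enumerate(probe_ids)}
    for j, rec in enumerate(records):
        for d in specs_by_class.get(rec.class_label, []):
            if d.region_name == "global":
                n_affected = max(1, int(round(d.fraction_probes_affected * spec.n_probes)))
                rows = rng.choice(spec.n_probes, size=n_affected, replace=False)
            else:
                rows = np.array([probe_row[p] for p in spec.regions[d.region_name]])
                if d.fraction_probes_affected < 1.0:
                    k = max(1, int(round(d.fraction_probes_affected * len(rows))))
                    rows = rng.choice(rows, size=k, replace=False)
            if d.direction == "random":
                directions = np.where(rng.random(len(rows)) < 0.5, "hyper", "hypo")
            else:
                directions = np.full(len(rows), d.direction)
            for row, direction in zip(rows, directions):
                values[row, j] = apply_effect(
                    values[row, j], d.effect_delta, direction, spec.epsilon
                )

    values = np.clip(values, spec.epsilon, 1.0 - spec.epsilon)
    matrix = BetaMatrix(probe_ids, [r.sample_id for r in records], values)
    return matrix, records


def default_cohort_spec(
    n_normal: int = 150,
    n_per_disorder: int = 15,
    n_probes: int = 2000,
    seed: int = 0,
    effect_delta: float = 0.3,
    region_size: int = 10,
) -> CohortSpec:
    """The study-like synthetic cohort: controls plus seven disorder classes.

    Disease loci mirror the real disorders' methylation patterns: BWS1 shows
    H19 hypermethylation with LIT1 hypomethylation, BWS2 LIT1 hypomethylation
    only, AS2/PWS1 opposite aberrations of the SNRPN locus, PWS2 a MAGEL2
    aberration, FXS FMR1 hypermethylation, and SRS1 a diffuse signature over
    a random 10% of probes per sample (delta 0.15, random direction).
    """
    region_names = ("H19", "LIT1", "SNRPN", "MAGEL2", "FMR1")
    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    if n_probes < region_size * len(region_names):
        raise ValidationError("n_probes too small for the default region layout")
    regions = RegionSet(
        {
            name: probe_ids[i * region_size : (i + 1) * region_size]
            for i, name in enumerate(region_names)
        }
    )
    disease_specs = [
        DiseaseSpec("BWS1", "H19", "hyper", effect_delta),
        DiseaseSpec("BWS1", "LIT1", "hypo", effect_delta),
        DiseaseSpec("BWS2", "LIT1", "hypo", effect_delta),
        DiseaseSpec("SRS1", "global", "random", 0.15, fraction_probes_affected=0.1),
        DiseaseSpec("AS2", "SNRPN", "hypo", effect_delta),
        DiseaseSpec("PWS1", "SNRPN", "hyper", effect_delta),
        DiseaseSpec("PWS2", "MAGEL2", "hyper", effect_delta),
        DiseaseSpec("FXS", "FMR1", "hyper", effect_delta),
    ]
    n_per_class = {label: n_per_disorder for label in CLASS_LABELS if label != "Normal"}
    n_per_class["Normal"] = n_normal
    # region probes get mid-range baselines so +/-0.3 effects neither vanish
    # nor saturate; off-region probes draw from the full realistic range
    rng = np.random.default_rng(seed + 1)
    models = random_probe_models(probe_ids, rng)
    for region in regions:
        for pid in regions[region]:
            models[pid] = GroundTruthProbeModel(
                mu0=float(rng.uniform(-1.5, 0.5)),
                age_coef=float(rng.uniform(-0.4, 0.4)),
                sex_offset=float(rng.uniform(-0.5, 0.5)) if rng.random() >= 0.7 else 0.0,
                sigma0=float(rng.uniform(0.2, 0.5)),
            )
    return CohortSpec(
        n_per_class=n_per_class,
        n_probes=n_probes,
        regions=regions,
        probe_models=models,
        disease_specs=disease_specs,
        seed=seed,
    )
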