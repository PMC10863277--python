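"""Data model and file I/O for methylation cohorts.

All downstream stages consume the containers defined here (``BetaMatrix``,
``SampleRecord``, ``RegionSet``, ``PipelineConfig``); no other module reads
files directly.  Beta matrices are plain probes x samples tables of
methylation fractions in (0, 1); values exactly 0 or 1 are clipped to
``[epsilon, 1 - epsilon]`` on input because the logit transform used by the
reference model is undefined at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CLASS_LABELS",
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
    "ParseError",
    "ValidationError",
    "SampleRecord",
    "BetaMatrix",
    "RegionSet",
    "PipelineConfig",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_region_map",
    "write_region_map",
    "years_to_days",
]

#: The eight cohort classes: healthy controls plus seven imprinting /
#: repeat-expansion disorder categories (BWS split by H19/LIT1 status).
CLASS_LABELS: tuple[str, ...] = (
    "Normal",
    "BWS1",
    "BWS2",
    "SRS1",
    "AS2",
    "PWS1",
    "PWS2",
    "FXS",
)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375

SEXES = ("F", "M")
SPLITS = ("train", "test", "unassigned")


class ParseError(ValueError):
    """A file could not be parsed into the expected structure."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant."""


def years_to_days(years: float) -> int:
    """Convert an age in years to the canonical integer-day unit."""
    return int(np.floor(years * DAYS_PER_YEAR + 0.5))


@dataclass(frozen=True)
class SampleRecord:
    """One cohort member: identity, demographics, class label, split."""

    sample_id: str
    age_days: int
    sex: str
    class_label: str = "Normal"
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: age_days must be >= 0, got {self.age_days}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"sample {self.sample_id!r}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown class label {self.class_label!r}"
            )
        if self.split not in SPLITS:
            raise ValidationError(
                f"sample {self.sample_id!r}: split must be one of {SPLITS}, got {self.split!r}"
            )

    @property
    def age_years(self) -> float:
        return self.age_days / DAYS_PER_YEAR


class BetaMatrix:
    """Probes x samples matrix of methylation beta values, strictly in (0, 1)."""

    def __init__(
        self,
        probe_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
        *,
        validate: bool = True,
    ) -> None:
        self.probe_ids = list(probe_ids)
        self.sample_ids = list(sample_ids)
        self.values = np.asarray(values, dtype=float)
        if validate:
            self._validate()
        self._probe_index = {p: i for i, p in enumerate(self.probe_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    def _validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = _duplicates(self.probe_ids)
            raise ValidationError(f"duplicate probe ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("beta matrix contains missing or non-finite values")
        if np.any(self.values <= 0.0) or np.any(self.values >= 1.0):
            raise ValidationError("beta values must lie strictly in (0, 1) after clipping")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def probe_indices(self, probe_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._probe_index[p] for p in probe_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"probe id {exc.args[0]!r} not in matrix") from None

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"sample id {exc.args[0]!r} not in matrix") from None

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        idx = self.sample_indices(sample_ids)
        return BetaMatrix(self.probe_ids, list(sample_ids), self.values[:, idx], validate=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"BetaMatrix({len(self.probe_ids)} probes x {len(self.sample_ids)} samples)"


class RegionSet:
    """Ordered mapping from disorder/region name to its probe-id list.

    Regions may share probes (e.g. overlapping disease loci); probe lists are
    non-empty and keep file order.
    """

    def __init__(self, regions: Mapping[str, Sequence[str]]) -> None:
        self.regions: dict[str, list[str]] = {}
        for name, probes in regions.items():
            probes = list(probes)
            if not probes:
                raise ValidationError(f"region {name!r} has an empty probe list")
            self.regions[name] = probes

    def __getitem__(self, name: str) -> list[str]:
        return self.regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def items(self):
        return self.regions.items()

    def all_probes(self) -> list[str]:
        """Unique probes across all regions, first occurrence order."""
        seen: dict[str, None] = {}
        for probes in self.regions.values():
            for p in probes:
                seen.setdefault(p)
        return list(seen)

    def validate_against(self, matrix: BetaMatrix) -> None:
        matrix.probe_indices(self.all_probes())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions

    def __repr__(self) -> str:
        return f"RegionSet({len(self.regions)} regions, {len(self.all_probes())} unique probes)"


@dataclass
class PipelineConfig:
    """Tunable constants shared across pipeline stages.

    Defaults follow the published analysis: outliers at |z| >= 3, alpha 0.05,
    regularization weight 0.5 toward the global reference, 50 UMAP global
    features, correlation pruning at 0.9, stratified 80/20 split, 5-fold
    bagging.
    """

    seed: int = 0
    z_outlier_threshold: float = 3.0
    alpha: float = 0.05
    regularization_weight: float = 0.5
    umap_dims: int = 50
    correlation_cutoff: float = 0.9
    train_fraction: float = 0.8
    bag_folds: int = 5
    logit_epsilon: float = 1e-6
    z_filter_min_samples: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")
        if not 0.0 <= self.regularization_weight <= 1.0:
            raise ValidationError("regularization_weight must be in [0, 1]")
        if self.z_outlier_threshold <= 0:
            raise ValidationError("z_outlier_threshold must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0.0 < self.logit_epsilon < 0.5:
            raise ValidationError("logit_epsilon must be in (0, 0.5)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_beta_matrix(path: str | Path, epsilon: float = 1e-6) -> BetaMatrix:
    """Read a probes x samples beta matrix from TSV/CSV.

    The first column must be ``probe_id``; remaining columns are samples.
    Values are clipped to ``[epsilon, 1 - epsilon]``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a probe_id column plus sample columns")
    probe_ids = df.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {body.iat[r, c]!r} at probe "
            f"{probe_ids[r]!r}, sample {sample_ids[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at probe {probe_ids[r]!r}, sample {sample_ids[c]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if np.any(values < 0.0) or np.any(values > 1.0):
        raise ValidationError(f"{path}: beta values must lie in [0, 1]")
    values = np.clip(values, epsilon, 1.0 - epsilon)
    return BetaMatrix(probe_ids, sample_ids, values)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a sample sheet CSV with columns sample_id, age, sex, class_label.

    Age may be given as ``age_days`` (integer days) or ``age_years`` (converted
    with 365.25 days/year).  An optional ``split`` column is honored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    cols = set(df.columns)
    if "sample_id" not in cols:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    if "age_days" in cols:
        ages = pd.to_numeric(df["age_days"], errors="coerce")
        if ages.isna().any():
            raise ParseError(f"{path}: non-numeric age_days value")
        age_days = ages.round().astype(int)
    elif "age_years" in cols:
        ages = pd.to_numeric(df["age_years"], errors="coerce")
        if ages.isna().any():
            raise ParseError(f"{path}: non-numeric age_years value")
        age_days = ages.map(years_to_days)
    else:
        raise ParseError(f"{path}: need an 'age_days' or 'age_years' column")
    for required in ("sex", "class_label"):
        if required not in cols:
            raise ParseError(f"{path}: missing required column {required!r}")
    splits = df["split"] if "split" in cols else pd.Series(["unassigned"] * len(df))
    records = [
        SampleRecord(
            sample_id=str(row.sample_id),
            age_days=int(age),
            sex=str(row.sex),
            class_label=str(row.class_label),
            split=str(split),
        )
        for row, age, split in zip(df.itertuples(index=False), age_days, splits)
    ]
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample ids {sorted(_duplicates(ids))[:5]}")
    return records


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "age_days": [r.age_days for r in records],
            "sex": [r.sex for r in records],
            "class_label": [r.class_label for r in records],
            "split": [r.split for r in records],
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_region_map(path: str | Path) -> RegionSet:
    """Read a two-column region map TSV (region_name, probe_id)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: region map is empty") from None
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected two tab-separated columns, got {df.shape[1]}")
    if len(df) == 0:
        raise ValidationError(f"{path}: region map is empty")
    regions: dict[str, list[str]] = {}
    for name, probe in df.itertuples(index=False):
        regions.setdefault(name, []).append(probe)
    return RegionSet(regions)


def write_region_map(regions: RegionSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, probes in regions.items():
            for probe in probes:
                fh.write(f"{name}\t{probe}\n")
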