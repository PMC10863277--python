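"""Per-probe age- and sex-adjusted reference model on the logit scale.

Methylation beta values are logit transformed and, for each probe, a Gaussian
location-scale model is fit to healthy-control samples:

    x ~ Normal(mu(age, sex), sigma(age, sex))
    mu        = s_mu(t)  + b_mu  * 1[sex == M]
    log sigma = s_sig(t) + b_sig * 1[sex == M]

with ``t = log(1 + age_years)`` and ``s_*`` penalized cubic B-splines
(P-splines: second-order difference penalty; the mu smoothing parameter is
chosen by GCV).  The log-age transform concentrates flexibility in infancy,
where methylation trajectories change fastest.  Fitting alternates penalized
weighted least squares for mu with Fisher scoring for log-sigma until the
joint Gaussian log-likelihood stabilizes.

The fitted smooth is then discretized onto a fixed age x sex grid — one-day
steps through the first year, monthly steps to 24 months, yearly steps from
3 to 85 years — and all downstream scoring uses nearest-grid-age lookup,
which keeps the stored model small and lookups O(log n).

Probes with too few controls (< 10), a single sex, or a failed fit fall back
to a constant model equal to the cohort-global mean/SD, which degrades
gracefully to unadjusted scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit
from scipy.special import logit as _logit

from .io import DAYS_PER_MONTH, DAYS_PER_YEAR, BetaMatrix, SampleRecord, ValidationError

__all__ = [
    "logit",
    "inverse_logit",
    "age_transform",
    "build_age_grid",
    "GlobalStats",
    "compute_global_stats",
    "FitSettings",
    "ProbeReferenceModel",
    "fit_probe_model",
    "lookup",
    "nearest_grid_index",
    "ReferenceModel",
    "fit_reference_model",
]

SIGMA_FLOOR = 1e-4
MIN_CONTROLS = 10

_SEX_CODE = {"F": 0, "M": 1}


def logit(beta):
    """log(beta / (1 - beta)); callers must pre-clip boundary values."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0.0) or np.any(beta >= 1.0):
        raise ValidationError("logit requires values strictly in (0, 1); clip at I/O first")
    return _logit(beta)


def inverse_logit(x):
    return expit(np.asarray(x, dtype=float))


def age_transform(age_days):
    """Smoothing covariate t = log(1 + age_years)."""
    return np.log1p(np.asarray(age_days, dtype=float) / DAYS_PER_YEAR)


def build_age_grid() -> np.ndarray:
    """The discretized reference ages, in integer days.

    Daily from 0 to 365 days, monthly from 13 to 24 months (months 1-12 are
    already covered by the daily range), yearly from 3 to 85 years; month and
    year lengths 30.4375 and 365.25 days, rounded half away from zero.
    """
    days = np.arange(0, 366)
    months = np.floor(np.arange(13, 25) * DAYS_PER_MONTH + 0.5).astype(int)
    years = np.floor(np.arange(3, 86) * DAYS_PER_YEAR + 0.5).astype(int)
    grid = np.unique(np.concatenate([days, months, years]))
    return grid


@dataclass(frozen=True)
class GlobalStats:
    """Cohort-global mean and SD of a probe's logit beta values."""

    global_mu: float
    global_sigma: float

    @property
    def degenerate(self) -> bool:
        return not self.global_sigma > 0.0


def compute_global_stats(logit_values: Sequence[float]) -> GlobalStats:
    """Sample mean and SD (ddof=1) of logit-transformed betas."""
    x = np.asarray(logit_values, dtype=float)
    if x.size < 2:
        raise ValidationError("global stats require at least 2 values")
    return GlobalStats(float(np.mean(x)), float(np.std(x, ddof=1)))


@dataclass(frozen=True)
class FitSettings:
    """Knobs for the location-scale P-spline fit."""

    n_basis: int = 8
    lambda_grid: tuple[float, ...] = (1.0, 10.0, 100.0, 1e3, 1e4)
    lambda_sigma: float = 100.0
    sex_in_sigma: bool = True
    max_iter: int = 200
    tol: float = 1e-8


@dataclass
class FitDiagnostics:
    n_controls: int
    converged: bool
    effective_df: float
    fallback: bool = False


class _SplineBasis:
    """Shared design-matrix builder: B-spline block in t plus a sex column."""

    def __init__(self, n_basis: int = 8, t_max: float | None = None) -> None:
        if t_max is None:
            t_max = float(np.log1p(85.0))
        # uniform extended knots (standard P-spline construction): with equal
        # spacing, the 2nd-difference coefficient penalty leaves exactly the
        # linear-in-t functions unpenalized
        h = t_max / (n_basis - 3)
        self.knots = np.arange(-3, n_basis + 1) * h
        self.n_basis = n_basis
        # second-order difference penalty on the spline coefficient block only
        D = np.diff(np.eye(n_basis), n=2, axis=0)
        P = D.T @ D
        self.penalty = np.zeros((n_basis + 1, n_basis + 1))
        self.penalty[:n_basis, :n_basis] = P

    def design(self, t: np.ndarray, sex_code: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), self.knots[0], self.knots[-1])
        B = BSpline.design_matrix(t, self.knots, 3).toarray()
        return np.column_stack([B, np.asarray(sex_code, dtype=float)])


_BASIS_CACHE: dict[int, _SplineBasis] = {}
_GRID_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _basis(n_basis: int) -> _SplineBasis:
    if n_basis not in _BASIS_CACHE:
        _BASIS_CACHE[n_basis] = _SplineBasis(n_basis)
    return _BASIS_CACHE[n_basis]


def _grid_designs(n_basis: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(age grid, design at grid for F, design at grid for M), cached."""
    if n_basis not in _GRID_CACHE:
        basis = _basis(n_basis)
        grid = build_age_grid()
        t = age_transform(grid)
        XF = basis.design(t, np.zeros(len(grid)))
        XM = basis.design(t, np.ones(len(grid)))
        _GRID_CACHE[n_basis] = (grid, XF, XM)
    return _GRID_CACHE[n_basis]


@dataclass
class ProbeReferenceModel:
    """Discretized (mu, sigma) lookup for one probe over the age x sex grid.

    ``mu`` and ``sigma`` have shape (n_grid, 2); column 0 is female, column 1
    male.  ``global_stats`` holds the unadjusted reference for the same probe.
    """

    probe_id: str
    age_grid: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    global_stats: GlobalStats
    diagnostics: FitDiagnostics

    def __post_init__(self) -> None:
        if self.mu.shape != (len(self.age_grid), 2) or self.sigma.shape != self.mu.shape:
            raise ValidationError("mu/sigma tables must cover every (grid age, sex)")
        if np.any(self.sigma <= 0.0):
            raise ValidationError("sigma must be > 0 at every grid point")


def nearest_grid_index(age_grid: np.ndarray, age_days) -> np.ndarray:
    """Index of the grid age nearest each query age; ties go to the younger age."""
    age_days = np.atleast_1d(np.asarray(age_days, dtype=float))
    pos = np.searchsorted(age_grid, age_days)
    pos = np.clip(pos, 1, len(age_grid) - 1)
    left = age_grid[pos - 1]
    right = age_grid[pos]
    # strict inequality: equidistant queries resolve to the younger (left) age
    use_right = (age_days - left) > (right - age_days)
    idx = pos - 1 + use_right.astype(int)
    idx[age_days <= age_grid[0]] = 0
    return idx


def lookup(model: ProbeReferenceModel, age_days, sex) -> tuple[float, float]:
    """(mu, sigma) at the grid age nearest ``age_days`` for the given sex."""
    idx = nearest_grid_index(model.age_grid, age_days)[0]
    s = _SEX_CODE[sex]
    return float(model.mu[idx, s]), float(model.sigma[idx, s])


def _penalized_wls(X, y, w, penalty, lam):
    XtW = X.T * w
    A = XtW @ X + lam * penalty
    return np.linalg.solve(A, XtW @ y)


def _gcv_lambda(X, y, w, penalty, lambda_grid):
    """Pick the mu smoothing parameter by generalized cross-validation.

    GCV curves for near-linear age trends are very flat, and the lightest
    smoothing that ties the minimum can leave the sparsely sampled infancy
    edge badly under-determined; among candidates within 1% of the minimum
    GCV the heaviest smoothing is preferred.
    """
    n = len(y)
    results = []
    XtW = X.T * w
    XtWX = XtW @ X
    XtWy = XtW @ y
    for lam in lambda_grid:
        A = XtWX + lam * penalty
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        beta = Ainv @ XtWy
        fitted = X @ beta
        edf = float(np.trace(Ainv @ XtWX))
        denom = max(n - edf, 1e-8)
        gcv = n * float(np.sum(w * (y - fitted) ** 2)) / denom**2
        results.append((lam, gcv, edf))
    if not results:
        return lambda_grid[0], None
    gcv_min = min(g for _, g, _ in results)
    lam, _, edf = max(
        (r for r in results if r[1] <= 1.01 * gcv_min), key=lambda r: r[0]
    )
    return lam, edf


def _fit_location_scale(y, X, penalty, settings: FitSettings, sigma_cols: np.ndarray):
    """Alternating penalized WLS (mu) / Fisher scoring (log sigma).

    ``sigma_cols`` masks which design columns enter the sigma submodel
    (the sex column can be excluded via FitSettings.sex_in_sigma).
    """
    n, p = X.shape
    Xs = X[:, sigma_cols]
    Ps = penalty[np.ix_(sigma_cols, sigma_cols)]

    # init: homoscedastic fit
    coef_mu = _penalized_wls(X, y, np.ones(n), penalty, settings.lambda_grid[1])
    resid = y - X @ coef_mu
    sd0 = max(float(np.std(resid, ddof=1)), SIGMA_FLOOR)
    coef_sig = np.zeros(Xs.shape[1])
    coef_sig[: _n_spline_cols(sigma_cols)] = np.log(sd0)  # basis sums to 1
    eta = Xs @ coef_sig

    lam_mu, edf = _gcv_lambda(X, y, np.exp(-2.0 * eta), penalty, settings.lambda_grid)
    lam_sig = settings.lambda_sigma

    ll_prev = -np.inf
    converged = False
    for _ in range(settings.max_iter):
        w = np.exp(-2.0 * eta)
        coef_mu = _penalized_wls(X, y, w, penalty, lam_mu)
        resid = y - X @ coef_mu
        # one Fisher-scoring step for log sigma: E[d2l/deta2] = -2
        r2 = resid**2 * np.exp(-2.0 * eta)
        z = eta + 0.5 * (r2 - 1.0)
        coef_sig = _penalized_wls(Xs, z, np.full(n, 2.0), Ps, lam_sig)
        eta = np.clip(Xs @ coef_sig, np.log(SIGMA_FLOOR), 10.0)
        ll = float(np.sum(-0.5 * np.log(2 * np.pi) - eta - 0.5 * resid**2 * np.exp(-2.0 * eta)))
        if abs(ll - ll_prev) < settings.tol:
            converged = True
            break
        ll_prev = ll
    return coef_mu, coef_sig, converged, (edf if edf is not None else float(p))


def _n_spline_cols(sigma_cols: np.ndarray) -> int:
    # spline block always included; only the trailing sex column is optional
    return int(np.sum(sigma_cols)) - (1 if sigma_cols[-1] else 0)


def _fallback_model(
    probe_id: str, gstats: GlobalStats, n: int, age_grid: np.ndarray
) -> ProbeReferenceModel:
    sigma = max(gstats.global_sigma, SIGMA_FLOOR)
    shape = (len(age_grid), 2)
    return ProbeReferenceModel(
        probe_id=probe_id,
        age_grid=age_grid,
        mu=np.full(shape, gstats.global_mu),
        sigma=np.full(shape, sigma),
        global_stats=gstats,
        diagnostics=FitDiagnostics(n, converged=False, effective_df=1.0, fallback=True),
    )


def fit_probe_model(
    logit_values: Sequence[float],
    ages_days: Sequence[float],
    sexes: Sequence[str],
    *,
    probe_id: str = "probe",
    settings: FitSettings | None = None,
) -> ProbeReferenceModel:
    """Fit the location-scale model for one probe and discretize onto the grid.

    Requires at least 10 controls with both sexes represented; otherwise the
    constant global-stats fallback is returned (``diagnostics.fallback``).
    """
    settings = settings or FitSettings()
    y = np.asarray(logit_values, dtype=float)
    ages = np.asarray(ages_days, dtype=float)
    sex_code = np.array([_SEX_CODE[s] for s in sexes], dtype=float)
    if not (len(y) == len(ages) == len(sex_code)):
        raise ValidationError("logit_values, ages_days and sexes must have equal length")
    gstats = compute_global_stats(y)
    grid, XF, XM = _grid_designs(settings.n_basis)
    if gstats.degenerate:
        raise ValidationError(f"probe {probe_id!r}: all control values identical")
    if len(y) < MIN_CONTROLS or len(set(sex_code)) < 2:
        return _fallback_model(probe_id, gstats, len(y), grid)

    basis = _basis(settings.n_basis)
    X = basis.design(age_transform(ages), sex_code)
    sigma_cols = np.ones(X.shape[1], dtype=bool)
    if not settings.sex_in_sigma:
        sigma_cols[-1] = False
    try:
        coef_mu, coef_sig, converged, edf = _fit_location_scale(
            y, X, basis.penalty, settings, sigma_cols
        )
    except np.linalg.LinAlgError:
        return _fallback_model(probe_id, gstats, len(y), grid)
    if not converged:
        return _fallback_model(probe_id, gstats, len(y), grid)

    mu = np.column_stack([XF @ coef_mu, XM @ coef_mu])
    sigma = np.column_stack(
        [
            np.exp(np.clip(XF[:, sigma_cols] @ coef_sig, np.log(SIGMA_FLOOR), 10.0)),
            np.exp(np.clip(XM[:, sigma_cols] @ coef_sig, np.log(SIGMA_FLOOR), 10.0)),
        ]
    )
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    return ProbeReferenceModel(
        probe_id=probe_id,
        age_grid=grid,
        mu=mu,
        sigma=sigma,
        global_stats=gstats,
        diagnostics=FitDiagnostics(len(y), converged=True, effective_df=edf),
    )


class ReferenceModel:
    """Per-probe reference models for a whole cohort, sharing one age grid."""

    def __init__(self, probes: Sequence[ProbeReferenceModel]) -> None:
        if not probes:
            raise ValidationError("empty reference model")
        self.age_grid = probes[0].age_grid
        self.probe_ids = [p.probe_id for p in probes]
        self._by_id = {p.probe_id: p for p in probes}
        self.mu = np.stack([p.mu for p in probes])  # (P, G, 2)
        self.sigma = np.stack([p.sigma for p in probes])
        self.global_mu = np.array([p.global_stats.global_mu for p in probes])
        self.global_sigma = np.array([p.global_stats.global_sigma for p in probes])

    def __getitem__(self, probe_id: str) -> ProbeReferenceModel:
        return self._by_id[probe_id]

    def __len__(self) -> int:
        return len(self.probe_ids)

    def lookup_samples(self, ages_days, sexes) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) arrays of shape (P, n_samples) for the given demographics."""
        idx = nearest_grid_index(self.age_grid, ages_days)
        sex = np.array([_SEX_CODE[s] for s in sexes], dtype=int)
        return self.mu[:, idx, sex], self.sigma[:, idx, sex]

    def save(self, table_path: str | Path, sidecar_path: str | Path) -> None:
        """Serialize to a long TSV (probe, sex, age, mu, sigma) + JSON sidecar.

        Floats are written at full ``repr`` precision so reload is bit-exact.
        """
        G = len(self.age_grid)
        P = len(self.probe_ids)
        with Path(table_path).open("w") as fh:
            fh.write("probe_id\tsex\tage_days\tmu\tsigma\n")
            for i, pid in enumerate(self.probe_ids):
                for s_i, s in enumerate(("F", "M")):
                    for g in range(G):
                        fh.write(
                            f"{pid}\t{s}\t{self.age_grid[g]}\t"
                            f"{float(self.mu[i, g, s_i])!r}\t{float(self.sigma[i, g, s_i])!r}\n"
                        )
        sidecar = {
            "probe_ids": self.probe_ids,
            "n_grid": G,
            "global_mu": {p: repr(float(self.global_mu[i])) for i, p in enumerate(self.probe_ids)},
            "global_sigma": {
                p: repr(float(self.global_sigma[i])) for i, p in enumerate(self.probe_ids)
            },
            "diagnostics": {
                p: {
                    "n_controls": self._by_id[p].diagnostics.n_controls,
                    "converged": self._by_id[p].diagnostics.converged,
                    "effective_df": self._by_id[p].diagnostics.effective_df,
                    "fallback": self._by_id[p].diagnostics.fallback,
                }
                for p in self.probe_ids
            },
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))
        del P

    @classmethod
    def load(cls, table_path: str | Path, sidecar_path: str | Path) -> "ReferenceModel":
        sidecar = json.loads(Path(sidecar_path).read_text())
        df = pd.read_csv(
            table_path,
            sep="\t",
            dtype={"probe_id": str, "sex": str},
            float_precision="round_trip",
        )
        probes: list[ProbeReferenceModel] = []
        for pid in sidecar["probe_ids"]:
            sub = df[df["probe_id"] == pid]
            grid = np.sort(sub["age_days"].unique())
            mu = np.empty((len(grid), 2))
            sigma = np.empty((len(grid), 2))
            for s_i, s in enumerate(("F", "M")):
                block = sub[sub["sex"] == s].sort_values("age_days")
                mu[:, s_i] = block["mu"].to_numpy()
                sigma[:, s_i] = block["sigma"].to_numpy()
            diag = sidecar["diagnostics"][pid]
            probes.append(
                ProbeReferenceModel(
                    probe_id=pid,
                    age_grid=grid,
                    mu=mu,
                    sigma=sigma,
                    global_stats=GlobalStats(
                        float(sidecar["global_mu"][pid]), float(sidecar["global_sigma"][pid])
                    ),
                    diagnostics=FitDiagnostics(
                        diag["n_controls"],
                        diag["converged"],
                        diag["effective_df"],
                        diag["fallback"],
                    ),
                )
            )
        return cls(probes)


def fit_reference_model(
    beta: BetaMatrix,
    samples: Sequence[SampleRecord],
    *,
    controls_only: bool = True,
    train_only: bool = True,
    settings: FitSettings | None = None,
    epsilon: float = 1e-6,
) -> ReferenceModel:
    """Fit every probe's reference model from a cohort's control samples.

    Controls are samples with ``class_label == "Normal"`` and (when splits are
    assigned and ``train_only``) ``split == "train"``.
    """
    controls = [s for s in samples if (not controls_only) or s.class_label == "Normal"]
    if train_only and any(s.split != "unassigned" for s in controls):
        controls = [s for s in controls if s.split == "train"]
    if len(controls) < 2:
        raise ValidationError("need at least 2 control samples to fit a reference model")
    idx = beta.sample_indices([s.sample_id for s in controls])
    values = np.clip(beta.values[:, idx], epsilon, 1.0 - epsilon)
    X = logit(values)
    ages = [s.age_days for s in controls]
    sexes = [s.sex for s in controls]
    probes = [
        fit_probe_model(X[i], ages, sexes, probe_id=pid, settings=settings)
        for i, pid in enumerate(beta.probe_ids)
    ]
    return ReferenceModel(probes)
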