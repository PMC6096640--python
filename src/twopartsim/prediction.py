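"""Ridge-regression genomic prediction with heterogeneous error variance.

The model is the standard random-marker-effects ridge (RR-BLUP):

    y_j = mu + x_j . beta + e_j,   beta ~ N(0, sigma_b^2 I),
    e_j ~ N(0, sigma_e^2 / w_j),

where ``w_j`` is a per-record weight expressing the effective number of
replicates behind the phenotype (later trial stages are better replicated
and get larger weights).  The variance ratio lambda = sigma_e^2/sigma_b^2
is estimated by REML, profiled down to a one-dimensional optimisation over
log(lambda) after an eigendecomposition of the weighted marker
cross-product matrix.  The intercept is the only fixed effect and is
absorbed by weighted centring, which is what makes the profiled
log-likelihood a REML rather than an ML criterion.

The training set is append-only and retrained once per simulated year; it
maintains running cross-products so that yearly retraining costs are
dominated by a single m x m eigendecomposition rather than by the evergrowing
number of records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genome import HaplotypePopulation

__all__ = [
    "TrainingSet",
    "PredictionModel",
    "EstimationError",
    "train",
    "predict",
    "accuracy",
]

DEFAULT_STAGE_WEIGHTS = {
    "headrow": 1.0,
    "preliminary": 2.0,
    "advanced": 4.0,
    "elite": 8.0,
}


class EstimationError(RuntimeError):
    """Variance components could not be estimated (degenerate system)."""


class TrainingSet:
    """Append-only genotype/phenotype records with per-record weights.

    Sufficient statistics (Z'WZ, Z'Wy, Z'w, and weighted scalar sums) are
    updated incrementally on append; raw records are kept for export and
    inspection.
    """

    def __init__(self, n_markers: int):
        if n_markers < 1:
            raise ValueError("need at least one marker")
        self.n_markers = int(n_markers)
        self._ids: list = []
        self._year: list = []
        self._stage: list = []
        self._y: list = []
        self._w: list = []
        self._Z_chunks: list[np.ndarray] = []
        # running cross-products
        self._A = np.zeros((n_markers, n_markers))
        self._b = np.zeros(n_markers)
        self._c = np.zeros(n_markers)
        self._sw = 0.0
        self._swy = 0.0
        self._swyy = 0.0
        self._n = 0

    # -- growth ------------------------------------------------------------
    def add_records(self, ids, dosages, phenotypes, weights, year, stage) -> None:
        """Append a batch of records.  ``year``/``stage`` may be scalars."""
        Z = np.asarray(dosages, dtype=np.float64)
        y = np.asarray(phenotypes, dtype=np.float64)
        if Z.ndim != 2 or Z.shape[1] != self.n_markers:
            raise ValueError("marker dimension must stay constant")
        n = Z.shape[0]
        if n == 0:
            return
        w = np.broadcast_to(np.asarray(weights, dtype=np.float64), (n,)).copy()
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if y.shape != (n,):
            raise ValueError("one phenotype per record required")
        years = np.broadcast_to(np.asarray(year), (n,))
        if self._year and years.min() < max(self._year):
            raise ValueError("records are append-only; years must not decrease")
        stages = np.broadcast_to(np.asarray(stage), (n,))
        self._ids.extend(np.asarray(ids).tolist())
        self._year.extend(years.tolist())
        self._stage.extend(stages.tolist())
        self._y.extend(y.tolist())
        self._w.extend(w.tolist())
        self._Z_chunks.append(Z.astype(np.float32))
        Zw = Z * w[:, None]
        self._A += Z.T @ Zw
        self._b += Zw.T @ y
        self._c += Z.T @ w
        self._sw += w.sum()
        self._swy += float(w @ y)
        self._swyy += float(w @ (y * y))
        self._n += n

    @property
    def n_records(self) -> int:
        return self._n

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self._year)

    def phenotypes(self) -> np.ndarray:
        return np.asarray(self._y)

    def weights(self) -> np.ndarray:
        return np.asarray(self._w)

    def genotypes(self) -> np.ndarray:
        if not self._Z_chunks:
            return np.empty((0, self.n_markers))
        return np.concatenate(self._Z_chunks, axis=0).astype(np.float64)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "id": self._ids,
                "year": self._year,
                "stage": self._stage,
                "weight": self._w,
                "phenotype": self._y,
            }
        )
        Z = self.genotypes()
        for j in range(self.n_markers):
            df[f"m{j}"] = Z[:, j]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingSet":
        df = pd.read_csv(path)
        mcols = [c for c in df.columns if c.startswith("m")]
        ts = cls(len(mcols))
        for year in sorted(df["year"].unique()):
            sub = df[df["year"] == year]
            ts.add_records(
                sub["id"].to_numpy(),
                sub[mcols].to_numpy(dtype=float),
                sub["phenotype"].to_numpy(dtype=float),
                sub["weight"].to_numpy(dtype=float),
                year,
                sub["stage"].to_numpy(),
            )
        return ts


def update_training(ts: TrainingSet, new_records: dict | None) -> TrainingSet:
    """Grow the training set in place with one year's trial records.

    ``new_records`` maps the keyword arguments of
    :meth:`TrainingSet.add_records`; an empty/None batch is a no-op.
    Returns the same (mutated) set for chaining.
    """
    if new_records:
        ts.add_records(**new_records)
    return ts


@dataclass(frozen=True)
class PredictionModel:
    """Fitted marker effects with the variance components behind them."""

    marker_effects: np.ndarray
    intercept: float
    var_marker: float
    var_residual: float
    lambda_: float

    def __post_init__(self):
        if self.var_marker < 0 or self.var_residual < 0:
            raise ValueError("variance components must be non-negative")


def _reml_profile(theta, u2, r0, n_eff):
    """Return f(log lambda): -2 * profiled REML log-likelihood (up to a
    constant).  ``theta`` are non-zero eigenvalues of the centred Z'WZ,
    ``u2`` the squared rotated data, ``r0`` the residual data mass."""

    def f(loglam):
        lam = np.exp(loglam)
        denom = theta + lam
        ss = float(np.sum(u2 / denom) + r0 / lam)
        sigma_b2 = ss / n_eff
        if sigma_b2 <= 0:
            return np.inf
        return (
            float(np.sum(np.log(denom)))
            + (n_eff - theta.size) * loglam
            + n_eff * np.log(sigma_b2)
        )

    return f


def train(ts: TrainingSet, lambda_: float | None = None) -> PredictionModel:
    """Fit the weighted ridge model; REML for lambda unless it is given.

    Raises :class:`EstimationError` when the system is degenerate (all
    phenotypes identical after weighting); callers in the yearly simulation
    loop fall back to the previous year's model.
    """
    if ts.n_records < 2:
        raise EstimationError("need at least two records")
    yty = ts._swyy - ts._swy**2 / ts._sw
    if yty <= 1e-12 * max(1.0, abs(ts._swyy)):
        raise EstimationError("phenotypes carry no variation")
    m = ts.n_markers
    # weighted centring (absorbs the intercept)
    A_c = ts._A - np.outer(ts._c, ts._c) / ts._sw
    r = ts._b - ts._c * (ts._swy / ts._sw)
    evals, V = np.linalg.eigh(A_c)
    tol = max(evals.max(), 0.0) * 1e-12 + 1e-12
    nz = evals > tol
    theta = evals[nz]
    if theta.size == 0:
        raise EstimationError("no marker variation in the training set")
    Vr = V.T @ r
    u = Vr[nz] / np.sqrt(theta)
    u2 = u * u
    r0 = max(yty - float(u2.sum()), 0.0)
    n_eff = ts.n_records - 1  # intercept absorbed
    if lambda_ is None:
        obj = _reml_profile(theta, u2, r0, n_eff)
        res = minimize_scalar(obj, bounds=(-18.0, 18.0), method="bounded",
                              options={"xatol": 1e-8})
        lam = float(np.exp(res.x))
    else:
        if lambda_ < 0:
            raise ValueError("lambda must be non-negative")
        lam = float(lambda_)
    # ridge solution through the eigenbasis
    shrink = np.zeros_like(evals)
    shrink[nz] = 1.0 / (theta + lam)
    beta = V @ (shrink * Vr)
    mu = (ts._swy - float(ts._c @ beta)) / ts._sw
    ss = float(np.sum(u2 / (theta + lam)) + (r0 / lam if lam > 0 else 0.0))
    sigma_b2 = ss / n_eff
    sigma_e2 = lam * sigma_b2
    return PredictionModel(beta, float(mu), sigma_b2, sigma_e2, lam)


def predict(model: PredictionModel, pop) -> np.ndarray:
    """GEBV = intercept + marker dosages . effects.

    ``pop`` may be a :class:`HaplotypePopulation` (marker loci taken from
    its map) or a plain dosage matrix.
    """
    if isinstance(pop, HaplotypePopulation):
        Z = pop.marker_dosages().astype(np.float64)
    else:
        Z = np.asarray(pop, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[1] != model.marker_effects.size:
        raise ValueError(
            f"marker mismatch: model has {model.marker_effects.size}, "
            f"data has {Z.shape[1] if Z.ndim == 2 else '?'}"
        )
    return model.intercept + Z @ model.marker_effects


def accuracy(gebv: np.ndarray, true_values: np.ndarray) -> float:
    """Pearson correlation between predicted and true genetic values.

    Returns ``nan`` (missing, not zero) when either vector is constant.
    """
    g = np.asarray(gebv, dtype=np.float64)
    t = np.asarray(true_values, dtype=np.float64)
    if g.shape != t.shape or g.size < 3:
        raise ValueError("need at least three paired values")
    if np.ptp(g) == 0 or np.ptp(t) == 0:
        return float("nan")
    return float(np.corrcoef(g, t)[0, 1])
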