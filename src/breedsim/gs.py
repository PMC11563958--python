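"""Ridge-regression BLUP (RR-BLUP) genomic prediction.

The model is ``y = 1 beta + Z u + e`` with ``Z`` the {-1, 0, +1} marker
matrix, ``u ~ N(0, sigma2_u I)`` and ``e ~ N(0, sigma2_e I)``.  The two
variance components are estimated by restricted maximum likelihood using
the spectral decomposition of the marker relationship matrix ``Z Z'``
projected free of the intercept, so each candidate ridge parameter
``lambda = sigma2_e / sigma2_u`` is evaluated in O(n) after one O(n^3)
eigendecomposition.  Marker effects then come from the equivalent-model
identity ``u = Z' (Z Z' + lambda I)^-1 (y - 1 beta)`` with the
generalized-least-squares intercept.

Training populations are either sampled within a cohort (every family
guaranteed at least one line) or accumulated across cohorts in a sliding
window for between-cohort prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .genome import Population, as_rng

__all__ = [
    "GSModel",
    "TrainingPopulation",
    "marker_matrix",
    "fit_rrblup",
    "solve_ridge",
    "predict_gebv",
    "sample_training_set",
    "update_between_cohort_tp",
    "write_model_tsv",
    "read_model_tsv",
]

_LOG_LAMBDA_BOUNDS = (-8.0, 8.0)
_GRID_POINTS = 81


@dataclass
class GSModel:
    """A fitted RR-BLUP model."""

    intercept: float                 # beta
    marker_effects: np.ndarray       # (m,) u
    ridge_parameter: float           # lambda = sigma2_e / sigma2_u
    sigma2_u: float = np.nan
    sigma2_e: float = np.nan
    degenerate: bool = False

    @property
    def n_markers(self) -> int:
        return self.marker_effects.size


def marker_matrix(pop: Population, marker_idx) -> np.ndarray:
    """Scaled marker dosages {-1, 0, +1} as float64, shape (n, m)."""
    return pop.dosage(marker_idx).astype(np.float64)


def fit_rrblup(Z: np.ndarray, y: np.ndarray) -> GSModel:
    """Fit RR-BLUP with the ridge parameter estimated by REML.

    Degenerate inputs (no phenotypic variance, or an all-constant marker
    matrix) yield a flagged null model with ``u = 0`` and
    ``beta = mean(y)``.
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    if Z.shape[0] != n:
        raise ValueError("Z row count must match the phenotype vector")
    if n < 2:
        raise ValueError("at least two training lines are required")
    if np.ptp(y) == 0 or np.all(np.ptp(Z, axis=0) == 0):
        return GSModel(intercept=float(np.mean(y)),
                       marker_effects=np.zeros(Z.shape[1]),
                       ridge_parameter=np.inf, degenerate=True)

    K = Z @ Z.T
    # eigenstructure of S (K + I) S, S the centering projector: the
    # intercept direction appears as the single ~0 eigenvalue
    B = K + np.eye(n)
    col = B.mean(axis=0)
    tot = B.mean()
    B = B - col[None, :] - col[:, None] + tot
    vals, vecs = eigh(B)
    xi = np.clip(vals[1:] - 1.0, 0.0, None)  # drop the intercept eigenvalue
    eta = vecs[:, 1:].T @ y
    eta2 = eta**2
    nq = n - 1

    def neg_reml(log_lam: float) -> float:
        d = xi + np.exp(log_lam)
        return float(nq * np.log(eta2 @ (1.0 / d)) + np.log(d).sum())

    grid = np.linspace(*_LOG_LAMBDA_BOUNDS, _GRID_POINTS)
    best = int(np.argmin([neg_reml(g) for g in grid]))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    res = minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))

    sigma2_u = float(eta2 @ (1.0 / (xi + lam)) / nq)
    sigma2_e = lam * sigma2_u
    beta, u = _solve_at_lambda(Z, y, K, lam)
    return GSModel(intercept=beta, marker_effects=u, ridge_parameter=lam,
                   sigma2_u=sigma2_u, sigma2_e=sigma2_e)


def solve_ridge(Z: np.ndarray, y: np.ndarray, ridge_parameter: float):
    """GLS intercept and marker effects at a fixed ridge parameter.

    Returns ``(beta, u)``; equivalent to solving the mixed-model
    equations ``(Z'Z + lambda I) u = Z'(y - 1 beta)``.
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    return _solve_at_lambda(Z, y, Z @ Z.T, float(ridge_parameter))


def _solve_at_lambda(Z, y, K, lam):
    n = y.size
    V = K + lam * np.eye(n)
    c, low = cho_factor(V, lower=True)
    vinv_y = cho_solve((c, low), y)
    vinv_1 = cho_solve((c, low), np.ones(n))
    beta = float(vinv_1 @ y / vinv_1.sum())
    u = Z.T @ (vinv_y - beta * vinv_1)
    return beta, u


def predict_gebv(model: GSModel, Z: np.ndarray) -> np.ndarray:
    """GEBV_i = beta + z_i' u."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[1] != model.n_markers:
        raise ValueError(
            f"marker count mismatch: model has {model.n_markers}, "
            f"Z has {Z.shape[1]} columns"
        )
    return model.intercept + Z @ model.marker_effects


def sample_training_set(pop: Population, n: int, seed) -> np.ndarray:
    """Random training sample constrained to cover every family.

    One line is drawn uniformly from each family first; the remaining
    slots are filled uniformly without replacement.  Returns row indices
    into ``pop``.
    """
    rng = as_rng(seed)
    families = np.unique(pop.family)
    if n > pop.n:
        raise ValueError("training set larger than the population")
    if n < families.size:
        raise ValueError(
            f"cannot cover {families.size} families with {n} lines"
        )
    picked = []
    for fam in families:
        rows = np.flatnonzero(pop.family == fam)
        picked.append(rng.choice(rows))
    picked = np.array(picked)
    rest = np.setdiff1d(np.arange(pop.n), picked)
    extra = rng.choice(rest, size=n - picked.size, replace=False)
    return np.sort(np.concatenate([picked, extra]))


@dataclass
class CohortData:
    """Marker genotypes and trial-mean phenotypes of one training cohort."""

    tag: int
    Z: np.ndarray
    y: np.ndarray


@dataclass
class TrainingPopulation:
    """Sliding-window multi-cohort training data for between-cohort GS."""

    cohorts: list = field(default_factory=list)
    window: int = 3

    @property
    def n(self) -> int:
        return sum(c.y.size for c in self.cohorts)

    @property
    def Z(self) -> np.ndarray:
        return np.concatenate([c.Z for c in self.cohorts], axis=0)

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([c.y for c in self.cohorts])

    @property
    def cohort_tags(self):
        return [c.tag for c in self.cohorts]

    def copy(self) -> "TrainingPopulation":
        return TrainingPopulation(
            cohorts=[CohortData(c.tag, c.Z, c.y) for c in self.cohorts],
            window=self.window,
        )


def write_model_tsv(path, model: GSModel) -> None:
    """Dump a fitted model (beta, lambda, per-marker u) as TSV."""
    with open(path, "w") as fh:
        fh.write(f"# intercept\t{float(model.intercept)!r}\n")
        fh.write(f"# ridge_parameter\t{float(model.ridge_parameter)!r}\n")
        fh.write("marker\tu\n")
        for j, u in enumerate(model.marker_effects):
            fh.write(f"{j}\t{float(u)!r}\n")


def read_model_tsv(path) -> GSModel:
    """Re-import a model written by :func:`write_model_tsv`."""
    with open(path) as fh:
        intercept = float(fh.readline().split("\t")[1])
        lam = float(fh.readline().split("\t")[1])
        fh.readline()
        u = np.array([float(line.split("\t")[1]) for line in fh])
    return GSModel(intercept=intercept, marker_effects=u, ridge_parameter=lam)


def update_between_cohort_tp(tp: TrainingPopulation,
                             new_cohort: CohortData) -> TrainingPopulation:
    """Append a cohort; drop the oldest beyond the sliding window."""
    if tp.cohorts and tp.cohorts[0].Z.shape[1] != new_cohort.Z.shape[1]:
        raise ValueError("marker panels differ between cohorts")
    cohorts = tp.cohorts + [new_cohort]
    if len(cohorts) > tp.window:
        cohorts = cohorts[-tp.window:]
    return TrainingPopulation(cohorts=cohorts, window=tp.window)
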