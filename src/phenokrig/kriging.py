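"""Simple kriging point prediction and grid interpolation.

Simple kriging assumes a known, constant stationary mean m and predicts

    Z*(v) = sum_i lambda_i Z(x_i) + m * (1 - sum_i lambda_i),

where the weights solve the covariance system C lambda = c with
C_ij = Cov(d(x_i, x_j)) and c_i = Cov(d(x_i, v)), and the covariance derives
from the fitted variogram as Cov(h) = (C0 + C) - gamma(h), i.e.
Cov(0) = C0 + C and Cov(h > 0) decays to 0.  The kriging variance
(C0 + C) - lambda' c depends only on the geometry and the model, never on
the observed values.

The datum convention keeps the nugget in Cov(0): data are treated as
error-free, so prediction at a sampled location reproduces the sample exactly
only when C0 = 0.  ``nugget_as_error=True`` instead treats C0 as measurement
error (filtered kriging), removing it from the right-hand side at lag 0.

Networks here hold at most a dozen sites, so every prediction uses the full
neighbourhood and the SPD system is solved by a direct dense Cholesky
factorisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist, squareform, pdist

from .data import PHASE_MAX, PHASE_MIN, PhenoDataset, PhenoGrid
from .variogram import VariogramModel

__all__ = ["KrigingEstimate", "simple_kriging", "krige_grid", "stationary_mean"]

#: tolerance below which a (numerically) negative kriging variance is clipped to 0
VARIANCE_TOL = 1e-10


@dataclass
class KrigingEstimate:
    """Simple-kriging prediction at one location."""

    location: tuple[float, float]
    estimate: float
    variance: float
    weights: np.ndarray
    weight_sum: float


def stationary_mean(dataset: PhenoDataset, policy: str = "mean") -> float:
    """The known mean m used by simple kriging (arithmetic mean or median)."""
    if policy == "mean":
        return float(np.mean(dataset.values))
    if policy == "median":
        return float(np.median(dataset.values))
    raise ValueError(f"unknown mean policy {policy!r}")


def _covariance_matrix(
    dataset: PhenoDataset, model: VariogramModel, nugget_as_error: bool
) -> np.ndarray:
    xy = dataset.coords()
    D = squareform(pdist(xy))
    # data-data covariance always keeps the nugget at lag 0; under
    # nugget_as_error only the target-data covariances (the RHS) drop it
    C = np.asarray(model.covariance(D), dtype=float)
    if model.nugget == 0.0:
        dup = np.argwhere((D == 0) & ~np.eye(dataset.n, dtype=bool))
        if dup.size:
            i, j = dup[0]
            raise ValueError(
                "singular kriging system: points "
                f"{dataset.points[i].id!r} and {dataset.points[j].id!r} share "
                "coordinates and the model has zero nugget"
            )
    return C


def _factorize(C: np.ndarray, dataset: PhenoDataset):
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(f"singular kriging covariance matrix: {exc}") from exc


def simple_kriging(
    target: tuple[float, float],
    dataset: PhenoDataset,
    model: VariogramModel,
    mean: float | None = None,
    nugget_as_error: bool = False,
) -> KrigingEstimate:
    """Predict the phase at ``target`` from one date's observations.

    ``mean`` defaults to the dataset's arithmetic mean.
    """
    if dataset.n < 1:
        raise ValueError("simple kriging needs at least one datum")
    m = stationary_mean(dataset) if mean is None else float(mean)
    C = _covariance_matrix(dataset, model, nugget_as_error)
    factor = _factorize(C, dataset)
    d = cdist(np.atleast_2d(np.asarray(target, dtype=float)), dataset.coords())[0]
    c = np.asarray(model.covariance(d), dtype=float)
    if nugget_as_error:
        c[d == 0] = model.sill - model.nugget
    lam = cho_solve(factor, c)
    est = float(lam @ dataset.values + m * (1.0 - lam.sum()))
    var = float(model.sill - lam @ c)
    if var < 0:
        if var < -VARIANCE_TOL:
            warnings.warn(
                f"kriging variance {var:.3e} clipped to 0 (numerical)", stacklevel=2
            )
        var = 0.0
    return KrigingEstimate(
        location=(float(target[0]), float(target[1])),
        estimate=est,
        variance=var,
        weights=lam,
        weight_sum=float(lam.sum()),
    )


def krige_grid(
    dataset: PhenoDataset,
    model: VariogramModel,
    mean: float | None = None,
    bbox: tuple[float, float, float, float] | None = None,
    cellsize: float = 100.0,
    pad_fraction: float = 0.05,
    nugget_as_error: bool = False,
) -> PhenoGrid:
    """Simple-kriging estimate at every cell centre of a regular grid.

    ``bbox`` defaults to the data bounding box padded by ``pad_fraction`` on
    each side.  Estimates are clamped into the phase range [0, 4] after
    interpolation, with per-cell clamp flags recorded on the grid.
    """
    if dataset.n < 1:
        raise ValueError("krige_grid needs at least one datum")
    if cellsize <= 0:
        raise ValueError("cellsize must be positive")
    xy = dataset.coords()
    if bbox is None:
        xmin, ymin = xy.min(axis=0)
        xmax, ymax = xy.max(axis=0)
        px, py = pad_fraction * (xmax - xmin), pad_fraction * (ymax - ymin)
        bbox = (xmin - px, ymin - py, xmax + px, ymax + py)
    xmin, ymin, xmax, ymax = bbox
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounding box {bbox}")
    if xmax < xy[:, 0].min() or xmin > xy[:, 0].max() or \
       ymax < xy[:, 1].min() or ymin > xy[:, 1].max():
        warnings.warn("bounding box excludes all data; extrapolating", stacklevel=2)

    ncols = max(1, int(np.ceil((xmax - xmin) / cellsize)))
    nrows = max(1, int(np.ceil((ymax - ymin) / cellsize)))
    grid = PhenoGrid(
        xll=xmin, yll=ymin, cellsize=cellsize,
        values=np.zeros((nrows, ncols)),
    )
    X, Y = grid.cell_centers()
    targets = np.column_stack([X.ravel(), Y.ravel()])

    m = stationary_mean(dataset) if mean is None else float(mean)
    C = _covariance_matrix(dataset, model, nugget_as_error)
    factor = _factorize(C, dataset)
    d = cdist(dataset.coords(), targets)  # (n, ncells)
    crhs = np.asarray(model.covariance(d), dtype=float)
    if nugget_as_error:
        crhs[d == 0] = model.sill - model.nugget
    lam = cho_solve(factor, crhs)  # (n, ncells)
    est = lam.T @ dataset.values + m * (1.0 - lam.sum(axis=0))
    clamped = (est < PHASE_MIN) | (est > PHASE_MAX)
    est = np.clip(est, PHASE_MIN, PHASE_MAX)
    grid.values = est.reshape(nrows, ncols)
    grid.clamp_flags = clamped.reshape(nrows, ncols)
    return grid
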