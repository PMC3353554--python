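"""Leave-one-out cross-validation of the kriging interpolation.

Each observation is removed in turn and predicted by simple kriging from the
remaining points; the variogram model is held fixed across folds (refitting
on 6 observations is unstable and is not what desktop geostatistics packages
do by default), while the stationary mean is recomputed from the retained
values.  Interpolation quality is summarised by the ordinary least squares
regression of actual on estimated values — slope near 1 indicates
well-calibrated predictions — together with r² and the RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PhenoDataset
from .kriging import simple_kriging
from .variogram import VariogramModel, empirical_semivariogram, fit_variogram

__all__ = ["CrossValidationResult", "loo_cross_validation"]


@dataclass
class CrossValidationResult:
    point_ids: list[str]
    actual: np.ndarray
    estimated: np.ndarray
    slope: float  # the regression coefficient of actual on estimated
    intercept: float
    r2: float
    rmse: float
    degenerate: bool = False  # zero spread in the estimates: OLS undefined

    @property
    def pairs(self) -> list[tuple[str, float, float]]:
        return list(zip(self.point_ids, self.actual, self.estimated))

    @property
    def bias(self) -> float:
        """Mean(actual - estimated); 0 for unbiased interpolation."""
        return float(np.mean(self.actual - self.estimated))


def loo_cross_validation(
    dataset: PhenoDataset,
    model: VariogramModel,
    mean_policy: str = "mean",
    refit_per_fold: bool = False,
    nugget_as_error: bool = False,
) -> CrossValidationResult:
    """Leave-one-out cross-validation of simple kriging on one date.

    ``refit_per_fold=True`` re-estimates the variogram from each fold's n-1
    points (same bin settings implied by the data); the default keeps the
    model fitted on the full dataset.
    """
    if dataset.n < 4:
        raise ValueError("leave-one-out needs n >= 4 (>= 3 points per fold)")
    n = dataset.n
    actual = np.asarray(dataset.values, dtype=float)
    estimated = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        fold = PhenoDataset(
            date=dataset.date,
            points=[dataset.points[j] for j in keep],
            values=actual[keep],
        )
        fold_model = model
        if refit_per_fold:
            fold_model = fit_variogram(empirical_semivariogram(fold), kind=model.kind)
        est = simple_kriging(
            (dataset.points[i].x, dataset.points[i].y),
            fold,
            fold_model,
            mean=None if mean_policy == "mean" else np.median(actual[keep]),
            nugget_as_error=nugget_as_error,
        )
        estimated[i] = est.estimate

    rmse = float(np.sqrt(np.mean((actual - estimated) ** 2)))
    var_est = float(np.var(estimated))
    if var_est < 1e-15:
        return CrossValidationResult(
            point_ids=[p.id for p in dataset.points],
            actual=actual, estimated=estimated,
            slope=float("nan"), intercept=float("nan"), r2=float("nan"),
            rmse=rmse, degenerate=True,
        )
    cov = float(np.mean((actual - actual.mean()) * (estimated - estimated.mean())))
    slope = cov / var_est
    intercept = float(actual.mean() - slope * estimated.mean())
    var_act = float(np.var(actual))
    r2 = cov**2 / (var_est * var_act) if var_act > 0 else float("nan")
    return CrossValidationResult(
        point_ids=[p.id for p in dataset.points],
        actual=actual, estimated=estimated,
        slope=slope, intercept=intercept, r2=r2, rmse=rmse,
    )
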