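"""Empirical semivariogram estimation and bounded least-squares model fitting.

The empirical semivariogram is the classical method-of-moments estimator

    gamma_hat(h_k) = sum_{(i,j) in bin k} (z_i - z_j)^2 / (2 N(h_k)),

with pairs binned by Euclidean separation into uniform lag classes on
(0, max_lag].  Phenophase fields are very smooth in space, so the default
theoretical model is the Gaussian one,

    gamma(h) = C0 + C * (1 - exp(-(h/A0)^2)),   gamma(0) = 0,

with nugget C0, structural sill C (total sill C0 + C) and range parameter A0
(effective range sqrt(3)*A0, the lag where the model reaches ~95 % of its
sill).  Spherical and exponential alternatives are provided for comparison.
Fitting minimises the (optionally pair-count-weighted) residual sum of
squares over the retained bins under the constraints C0 >= 0, C >= 0,
A0 > 0, using deterministic multi-start bounded nonlinear least squares; the
exact pure-nugget solution is always evaluated as a candidate, so the
reported fit can never be worse than a flat model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .data import PhenoDataset

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "empirical_semivariogram",
    "gaussian_model_value",
    "model_value",
    "fit_variogram",
]

MODEL_KINDS = ("gaussian", "spherical", "exponential")


@dataclass
class EmpiricalVariogram:
    """Binned method-of-moments semivariogram estimates."""

    lags: np.ndarray  # mean pair distance per retained bin, strictly increasing
    gamma: np.ndarray  # gamma_hat per bin, phase^2
    pair_counts: np.ndarray  # N(h_k) per bin
    max_lag: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if not (len(self.lags) == len(self.gamma) == len(self.pair_counts)):
            raise ValueError("lags, gamma and pair_counts must align")
        if len(self.lags) and np.any(np.diff(self.lags) <= 0):
            raise ValueError("mean lags must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.lags)


@dataclass
class VariogramModel:
    """Fitted isotropic variogram model with its goodness-of-fit statistics."""

    kind: str
    nugget: float  # C0, phase^2
    structural_sill: float  # C, phase^2
    range_param: float  # A0, metres
    r2: float = float("nan")
    rss: float = float("nan")
    pure_nugget: bool = False  # A0 unidentifiable (flat variogram)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.nugget < 0 or self.structural_sill < 0 or self.range_param <= 0:
            raise ValueError("require C0 >= 0, C >= 0, A0 > 0")

    @property
    def sill(self) -> float:
        """Total sill C0 + C."""
        return self.nugget + self.structural_sill

    @property
    def effective_range(self) -> float:
        """Lag beyond which spatial correlation is negligible."""
        if self.kind == "gaussian":
            return float(np.sqrt(3.0) * self.range_param)
        if self.kind == "exponential":
            return 3.0 * self.range_param
        return self.range_param  # spherical: exact range

    def __call__(self, h) -> np.ndarray:
        return model_value(h, self.kind, self.nugget, self.structural_sill, self.range_param)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance Cov(h) = sill - gamma(h); Cov(0) = C0 + C."""
        return self.sill - self.__call__(h)


def gaussian_model_value(h, C0: float, C: float, A0: float) -> np.ndarray:
    """Gaussian semivariogram; 0 at h = 0, C0 + C*(1 - exp(-(h/A0)^2)) beyond."""
    return model_value(h, "gaussian", C0, C, A0)


def model_value(h, kind: str, C0: float, C: float, A0: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("lag distances must be >= 0")
    if A0 <= 0:
        raise ValueError("range parameter A0 must be > 0")
    if kind == "gaussian":
        g = C0 + C * (1.0 - np.exp(-((h / A0) ** 2)))
    elif kind == "exponential":
        g = C0 + C * (1.0 - np.exp(-h / A0))
    elif kind == "spherical":
        r = np.minimum(h / A0, 1.0)
        g = C0 + C * (1.5 * r - 0.5 * r**3)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    g = np.where(h == 0.0, 0.0, g)  # gamma(0) = 0 by definition
    return g if g.ndim else float(g)


def empirical_semivariogram(
    dataset: PhenoDataset,
    n_lags: int = 6,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Method-of-moments semivariogram of one date's phase field.

    Pairs at Euclidean distance d in ((k-1)*w, k*w], w = max_lag/n_lags, enter
    bin k; empty bins are dropped and each retained bin reports the mean pair
    distance.  By default max_lag is the maximum pairwise distance, so every
    pair is used (the sparse networks here have at most 45 pairs).
    """
    if dataset.n < 3:
        raise ValueError("semivariogram needs at least 3 points")
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    xy = dataset.coords()
    d = pdist(xy)  # i<j lexicographic pair order
    z = dataset.values
    n = dataset.n
    iu, ju = np.triu_indices(n, k=1)
    sq = (z[iu] - z[ju]) ** 2

    if max_lag is None:
        max_lag = float(d.max())
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")

    width = max_lag / n_lags
    keep = (d > 0) & (d <= max_lag)
    # bin k-1 holds d in ((k-1)w, kw]
    bin_idx = np.ceil(d[keep] / width).astype(int) - 1
    bin_idx = np.clip(bin_idx, 0, n_lags - 1)

    lags, gammas, counts = [], [], []
    for k in range(n_lags):
        sel = bin_idx == k
        if not sel.any():
            continue
        lags.append(float(np.mean(d[keep][sel])))
        gammas.append(float(np.mean(sq[keep][sel]) / 2.0))
        counts.append(int(sel.sum()))
    if not lags:
        raise ValueError("no point pairs within (0, max_lag]")
    if len(lags) == 1 and n_lags > 1:
        warnings.warn("all pairs fell in a single lag bin", stacklevel=2)
    return EmpiricalVariogram(
        lags=np.array(lags), gamma=np.array(gammas),
        pair_counts=np.array(counts), max_lag=max_lag,
    )


def _rss(params, emp: EmpiricalVariogram, kind: str, w: np.ndarray) -> float:
    C0, C, A0 = params
    resid = emp.gamma - model_value(emp.lags, kind, C0, C, A0)
    return float(np.sum(w * resid**2))


def fit_variogram(
    emp: EmpiricalVariogram,
    kind: str = "gaussian",
    weighting: str = "none",
) -> VariogramModel:
    """Fit a 3-parameter isotropic model to binned semivariogram estimates.

    ``weighting="pairs"`` weights each bin's squared residual by its pair
    count N(h_k); the default is the unweighted RSS.  r² is 1 - RSS/TSS with
    TSS the (weighted) spread of gamma_hat around its (weighted) mean; for a
    flat variogram TSS is 0, the pure-nugget solution is returned with r²
    undefined (NaN) and ``pure_nugget`` set.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if weighting not in ("none", "pairs"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if emp.n_bins < 3:
        raise ValueError(
            f"need >= 3 non-empty bins for a 3-parameter fit, have {emp.n_bins}"
        )
    w = emp.pair_counts.astype(float) if weighting == "pairs" else np.ones(emp.n_bins)

    wmean = float(np.average(emp.gamma, weights=w))
    tss = float(np.sum(w * (emp.gamma - wmean) ** 2))

    # exact pure-nugget candidate: best flat model gamma ≡ C0
    nugget_rss = tss
    best = (max(wmean, 0.0), 0.0, emp.max_lag, nugget_rss, True)

    sill0 = float(emp.gamma.max())
    if sill0 > 0 and tss > 0:
        sw = np.sqrt(w)

        def resid(p):
            C0, C, A0 = p
            return sw * (emp.gamma - model_value(emp.lags, kind, C0, C, A0))

        lo = [0.0, 0.0, 1e-6 * emp.max_lag]
        hi = [np.inf, np.inf, np.inf]
        for frac in (0.25, 0.5, 1.0):
            x0 = [0.0, sill0, frac * emp.max_lag]
            try:
                sol = least_squares(
                    resid, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if rss < best[3] - 1e-15 * max(1.0, best[3]):
                C0, C, A0 = sol.x
                best = (float(C0), float(C), float(max(A0, lo[2])), rss, False)

    C0, C, A0, rss, flat = best
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    if tss > 0:
        r2 = float(np.clip(r2, 0.0, 1.0))
    return VariogramModel(
        kind=kind, nugget=C0, structural_sill=C, range_param=A0,
        r2=r2, rss=rss, pure_nugget=flat,
    )
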