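"""Sparsity- and deformation-related summaries of an estimated transformation.

Two scalar metrics are derived from the estimated matrix:

* RDD — rate of decay of the *density curve*.  The matrix is normalised
  by its maximum absolute value; d(P) is the fraction of entries whose
  absolute value strictly exceeds the threshold P in [0, 1].  An
  exponential a*exp(b*P) is fitted to d and RDD is its exponent b.
  Steeper (more negative) decay indicates a sparser underlying
  transformation; the max-abs normalisation makes RDD invariant to
  rescaling the matrix.

* RDSV — rate of decay of the singular-value spectrum, the exponent b of
  a*exp(b*k) fitted to the descending singular values against their
  integer index k = 1..P.  RDSV = 0 means a uniform spectrum (the mapping
  deforms all input directions equally, as a rotation would); large |b|
  means strongly anisotropic amplification/compression.

A polar decomposition T = P1 R = R P2 (R orthogonal, P1/P2 symmetric PSD
with eigenvalues equal to the singular values of T) is provided as a
geometric diagnostic for square transformations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DensityCurve",
    "DecayFit",
    "SVSpectrum",
    "PolarParts",
    "DecayFitError",
    "default_thresholds",
    "density_curve",
    "fit_exp_decay",
    "rdd",
    "singular_spectrum",
    "rdsv",
    "polar_decompose",
]


class DecayFitError(RuntimeError):
    """Exponential decay fit failed to converge."""


@dataclass(frozen=True)
class DensityCurve:
    thresholds: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, float)
        d = np.asarray(self.density, float)
        if t.shape != d.shape:
            raise ValueError("thresholds and density differ in length")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "density", d)


@dataclass(frozen=True)
class DecayFit:
    a: float
    b: float
    fit_residual: float


@dataclass(frozen=True)
class SVSpectrum:
    values: np.ndarray  # descending, non-negative

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("spectrum must be a non-empty vector")
        if np.any(v < 0) or np.any(np.diff(v) > 1e-12 * max(1.0, v[0])):
            raise ValueError("singular values must be non-negative and descending")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PolarParts:
    R: np.ndarray
    P1: np.ndarray
    P2: np.ndarray


def default_thresholds(n: int = 101) -> np.ndarray:
    """Evenly spaced threshold grid on [0, 1]."""
    return np.linspace(0.0, 1.0, n)


def density_curve(
    T_hat: np.ndarray, thresholds: np.ndarray | None = None
) -> DensityCurve:
    """Fraction of max-abs-normalised entries strictly exceeding each threshold.

    d(0) = 1 when no entry is exactly zero and d(1) = 0 always (the
    comparison is strict, and the largest normalised magnitude is 1).  A
    d(0) < 1 therefore flags exact zeros in the matrix.
    """
    T = np.asarray(T_hat, float)
    thr = default_thresholds() if thresholds is None else np.asarray(thresholds, float)
    if np.any(thr < 0) or np.any(thr > 1) or np.any(np.diff(thr) < 0):
        raise ValueError("thresholds must be sorted within [0, 1]")
    absvals = np.abs(T).ravel()
    peak = absvals.max()
    if peak == 0:
        raise ValueError("all-zero matrix: max-abs normalisation undefined")
    absvals = absvals / peak
    # d(P) = #{|t| > P} / (N_X N_Y) for all P at once via a sorted scan
    absvals.sort()
    n = absvals.size
    counts = n - np.searchsorted(absvals, thr, side="right")
    return DensityCurve(thresholds=thr, density=counts / n)


def fit_exp_decay(xs: np.ndarray, ys: np.ndarray) -> DecayFit:
    """Least-squares fit of a*exp(b*x), a > 0, with fixed initialisation.

    Started at ``a = max(ys[0], tiny)``, ``b = -1`` so repeated fits of the
    same data are bit-identical.  Raises :class:`DecayFitError` when the
    optimiser does not converge.
    """
    x = np.asarray(xs, float)
    y = np.asarray(ys, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (x, y) points")
    if np.any(y < 0):
        raise ValueError("ordinates must be non-negative")
    a0 = float(y[0]) if y[0] > 0 else max(float(y.max()), 1e-12)
    try:
        popt, _ = curve_fit(
            lambda t, a, b: a * np.exp(b * t),
            x,
            y,
            p0=(a0, -1.0),
            bounds=([1e-300, -np.inf], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise DecayFitError(f"exponential fit did not converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    resid = float(np.sum((y - a * np.exp(b * x)) ** 2))
    return DecayFit(a=a, b=b, fit_residual=resid)


def rdd(T_hat: np.ndarray, thresholds: np.ndarray | None = None) -> float:
    """Rate of decay of the density curve (exponent b of the fitted a*exp(bP))."""
    curve = density_curve(T_hat, thresholds)
    return fit_exp_decay(curve.thresholds, curve.density).b


def singular_spectrum(
    T_hat: np.ndarray,
    rank_x: int | None = None,
    rank_y: int | None = None,
) -> SVSpectrum:
    """Descending singular values, truncated to P = min(rank_x, rank_y).

    The ranks are those of the pattern matrices the transformation was
    estimated from; when omitted the full min(N_Y, N_X) spectrum is kept.
    """
    T = np.asarray(T_hat, float)
    sv = np.linalg.svd(T, compute_uv=False)
    p = sv.size
    for r in (rank_x, rank_y):
        if r is not None:
            if r < 1:
                raise ValueError("rank must be >= 1")
            p = min(p, int(r))
    return SVSpectrum(values=sv[:p])


def rdsv(
    T_hat: np.ndarray,
    rank_x: int | None = None,
    rank_y: int | None = None,
) -> float:
    """Rate of decay of the singular values against their index 1..P."""
    spec = singular_spectrum(T_hat, rank_x, rank_y)
    k = np.arange(1, spec.values.size + 1, dtype=float)
    return fit_exp_decay(k, spec.values).b


def polar_decompose(T: np.ndarray) -> PolarParts:
    """Polar factors of a square matrix: T = P1 R = R P2.

    Built from the SVD T = U S V': R = U V', P1 = U S U', P2 = V S V'.
    R is orthogonal; P1 and P2 are the symmetric PSD square roots of TT'
    and T'T, whose eigenvalues coincide with the singular values of T.
    """
    Tm = np.asarray(T, float)
    if Tm.ndim != 2 or Tm.shape[0] != Tm.shape[1]:
        raise ValueError(f"polar decomposition needs a square matrix, got {Tm.shape}")
    U, s, Vt = np.linalg.svd(Tm)
    R = U @ Vt
    P1 = (U * s) @ U.T
    P2 = (Vt.T * s) @ Vt
    return PolarParts(R=R, P1=P1, P2=P2)
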