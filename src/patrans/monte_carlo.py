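"""Monte Carlo calibration of the sparsity and deformation metrics.

The decay metrics (RDD, RDSV) of a ridge-estimated transformation depend
not only on the true transformation but also on the noise level, so a
raw decay value cannot be read as a sparsity percentage or singular-value
decay directly.  The calibration procedure simulates ground-truth
transformations at known levels — percentages of exactly-zero entries for
sparsity, exponential singular-value decays b for deformation — mixes
their outputs with Gaussian noise at a grid of fractions gamma, re-runs
the same ridge estimate (at the lam selected on the data under study),
and records the mean (decay, GOF) per (level, gamma) cell.  An observed
(decay, GOF) point is then bracketed between the two adjacent simulated
levels whose calibration curves enclose it.

Synthetic output patterns follow the noise-mixing model

    Y_tilde = (1 - gamma) T X / ||T X||_F + gamma E / ||E||_F,

with E i.i.d. standard normal, after which every stimulus column is
demeaned and standardised; gamma in [0, 1) is the relative noise
strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .patterns_io import PatternMatrix, znormalise
from .ridge_core import _RidgeEigen, _values, select_lambda
from .transform_metrics import (
    default_thresholds,
    density_curve,
    fit_exp_decay,
)

__all__ = [
    "SimulationConfig",
    "CalibrationGrid",
    "BracketEstimate",
    "simulate_sparse_transform",
    "simulate_decay_transform",
    "mix_noise",
    "simulate_pattern_pair",
    "calibrate",
    "bracket_estimate",
]

Kind = Literal["sparsity", "deformation"]


@dataclass(frozen=True)
class SimulationConfig:
    """Levels, noise grid and simulation counts for a calibration run.

    Defaults are the study conditions: sparsity levels 50-99%, singular
    value decays {0, -0.01, -0.1, -1}, noise fractions gamma from 0 to
    0.9 in steps of 0.1, and 1000 simulations per (level, gamma) cell.
    """

    sparsity_levels: tuple[float, ...] = (50.0, 60.0, 70.0, 80.0, 90.0, 99.0)
    decay_levels: tuple[float, ...] = (0.0, -0.01, -0.1, -1.0)
    gamma_levels: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 10))
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0.0 <= g < 1.0) for g in self.gamma_levels):
            raise ValueError("gamma levels must lie in [0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        for name in ("sparsity_levels", "gamma_levels"):
            lv = getattr(self, name)
            if tuple(sorted(lv)) != tuple(lv):
                raise ValueError(f"{name} must be sorted ascending")
        if tuple(sorted(self.decay_levels, reverse=True)) != tuple(self.decay_levels):
            raise ValueError("decay_levels must be sorted descending (0 first)")

    def levels(self, kind: Kind) -> tuple[float, ...]:
        return self.sparsity_levels if kind == "sparsity" else self.decay_levels


@dataclass(frozen=True)
class CalibrationGrid:
    """Mean (decay, GOF) per simulated (level, gamma) cell."""

    kind: Kind
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {
            "level", "gamma", "mean_decay", "mean_gof",
            "sd_decay", "sd_gof", "n",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"calibration table missing columns {sorted(missing)}")

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.table["level"].to_numpy())


@dataclass(frozen=True)
class BracketEstimate:
    """Two adjacent simulated levels enclosing an observed (decay, GOF) point.

    ``lower_level``/``upper_level`` are None for an open end.  For the
    sparsity kind, an observed decay shallower than the lowest simulated
    level means the transformation is not sparse (``not_sparse`` flag).
    """

    lower_level: float | None
    upper_level: float | None
    observed_decay: float
    observed_gof: float
    not_sparse: bool = False
    extrapolated: bool = False

    def contains(self, level: float) -> bool:
        lo = -np.inf if self.lower_level is None else self.lower_level
        hi = np.inf if self.upper_level is None else self.upper_level
        return lo <= level <= hi


# ---------------------------------------------------------------------------
# Ground-truth transformation generators


def simulate_sparse_transform(
    n_out: int,
    n_in: int,
    sparsity_percent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Matrix with a given percentage of exactly-zero entries.

    Exactly ``round(sparsity * n_out * n_in / 100)`` entries, at uniformly
    random positions, are zero; the rest are i.i.d. standard normal.
    """
    if not 0.0 <= sparsity_percent < 100.0:
        raise ValueError("sparsity_percent must be in [0, 100)")
    total = n_out * n_in
    n_zero = int(round(sparsity_percent * total / 100.0))
    T = rng.standard_normal(total)
    if n_zero:
        T[rng.choice(total, size=n_zero, replace=False)] = 0.0
    return T.reshape(n_out, n_in)


def simulate_decay_transform(
    n_out: int,
    n_in: int,
    b: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Matrix whose singular values are exactly exp(b*k), k = 1..min(n_out, n_in).

    The singular bases U, V come from the SVD of a standard-normal matrix,
    so the result is a uniformly random rotation of the prescribed
    spectrum.  ``b = 0`` gives a (scaled) orthogonal transformation.
    """
    if b > 0:
        raise ValueError("decay rate b must be <= 0")
    G = rng.standard_normal((n_out, n_in))
    U, _, Vt = np.linalg.svd(G, full_matrices=False)
    k = np.arange(1, min(n_out, n_in) + 1, dtype=float)
    return (U * np.exp(b * k)) @ Vt


def mix_noise(
    T: np.ndarray,
    X: PatternMatrix | np.ndarray,
    gamma: float,
    rng: np.random.Generator,
) -> PatternMatrix:
    """Simulated output patterns: unit-norm signal TX plus unit-norm noise.

    Returns ``(1-gamma) TX/||TX||_F + gamma E/||E||_F`` with every
    stimulus column subsequently demeaned and standardised (so the result
    is a normalised :class:`PatternMatrix`).
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must be in [0, 1)")
    Xv = _values(X)
    S = np.asarray(T, float) @ Xv
    s_norm = np.linalg.norm(S)
    if s_norm == 0:
        raise ValueError("TX is identically zero; signal term undefined")
    E = rng.standard_normal(S.shape)
    Y = (1.0 - gamma) * S / s_norm + gamma * E / np.linalg.norm(E)
    sids = X.stimulus_ids if isinstance(X, PatternMatrix) else ()
    return znormalise(PatternMatrix(Y, stimulus_ids=sids))


def simulate_pattern_pair(
    n_x: int,
    n_y: int,
    n_s: int,
    rng: np.random.Generator,
    sparsity_percent: float | None = None,
    decay_b: float | None = None,
    gamma: float = 0.0,
) -> tuple[PatternMatrix, PatternMatrix, np.ndarray]:
    """Coupled (X, Y, T_true) with standard-normal X and a known ground truth.

    Exactly one of ``sparsity_percent`` / ``decay_b`` chooses the
    ground-truth family; both omitted gives a dense standard-normal T.
    """
    if sparsity_percent is not None and decay_b is not None:
        raise ValueError("give sparsity_percent or decay_b, not both")
    X = znormalise(PatternMatrix(rng.standard_normal((n_x, n_s))))
    if sparsity_percent is not None:
        T = simulate_sparse_transform(n_y, n_x, sparsity_percent, rng)
    elif decay_b is not None:
        T = simulate_decay_transform(n_y, n_x, decay_b, rng)
    else:
        T = rng.standard_normal((n_y, n_x))
    Y = mix_noise(T, X, gamma, rng)
    return X, Y, T


# ---------------------------------------------------------------------------
# Calibration


def _cell_rng(seed: int, kind: Kind, li: int, gi: int) -> np.random.Generator:
    # Per-cell streams keyed by (seed, kind, level, gamma): reproducible
    # regardless of the order cells are evaluated in.
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=int(seed) & 0x7FFFFFFF,
            spawn_key=(0 if kind == "sparsity" else 1, li, gi),
        )
    )


def _decay_and_gof(
    Tsim: np.ndarray,
    Xv: np.ndarray,
    gamma: float,
    lam: float,
    eig: _RidgeEigen,
    proj: np.ndarray,
    weights: np.ndarray,
    kind: Kind,
    thresholds: np.ndarray,
    p_sv: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    Yv = mix_noise(Tsim, Xv, gamma, rng).values
    T_hat = Yv @ proj  # ridge estimate at the fixed lam
    if kind == "sparsity":
        curve = density_curve(T_hat, thresholds)
        decay = fit_exp_decay(curve.thresholds, curve.density).b
    else:
        sv = np.linalg.svd(T_hat, compute_uv=False)[:p_sv]
        k = np.arange(1, sv.size + 1, dtype=float)
        decay = fit_exp_decay(k, sv).b
    R = eig.residual_matrix(lam, Yv)
    lam_obj = float(np.sum((weights[:, None] * R) ** 2))
    gof = 100.0 * (1.0 - lam_obj / (Yv.shape[0] * Yv.shape[1]))
    return decay, gof


def calibrate(
    kind: Kind,
    X: PatternMatrix | np.ndarray,
    lam: float | None,
    cfg: SimulationConfig,
    n_out: int | None = None,
) -> CalibrationGrid:
    """Simulate the metric's (decay, GOF) behaviour over known levels.

    For every (level, gamma) cell, ``cfg.n_sims`` ground-truth
    transformations are drawn, noisy output patterns are built from the
    supplied input patterns ``X``, the transformation is re-estimated by
    ridge at the fixed ``lam`` (the one selected on the data under
    study — pass None to select it here on a noise-free draw), and the
    decay metric and GOF are averaged.

    ``n_out`` is the output-region voxel count for the simulated
    transformations (defaults to the input count).  The run is fully
    reproducible from ``cfg.seed``; cells use independent seeded streams.
    """
    Xv = _values(X)
    n_x, n_s = Xv.shape
    n_out = n_x if n_out is None else int(n_out)
    levels = cfg.levels(kind)
    eig = _RidgeEigen(Xv)
    if lam is None:
        rng0 = _cell_rng(cfg.seed, kind, len(levels), 0)
        T0 = (
            simulate_sparse_transform(n_out, n_x, levels[0], rng0)
            if kind == "sparsity"
            else simulate_decay_transform(n_out, n_x, levels[0], rng0)
        )
        lam = select_lambda(Xv, mix_noise(T0, Xv, 0.0, rng0).values).lam
    lam = float(lam)
    # Shared per-lam precomputations: ridge projector and leverage weights.
    proj = eig.projector(lam)
    h = eig.leverages(lam)
    weights = 1.0 / (1.0 - h)
    thresholds = default_thresholds()
    rank_x = int(np.linalg.matrix_rank(Xv))
    p_sv = min(rank_x, n_out, n_s)
    records = []
    for li, level in enumerate(levels):
        for gi, gamma in enumerate(cfg.gamma_levels):
            rng = _cell_rng(cfg.seed, kind, li, gi)
            decays = np.empty(cfg.n_sims)
            gofs = np.empty(cfg.n_sims)
            for s in range(cfg.n_sims):
                Tsim = (
                    simulate_sparse_transform(n_out, n_x, level, rng)
                    if kind == "sparsity"
                    else simulate_decay_transform(n_out, n_x, level, rng)
                )
                decays[s], gofs[s] = _decay_and_gof(
                    Tsim, Xv, gamma, lam, eig, proj, weights,
                    kind, thresholds, p_sv, rng,
                )
            records.append(
                {
                    "level": level,
                    "gamma": gamma,
                    "mean_decay": decays.mean(),
                    "mean_gof": gofs.mean(),
                    "sd_decay": decays.std(ddof=1) if cfg.n_sims > 1 else 0.0,
                    "sd_gof": gofs.std(ddof=1) if cfg.n_sims > 1 else 0.0,
                    "n": cfg.n_sims,
                }
            )
    return CalibrationGrid(kind=kind, table=pd.DataFrame.from_records(records))


def bracket_estimate(
    grid: CalibrationGrid,
    observed_decay: float,
    observed_gof: float,
) -> BracketEstimate:
    """Locate an observed (decay, GOF) point between calibration curves.

    Each level's mean decay is linearly interpolated at the observed GOF
    along that level's (mean GOF, mean decay) curve over gamma.  The two
    adjacent levels whose interpolated decays enclose the observed decay
    form the bracket; a point sitting exactly on a curve gives a
    degenerate bracket.  Points shallower than every curve (sparsity
    kind) carry the not-sparse flag; an observed GOF outside every
    curve's range triggers an extrapolation warning and the endpoint
    value is used.
    """
    import warnings

    tbl = grid.table
    levels = list(grid.levels)
    interp = {}
    in_range_any = False
    for level in levels:
        sub = tbl[tbl["level"] == level].sort_values("mean_gof")
        gofs = sub["mean_gof"].to_numpy()
        decs = sub["mean_decay"].to_numpy()
        if gofs.min() <= observed_gof <= gofs.max():
            in_range_any = True
        interp[level] = float(np.interp(observed_gof, gofs, decs))
    extrapolated = not in_range_any
    if extrapolated:
        warnings.warn(
            "observed GOF lies outside every calibration curve's range; "
            "bracket uses endpoint extrapolation",
            stacklevel=2,
        )
    # Order levels from shallowest (least negative) to steepest decay.
    # For sparsity, numeric level grows with steepness; for deformation
    # (b levels) it shrinks.  Open ends map to the numeric side beyond
    # the boundary curve accordingly.
    ordered = sorted(levels, key=lambda lv: interp[lv], reverse=True)
    decays = [interp[lv] for lv in ordered]
    ascending = ordered[-1] > ordered[0]
    for lv, dec in zip(ordered, decays):
        if observed_decay == dec:
            return BracketEstimate(lv, lv, observed_decay, observed_gof,
                                   extrapolated=extrapolated)
    if observed_decay > decays[0]:  # shallower than every curve
        lo, hi = (None, ordered[0]) if ascending else (ordered[0], None)
        return BracketEstimate(
            lo, hi, observed_decay, observed_gof,
            not_sparse=grid.kind == "sparsity", extrapolated=extrapolated,
        )
    if observed_decay < decays[-1]:  # steeper than every curve
        lo, hi = (ordered[-1], None) if ascending else (None, ordered[-1])
        return BracketEstimate(
            lo, hi, observed_decay, observed_gof, extrapolated=extrapolated,
        )
    for (a_lv, a_d), (b_lv, b_d) in zip(
        zip(ordered, decays), zip(ordered[1:], decays[1:])
    ):
        if b_d < observed_decay < a_d:
            return BracketEstimate(
                min(a_lv, b_lv), max(a_lv, b_lv),
                observed_decay, observed_gof, extrapolated=extrapolated,
            )
    raise AssertionError("unreachable: bracket search exhausted")
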