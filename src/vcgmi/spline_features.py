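"""B-spline representation of normalized beats and feature assembly.

Each 400-sample normalized beat is approximated in the least-squares sense
by a degree-``p`` spline on a clamped knot vector whose interior knots are
knot averages of an arithmetic sequence spanning [1/400, 1]. The fitted
coefficients (16 per lead for n = 15), together with the time factor alpha
and the three per-lead amplitude factors beta, form the 52-dimensional
per-heartbeat feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import lstsq

from .beat_processing import NormalizedBeat

__all__ = [
    "DOMAIN_START",
    "DOMAIN_END",
    "KnotVector",
    "SplineFit",
    "build_knots",
    "bspline_basis",
    "design_matrix",
    "fit_spline",
    "fit_normalized_beat",
    "assemble_features",
    "feature_names",
    "FEATURE_DIM",
]

DOMAIN_START = 0.0025  # first grid point, 1/400
DOMAIN_END = 1.0
FEATURE_DIM = 52
_LEAD_TAGS = ("x", "y", "z")


@dataclass(frozen=True)
class KnotVector:
    """Clamped, non-decreasing knot sequence for degree-``p`` B-splines."""

    degree: int
    knots: tuple[float, ...]

    @property
    def m(self) -> int:
        return len(self.knots) - 1

    @property
    def n(self) -> int:
        """Index of the last basis function (coefficient count - 1)."""
        return self.m - self.degree - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.knots)


def build_knots(n: int, p: int = 3) -> KnotVector:
    """Knot vector with boundary multiplicity ``p + 1`` and averaged interior knots.

    The abscissae ``tau_{p+1} .. tau_m`` form an arithmetic sequence from
    ``DOMAIN_START`` to ``DOMAIN_END``; interior knot ``k`` is the mean of
    ``tau_{k+1} .. tau_{k+p}``.
    """
    if n < p + 1:
        raise ValueError(f"need n >= p + 1 (got n={n}, p={p})")
    m = n + p + 1
    step = (DOMAIN_END - DOMAIN_START) / (m - p - 1)
    tau = {j: DOMAIN_START + (j - (p + 1)) * step for j in range(p + 1, m + 1)}
    knots = [DOMAIN_START] * (p + 1)
    for k in range(p + 1, m - p):
        knots.append(sum(tau[j] for j in range(k + 1, k + p + 1)) / p)
    knots += [DOMAIN_END] * (p + 1)
    assert len(knots) == m + 1
    return KnotVector(degree=p, knots=tuple(knots))


def bspline_basis(t: float, i: int, p: int, knots: KnotVector) -> float:
    """Evaluate the ``i``-th degree-``p`` basis function at ``t``.

    Cox-de Boor recursion with 0/0 terms taken as 0. The degree-0 indicator
    is half-open except that the domain end belongs to the last non-empty
    interval, preserving the partition of unity on the closed domain.
    """
    if not 0 <= i <= len(knots.knots) - p - 2:
        raise IndexError(f"basis index {i} out of range [0, {len(knots.knots) - p - 2}]")
    return _basis_raw(float(t), i, p, knots.knots)


def _basis_raw(t: float, i: int, p: int, z: tuple[float, ...]) -> float:
    if p == 0:
        if z[i] <= t < z[i + 1]:
            return 1.0
        if t == z[-1] and z[i] < z[i + 1] and z[i + 1] == z[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if z[i + p] != z[i]:
        left = (t - z[i]) / (z[i + p] - z[i]) * _basis_raw(t, i, p - 1, z)
    right = 0.0
    if z[i + p + 1] != z[i + 1]:
        right = (z[i + p + 1] - t) / (z[i + p + 1] - z[i + 1]) * _basis_raw(t, i + 1, p - 1, z)
    return left + right


def design_matrix(ts: np.ndarray, knots: KnotVector) -> np.ndarray:
    """Basis values at each evaluation point: shape (len(ts), n + 1)."""
    ts = np.asarray(ts, dtype=float)
    out = np.empty((len(ts), knots.n + 1))
    for j, t in enumerate(ts):
        for i in range(knots.n + 1):
            out[j, i] = bspline_basis(float(t), i, knots.degree, knots)
    return out


@lru_cache(maxsize=8)
def _cached_grid_design(n: int, p: int, grid_len: int) -> np.ndarray:
    knots = build_knots(n, p)
    grid = np.arange(1, grid_len + 1) / grid_len
    return design_matrix(grid, knots)


@dataclass
class SplineFit:
    """Least-squares spline coefficients for one normalized beat."""

    coefficients: np.ndarray
    residual: float  # sum of squared residuals on the fitting grid
    n: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != self.n + 1:
            raise ValueError(
                f"expected {self.n + 1} coefficients, got {len(self.coefficients)}"
            )


def fit_spline(
    beat: np.ndarray, knots: KnotVector, grid: np.ndarray | None = None
) -> SplineFit:
    """Least-squares fit of a spline on the normalized-beat grid.

    The default evaluation grid is ``t_j = j / len(beat), j = 1..len(beat)``,
    matching the normalized-beat time axis. Solved by orthogonal
    decomposition (LAPACK ``gelsd``) rather than normal equations.
    """
    beat = np.asarray(beat, dtype=float)
    if len(beat) < knots.n + 1:
        raise ValueError(f"beat of {len(beat)} samples cannot determine {knots.n + 1} coefficients")
    if grid is None:
        B = _cached_grid_design(knots.n, knots.degree, len(beat))
    else:
        B = design_matrix(np.asarray(grid), knots)
    coeffs, _, rank, _ = lstsq(B, beat)
    if rank < knots.n + 1:
        raise np.linalg.LinAlgError(
            f"rank-deficient spline design (rank {rank} < {knots.n + 1}); check knot placement"
        )
    resid = float(np.sum((B @ coeffs - beat) ** 2))
    return SplineFit(coeffs, resid, knots.n)


def fit_normalized_beat(beat: NormalizedBeat, n: int = 15, p: int = 3) -> SplineFit:
    return fit_spline(beat.values, build_knots(n, p))


def assemble_features(
    fits: dict[str, SplineFit] | list[SplineFit],
    alpha: float,
    betas: np.ndarray | list[float],
) -> np.ndarray:
    """Concatenate three 16-coefficient fits with alpha and the three betas.

    Order: coefficients for the X, then Y, then Z derived lead (48 values),
    then alpha, then beta_x, beta_y, beta_z — 52 values total.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    if len(fits) != 3:
        raise ValueError(f"expected fits for 3 leads, got {len(fits)}")
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (3,):
        raise ValueError("expected 3 amplitude factors")
    parts = []
    for fit in fits:
        if fit.n != 15:
            raise ValueError(f"expected n = 15 (16 coefficients) per lead, got n = {fit.n}")
        parts.append(fit.coefficients)
    vec = np.concatenate(parts + [[alpha], betas])
    assert len(vec) == FEATURE_DIM
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value")
    return vec


def feature_names(n: int = 15) -> list[str]:
    """Column names in assembly order (a-coefficients per lead, then factors)."""
    names = [f"a{tag}{i}" for tag in _LEAD_TAGS for i in range(n + 1)]
    return names + ["alpha", "beta_x", "beta_y", "beta_z"]
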