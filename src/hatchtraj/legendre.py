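"""Normalized Legendre polynomial covariates for age-dependent regressions.

Hen age at record (38–62 weeks, biweekly) is mapped affinely onto [-1, 1]
and expanded in Legendre polynomials.  Random-regression animal models use
these covariates both for the fixed age trend and for the animal-specific
random coefficients, so age-varying genetic (co)variances are quadratic
forms in the basis.

The default normalization is the orthonormal one used throughout the
random-regression literature, ``phi_l(x) = sqrt((2l+1)/2) * P_l(x)``, which
makes ``integral_{-1}^{1} phi_i phi_j dx = delta_ij``.  Raw ``P_l`` values
are available via ``normalized=False`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as _npleg

#: Biweekly record ages (weeks of hen age) used by default.
DEFAULT_AGES: tuple[int, ...] = tuple(range(38, 63, 2))


@dataclass(frozen=True)
class AgeGrid:
    """Ordered grid of record ages with its standardization interval.

    Standardization maps ``t_min`` to -1 and ``t_max`` to +1:
    ``x = 2 (t - t_min) / (t_max - t_min) - 1``.
    """

    ages: tuple[int, ...] = DEFAULT_AGES

    def __post_init__(self) -> None:
        ages = tuple(self.ages)
        if len(ages) < 2:
            raise ValueError("an age grid needs at least two ages")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")
        object.__setattr__(self, "ages", ages)

    @property
    def t_min(self) -> float:
        return float(self.ages[0])

    @property
    def t_max(self) -> float:
        return float(self.ages[-1])

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    @property
    def standardized(self) -> np.ndarray:
        """Standardized coordinates x in [-1, 1] for every grid age."""
        return standardize_age(np.asarray(self.ages, dtype=float), self)

    def age_class(self, t) -> np.ndarray:
        """Index of each age in ``t`` on the grid (for residual classes)."""
        t = np.atleast_1d(np.asarray(t))
        lookup = {a: i for i, a in enumerate(self.ages)}
        try:
            return np.array([lookup[int(v)] for v in t], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise ValueError(f"age {exc.args[0]} is not on the grid {self.ages}") from None


def standardize_age(t, grid: AgeGrid):
    """Affine map of age in weeks onto the standardized interval [-1, 1]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < grid.t_min) or np.any(t > grid.t_max):
        raise ValueError(
            f"age outside the standardization range [{grid.t_min}, {grid.t_max}]"
        )
    x = 2.0 * (t - grid.t_min) / (grid.t_max - grid.t_min) - 1.0
    return x if x.ndim else float(x)


@dataclass(frozen=True)
class BasisMatrix:
    """Legendre covariates evaluated on an age grid.

    ``values`` has one row per grid age and ``order + 1`` columns
    ``phi_0 .. phi_order``; column 0 is constant.
    """

    values: np.ndarray
    order: int
    grid: AgeGrid
    normalized: bool = True

    @property
    def n_coef(self) -> int:
        return self.order + 1

    def row(self, t) -> np.ndarray:
        """Covariate row(s) for arbitrary in-range age(s) ``t``."""
        return legendre_row(t, self.grid, self.order, normalized=self.normalized)


def _scaling(order: int) -> np.ndarray:
    return np.sqrt((2.0 * np.arange(order + 1) + 1.0) / 2.0)


def legendre_row(t, grid: AgeGrid, order: int, normalized: bool = True) -> np.ndarray:
    """Evaluate the basis at age(s) ``t``; shape (..., order + 1)."""
    if order < 0:
        raise ValueError("polynomial order must be non-negative")
    x = np.asarray(standardize_age(t, grid))
    scalar = x.ndim == 0
    vals = _npleg.legvander(np.atleast_1d(x), order)
    if normalized:
        vals = vals * _scaling(order)
    return vals[0] if scalar else vals


def legendre_matrix(grid: AgeGrid, order: int, normalized: bool = True) -> BasisMatrix:
    """Basis matrix of (normalized) Legendre covariates on the full grid."""
    values = legendre_row(np.asarray(grid.ages, dtype=float), grid, order, normalized)
    return BasisMatrix(values=values, order=order, grid=grid, normalized=normalized)
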