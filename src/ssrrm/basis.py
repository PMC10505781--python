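"""Normalized Legendre polynomial age covariates.

Random-regression models express age-dependent effects as linear
combinations of Legendre polynomials evaluated at a standardized age
``x = 2 (t - t_min) / (t_max - t_min) - 1`` in [-1, 1].  The normalized
convention ``phi_k(x) = sqrt((2k + 1) / 2) * P_k(x)`` is used, which makes
the basis orthonormal under the uniform weight on [-1, 1]:
``int_{-1}^{1} phi_i phi_j dx = delta_ij``.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre as npleg


class LegendreBasis:
    """Evaluate normalized Legendre age covariates.

    Parameters
    ----------
    order
        Maximum polynomial degree ``k_max`` (the basis has ``order + 1``
        columns).
    t_min, t_max
        Age range (months) mapped onto [-1, 1]. Defaults to the full
        birth-to-60-months window.
    """

    def __init__(self, order: int, t_min: float = 0.0, t_max: float = 60.0):
        if order < 0:
            raise ValueError("order must be >= 0")
        if t_max <= t_min:
            raise ValueError("t_max must exceed t_min")
        self.order = int(order)
        self.t_min = float(t_min)
        self.t_max = float(t_max)
        # column scaling sqrt((2k+1)/2) applied to the raw Vandermonde matrix
        self._scale = np.sqrt((2.0 * np.arange(self.order + 1) + 1.0) / 2.0)

    def standardize(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < self.t_min - 1e-9) or np.any(ages > self.t_max + 1e-9):
            raise ValueError(
                f"age outside basis range [{self.t_min}, {self.t_max}] months"
            )
        return 2.0 * (ages - self.t_min) / (self.t_max - self.t_min) - 1.0

    def design(self, ages, order: int | None = None) -> np.ndarray:
        """Matrix of phi_k(age) with one row per age, columns k = 0..order."""
        order = self.order if order is None else int(order)
        if order > self.order:
            raise ValueError("requested order exceeds basis order")
        x = np.atleast_1d(self.standardize(ages))
        van = npleg.legvander(x, order)
        return van * self._scale[: order + 1]

    def row(self, age, order: int | None = None) -> np.ndarray:
        """Covariate vector (phi_0(x), ..., phi_order(x)) for one age."""
        return self.design([age], order=order)[0]

    def evaluate(self, age, k: int) -> float:
        """phi_k evaluated at a single age."""
        if not 0 <= k <= self.order:
            raise ValueError(f"k must lie in [0, {self.order}]")
        return float(self.row(age)[k])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LegendreBasis(order={self.order}, t_min={self.t_min}, "
            f"t_max={self.t_max})"
        )


def legendre_design_row(basis: LegendreBasis, age, k_max: int) -> np.ndarray:
    """Thin functional wrapper: covariate row (phi_0 .. phi_kmax) at ``age``."""
    return basis.row(age, order=k_max)
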