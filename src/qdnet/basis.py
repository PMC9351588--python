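"""Legendre orthogonal polynomial (LOP) bases and their integrals.

The interaction kernels of the quasi-dynamic ODE system are expressed as
Legendre series in a taxon's smoothed abundance curve, with the curve's
range affinely mapped onto [-1, 1].  Two block types are produced:

* a *self* block: the full series ``P_0 .. P_r`` in the focal taxon's own
  smoothed abundance (the intrinsic/independent kernel);
* a *partner* block: the constrained series ``P_k(u) - P_k(u0)`` for
  ``k = 1 .. r``, where ``u0`` is the image of zero abundance under the
  affine map.  Every basis function of a partner block vanishes when the
  partner is absent, which (a) encodes that an absent partner exerts no
  influence and (b) removes the constant term that would otherwise be
  perfectly collinear between the self block and every partner block,
  making the independent/dependent decomposition identifiable.

Because the kernels take *smoothed* curves (known functions of the habitat
index H) as arguments, integrating a basis function along H is ordinary
quadrature; :func:`cumulative_rk4` performs it with classical Runge-Kutta
steps so that component trajectories are exactly the RK4 integrals of
their own kernels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.polynomial import legendre as npleg

from .allometry import PowerFit


def affine_map(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map ``[lo, hi]`` onto ``[-1, 1]`` (identity-width guard for lo==hi)."""
    x = np.asarray(x, dtype=float)
    if hi <= lo:
        return np.zeros_like(x)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def legendre_design(u: np.ndarray, order: int) -> np.ndarray:
    """``(len(u), order+1)`` matrix of Legendre polynomials P_0..P_order."""
    return npleg.legvander(np.asarray(u, dtype=float), order)


@dataclass
class CurveBasis:
    """LOP basis attached to one taxon's smoothed power-law curve.

    The affine map is anchored to the curve's range over the evaluation
    grid, so the mapped variable covers [-1, 1] exactly at the grid's
    extremes.
    """

    fit: PowerFit
    lo: float
    hi: float

    @classmethod
    def from_grid(cls, fit: PowerFit, grid: np.ndarray) -> "CurveBasis":
        curve = fit.predict(grid)
        return cls(fit, float(curve.min()), float(curve.max()))

    def u(self, H: np.ndarray) -> np.ndarray:
        return affine_map(self.fit.predict(H), self.lo, self.hi)

    @property
    def u_zero(self) -> float:
        """Image of zero abundance under the affine map (may lie < -1)."""
        return float(affine_map(np.array(0.0), self.lo, self.hi))

    # -- pointwise designs ----------------------------------------------
    def self_design(self, H: np.ndarray, order: int) -> np.ndarray:
        """Full series P_0..P_r evaluated along the curve."""
        return legendre_design(self.u(H), order)

    def partner_design(self, H: np.ndarray, order: int) -> np.ndarray:
        """Constrained series P_k(u) - P_k(u0), k = 1..r (vanishes at y=0)."""
        V = legendre_design(self.u(H), order)
        at_zero = legendre_design(np.array([self.u_zero]), order)[0]
        return V[:, 1:] - at_zero[1:]


def cumulative_rk4(
    f: Callable[[np.ndarray], np.ndarray],
    grid: np.ndarray,
    resolution: int = 400,
) -> np.ndarray:
    """Cumulative integral of a (vector-valued) function along a sorted grid.

    Integrates ``dF/dh = f(h)`` with classical fourth-order Runge-Kutta from
    ``grid[0]``, using enough substeps per interval that no step exceeds
    ``(grid[-1] - grid[0]) / resolution``.  For a state-independent
    right-hand side RK4 reduces to Simpson's rule per step, which is what is
    evaluated.  Returns an array of shape ``(len(grid), K)`` where ``K`` is
    the number of outputs of ``f``; row 0 is zero.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    span = grid[-1] - grid[0]
    k = np.atleast_2d(f(grid[:1])).shape[-1]
    out = np.zeros((len(grid), k))
    if span == 0:
        return out
    max_step = span / resolution
    acc = np.zeros(k)
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        if b == a:
            out[i + 1] = acc
            continue
        nsub = max(1, int(np.ceil((b - a) / max_step)))
        edges = np.linspace(a, b, nsub + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        fe = np.atleast_2d(f(edges))
        fm = np.atleast_2d(f(mids))
        h = (b - a) / nsub
        # RK4 on dF/dh = f(h): k1=f(a), k2=k3=f(mid), k4=f(b)
        inc = (h / 6.0) * (fe[:-1] + 4.0 * fm + fe[1:])
        acc = acc + inc.sum(axis=0)
        out[i + 1] = acc
    return out
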