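"""Quasi-dynamic component decomposition of abundance along habitat index.

Each taxon's abundance along the habitat-index axis H decomposes into an
*independent* component G_j — the focal taxon's intrinsic capacity, a
Legendre series in its own smoothed power-law curve — plus one *dependent*
component G_jj' per selected partner, a constrained Legendre series that
vanishes when the partner is absent:

    fitted_j(H_i) = y_j(H_(1)) + G_j(H_i) + sum_j' G_jj'(H_i)

with the boundary convention that the whole observed abundance at the
smallest habitat index belongs to the independent component (every
dependent trajectory starts at zero there), which pins the decomposition
down at the boundary.

Two engines share this contract:

* ``engine="pointwise"`` (default) evaluates each partner kernel at the
  partner's observed abundance, sample by sample — the same regression
  form the selection stage fits, and the one under which partner-specific
  variation identifies who influences whom.  Alongside the
  boundary-anchored trajectories it reports each dependent component's
  *level* (anchored at zero partner abundance), whose sign is the
  ecological one: positive level = promotion, negative = inhibition.
* ``engine="integral"`` takes the strict dynamic reading: kernels are
  functions of the *smoothed* curves and each trajectory is the RK4
  integral of its own kernel along H.

Either way the criterion is an exact quadratic in the coefficients —
kernel arguments are known data, not unknown states — so the optimum is
closed-form weighted least squares, computed per focal taxon under the
independence working model (the residual covariance across taxa is
estimated afterwards for the joint likelihood).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allometry import PowerFit, fit_all
from .basis import CurveBasis, cumulative_rk4
from .io import AbundanceMatrix
from .selection import SelectionResult, weight_function

logger = logging.getLogger(__name__)


@dataclass
class QdODEFit:
    """Component decomposition for one focal taxon on the sorted H grid.

    ``dependent_traj`` holds the boundary-anchored trajectories (zero at
    the smallest habitat index; they sum with ``independent_traj`` to
    ``fitted`` exactly).  ``dependent_level`` holds the zero-abundance-
    anchored values whose sign carries the promotion/inhibition meaning;
    for the integral engine the two coincide.
    """

    focal: str
    theta_self: np.ndarray
    theta_partner: dict[str, np.ndarray]
    grid: np.ndarray                   # sorted (deduplicated) habitat indices
    sample_ids: list[str]              # sample ids in grid order
    observed: np.ndarray
    independent_traj: np.ndarray
    dependent_traj: dict[str, np.ndarray]
    dependent_level: dict[str, np.ndarray]
    fitted: np.ndarray
    sigma2: float                      # unweighted RSS / n
    rss: float                         # weighted criterion value
    engine: str = "pointwise"
    converged: bool = True

    @property
    def partners(self) -> list[str]:
        return list(self.theta_partner)

    def dependent_total(self) -> np.ndarray:
        if not self.dependent_traj:
            return np.zeros_like(self.grid)
        return np.sum(list(self.dependent_traj.values()), axis=0)

    def residuals(self) -> np.ndarray:
        return self.observed - self.fitted


@dataclass
class CovarianceModel:
    """Residual covariance across taxa under the same-sample structure.

    The implied (n*m) x (n*m) covariance is ``C (kron) I_n``: diagonal
    blocks ``sigma_j^2 I_n``, off-diagonal blocks ``sigma_j1j2 I_n``.
    """

    taxa: list[str]
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ValueError("residual covariance must be symmetric")
        if np.any(np.diag(self.cov) <= 0):
            raise ValueError("residual variances must be positive")

    @property
    def sigma2(self) -> np.ndarray:
        return np.diag(self.cov)


def _sorted_grid(matrix: AbundanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Sorted habitat grid with duplicate values minimally perturbed.

    The quasi-dynamic axis must be strictly increasing; exact ties are
    separated by 1e-9 of the range with a warning.
    """
    H = matrix.habitat_index()
    order = np.argsort(H, kind="stable")
    grid = H[order].astype(float)
    span = grid[-1] - grid[0]
    eps = 1e-9 * (span if span > 0 else 1.0)
    n_dup = 0
    for i in range(1, len(grid)):
        if grid[i] <= grid[i - 1]:
            grid[i] = grid[i - 1] + eps
            n_dup += 1
    if n_dup:
        logger.warning("perturbed %d duplicate habitat-index values by %g", n_dup, eps)
    return grid, order


def _links_partners(links: SelectionResult | Sequence[str] | None) -> list[str]:
    if links is None:
        return []
    if isinstance(links, SelectionResult):
        return list(links.selected)
    return list(links)


def fit_qdode(
    matrix: AbundanceMatrix,
    fits: dict[str, PowerFit | None] | None = None,
    links: Mapping[str, SelectionResult | Sequence[str]] | None = None,
    order: int = 3,
    self_order: int | None = None,
    weights: str = "none",
    engine: str = "pointwise",
    resolution: int = 400,
) -> dict[str, QdODEFit]:
    """Fit the sparse component system, one focal taxon at a time.

    Parameters
    ----------
    matrix
        Abundance data; samples are sorted internally by habitat index.
    fits
        Power-law fits per taxon (computed if omitted); they define the
        smoothed curves of the independent kernels.
    links
        Per-focal selected partner sets (``SelectionResult`` or plain id
        lists).  Missing focal -> no partners (isolated taxon).
    order
        Legendre degree r of the partner kernels; ``self_order`` (default
        ``order + 3``) is the degree of the independent kernel, kept more
        flexible so the intrinsic trend never leaks into partner terms.
    engine
        ``"pointwise"`` (partner kernels at observed partner abundance) or
        ``"integral"`` (RK4-integrated kernels of the smoothed curves).
    resolution
        Integral engine only: RK4 step control, no step exceeds
        ``range(H)/resolution``.
    """
    if engine not in ("pointwise", "integral"):
        raise ValueError(f"unknown engine {engine!r}")
    if self_order is None:
        self_order = order + 3
    if fits is None:
        fits = fit_all(matrix)
    links = links or {}
    grid, sample_order = _sorted_grid(matrix)
    ids_sorted = [matrix.sample_ids[i] for i in sample_order]

    bases = {
        t: CurveBasis.from_grid(f, grid)
        for t, f in fits.items() if f is not None
    }
    # design blocks shared across focal taxa; for the pointwise engine the
    # partner variable is the partner's observed abundance in grid order
    self_blocks: dict[str, np.ndarray] = {}
    partner_blocks: dict[str, np.ndarray] = {}
    if engine == "integral":
        for t, cb in bases.items():
            self_blocks[t] = cumulative_rk4(
                lambda h, cb=cb: cb.self_design(h, self_order), grid, resolution)
            partner_blocks[t] = cumulative_rk4(
                lambda h, cb=cb: cb.partner_design(h, order), grid, resolution)
    else:
        from .basis import affine_map, legendre_design
        from .selection import partner_block as _pblock
        self_blocks_full: dict[str, np.ndarray] = {}
        for t, cb in bases.items():
            # intrinsic kernel argument: smoothed curve at the leave-self-out
            # habitat index when partners are present (see build_design for
            # the compositional rationale); an isolated fit has no partner
            # terms and keeps the strict smoothed-curve representation
            v = matrix.values[sample_order, matrix.taxon_ids.index(t)]
            H_rest = np.maximum(grid - v, 1e-12 * float(grid.max()))
            vs = fits[t].predict(H_rest)
            self_blocks[t] = legendre_design(
                affine_map(vs, float(vs.min()), float(vs.max())), self_order)
            self_blocks_full[t] = cb.self_design(grid, self_order)
            if np.ptp(v) < 1e-12 * max(1.0, float(np.abs(v).max())):
                partner_blocks[t] = np.zeros((len(grid), order))
            else:
                partner_blocks[t] = _pblock(v, order)

    out: dict[str, QdODEFit] = {}
    for jj, focal in enumerate(matrix.taxon_ids):
        if focal not in bases:
            logger.warning("skipping %s (no power fit)", focal)
            continue
        partners = [p for p in _links_partners(links.get(focal)) if p in bases and p != focal]
        y = matrix.values[sample_order, jj]
        z = weight_function(grid, weights, curve=fits[focal].predict(grid))
        sz = np.sqrt(z)
        resp = y - y[0]
        self_block = (self_blocks[focal] if (partners or engine == "integral")
                      else self_blocks_full.get(focal, self_blocks[focal]))
        # boundary-anchored columns: every component vanishes at H_(1)
        Xs = self_block - self_block[0]
        Xps = [partner_blocks[p] - partner_blocks[p][0] for p in partners]
        X = np.hstack([Xs] + Xps) if Xps else Xs
        theta, *_ = np.linalg.lstsq(sz[:, None] * X, sz * resp, rcond=None)
        if not np.all(np.isfinite(theta)):
            raise RuntimeError(f"non-finite qdODE solution for focal taxon {focal!r}")

        k_self = Xs.shape[1]
        theta_self = theta[:k_self]
        independent = y[0] + Xs @ theta_self
        dependent: dict[str, np.ndarray] = {}
        level: dict[str, np.ndarray] = {}
        theta_partner: dict[str, np.ndarray] = {}
        pos = k_self
        for p, Xp in zip(partners, Xps):
            k_p = Xp.shape[1]
            theta_partner[p] = theta[pos:pos + k_p]
            dependent[p] = Xp @ theta_partner[p]
            level[p] = partner_blocks[p] @ theta_partner[p]
            pos += k_p
        fitted = independent + (np.sum(list(dependent.values()), axis=0)
                                if dependent else 0.0)
        resid = y - fitted
        out[focal] = QdODEFit(
            focal=focal, theta_self=theta_self, theta_partner=theta_partner,
            grid=grid, sample_ids=ids_sorted, observed=y,
            independent_traj=independent, dependent_traj=dependent,
            dependent_level=level, fitted=fitted, engine=engine,
            sigma2=float(resid @ resid / len(y)),
            rss=float((sz * resid) @ (sz * resid)),
        )
    return out


def decompose(fit: QdODEFit, sample_subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample component table for one focal taxon.

    Dependent values are the zero-abundance-anchored levels, so the
    positive total sums promoting influences and the negative total
    inhibiting ones; ``independent`` is the remainder ``fitted - sum of
    levels``, keeping the additivity ``independent + dependent_pos +
    dependent_neg = fitted`` exact.  Restrict to ``sample_subset`` for
    per-subject / per-position summaries.
    """
    if not fit.converged:
        raise ValueError("cannot decompose an unconverged fit")
    idx = np.arange(len(fit.grid))
    if sample_subset is not None:
        wanted = set(sample_subset)
        idx = np.array([i for i, s in enumerate(fit.sample_ids) if s in wanted])
        if idx.size == 0:
            raise ValueError("sample subset matches no samples")
    dep = {p: lvl[idx] for p, lvl in fit.dependent_level.items()}
    dep_stack = (np.vstack(list(dep.values())) if dep
                 else np.zeros((0, idx.size)))
    table = {
        "sample": [fit.sample_ids[i] for i in idx],
        "H": fit.grid[idx],
        "observed": fit.observed[idx],
        "independent": fit.fitted[idx] - dep_stack.sum(axis=0),
        "dependent_pos": np.clip(dep_stack, 0, None).sum(axis=0),
        "dependent_neg": np.clip(dep_stack, None, 0).sum(axis=0),
    }
    for p, lvl in dep.items():
        table[f"dep_{p}"] = lvl
    return pd.DataFrame(table)


def estimate_covariance(fitdict: Mapping[str, QdODEFit]) -> CovarianceModel:
    """Plug-in residual covariance across taxa (same-sample structure)."""
    taxa = list(fitdict)
    if not taxa:
        raise ValueError("no fits supplied")
    ids = fitdict[taxa[0]].sample_ids
    for t in taxa:
        if fitdict[t].sample_ids != ids:
            raise ValueError("fits are not on the same sample grid")
    R = np.column_stack([fitdict[t].residuals() for t in taxa])
    n = R.shape[0]
    cov = R.T @ R / n
    # an (almost) interpolated taxon carries no meaningful residual
    # correlation: floor its variance and drop its covariances
    d = np.diag(cov).copy()
    floor = max(1e-12, 1e-10 * float(d.max())) if d.max() > 0 else 1e-12
    degenerate = d < floor
    cov[degenerate, :] = 0.0
    cov[:, degenerate] = 0.0
    np.fill_diagonal(cov, np.maximum(d, floor))
    return CovarianceModel(taxa=taxa, cov=cov)


def _ensure_pd(C: np.ndarray) -> np.ndarray:
    """Shrink off-diagonals toward zero until positive definite."""
    D = np.diag(np.diag(C))
    gamma = 1.0
    for _ in range(200):
        trial = D + gamma * (C - D)
        if np.linalg.eigvalsh(trial).min() > 1e-12 * np.diag(trial).max():
            if gamma < 1.0:
                logger.warning("shrunk residual cross-covariances by factor %.3f "
                               "to restore positive definiteness", gamma)
            return trial
        gamma *= 0.9
    logger.warning("falling back to diagonal residual covariance")
    return D


def loglik(
    fitdict: Mapping[str, QdODEFit],
    cov: CovarianceModel | None = None,
) -> float:
    """Joint Gaussian log-likelihood of all residual vectors.

    Under the same-sample covariance structure ``Sigma = C (kron) I_n`` the
    density factorizes into

        -(n m / 2) log 2pi - (n / 2) log det C - tr(C^-1 R'R) / 2

    with ``R`` the n x m residual matrix — evaluated directly, no dense
    (n m) x (n m) matrix is ever formed.
    """
    taxa = list(fitdict)
    R = np.column_stack([fitdict[t].residuals() for t in taxa])
    n, m = R.shape
    if cov is None:
        cov = estimate_covariance(fitdict)
    if list(cov.taxa) != taxa:
        raise ValueError("covariance model does not match the supplied fits")
    C = _ensure_pd(cov.cov)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise RuntimeError("residual covariance not positive definite")
    quad = float(np.trace(np.linalg.solve(C, R.T @ R)))
    return -0.5 * n * m * np.log(2 * np.pi) - 0.5 * n * logdet - 0.5 * quad
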