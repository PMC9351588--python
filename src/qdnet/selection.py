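"""Sparse partner selection by group LASSO then adaptive group LASSO.

For a focal taxon j, the habitat-index-varying abundance is regressed on
Legendre-basis expansions of every other taxon's smoothed abundance curve;
each partner contributes one coefficient *group*, and group-penalized
weighted least squares

    (y - a - X b)' Z (y - a - X b) + lambda * sum_g w_g ||b_g||_2

shrinks whole groups to zero.  Stage 1 uses uniform group weights; stage 2
(adaptive) reweights by the inverse stage-1 group norms (zero groups get
infinite weight, i.e. permanent exclusion), which relieves the
over-penalization of strong groups.  The diagonal weight matrix Z applies a
prescribed non-negative weight function that vanishes at the smallest and
largest habitat index.  Penalty strength is chosen by BIC (or extended BIC)
along a descending log-spaced grid.

The solver is proximal gradient descent with the exact group
soft-thresholding operator; the unpenalized intercept block (the focal's
own-curve expansion, representing the independent term a_j) is concentrated
out by orthogonal projection, which leaves the penalized problem unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .allometry import PowerFit, fit_all
from .basis import affine_map, legendre_design
from .io import AbundanceMatrix

logger = logging.getLogger(__name__)


def weight_function(
    H: np.ndarray,
    kind: str = "plateau",
    curve: np.ndarray | None = None,
) -> np.ndarray:
    """Prescribed non-negative weights z(W) with z(W_1) = z(W_n) = 0.

    ``"plateau"`` (default) is ``1 - v**8`` with ``v`` the habitat index
    affinely mapped to [-1, 1]: it vanishes exactly at the boundary
    samples but keeps near-full weight everywhere else, so almost no
    information is discarded.  ``"parabolic"`` is ``(W - W_1)(W_n - W)``
    normalized to maximum 1 — the simplest polynomial satisfying the
    boundary conditions.  ``"adaptive"`` multiplies the plateau by
    ``1 / curve**2``, the focal taxon's squared smoothed abundance, which
    variance-stabilizes strongly heteroscedastic data while keeping the
    boundary zeros.  ``"none"`` returns identity weights.
    """
    H = np.asarray(H, dtype=float)
    if kind == "none":
        return np.ones_like(H)
    if kind not in ("plateau", "parabolic", "adaptive"):
        raise ValueError(f"unknown weight function {kind!r}")
    if kind == "parabolic":
        z = (H - H[0]) * (H[-1] - H)
    else:
        span = H[-1] - H[0]
        v = 2.0 * (H - H[0]) / span - 1.0 if span > 0 else np.zeros_like(H)
        z = 1.0 - v ** 8
    if kind == "adaptive":
        if curve is None:
            raise ValueError("adaptive weights need the focal taxon's smoothed curve")
        z = z / np.maximum(np.asarray(curve, dtype=float), 1e-300) ** 2
    top = z.max()
    return z / top if top > 0 else np.ones_like(H)


@dataclass
class DesignMatrices:
    """Response, basis blocks and weights for one focal taxon.

    Blocks are standardized to unit Frobenius norm before penalization
    (scales retained for back-transforming coefficients).  Samples are in
    ascending habitat-index order.
    """

    focal: str
    y: np.ndarray
    H: np.ndarray
    order: int
    intercept: np.ndarray              # n x (r+1), unpenalized
    blocks: dict[str, np.ndarray]      # partner -> n x (r+1) (scaled)
    block_scales: dict[str, float]
    z: np.ndarray
    sample_order: np.ndarray           # permutation applied to the input rows
    flagged: list[str] = field(default_factory=list)


@dataclass
class SelectionResult:
    """Outcome of one (stage of) group-penalized selection for a focal taxon."""

    focal: str
    selected: list[str]
    beta_groups: dict[str, np.ndarray]     # original-scale coefficients
    lambda1: float | None
    lambda2: float | None
    bic_path: list[tuple[float, float, int]]   # (lambda, criterion, n_active)
    weights: dict[str, float]
    intercept_coef: np.ndarray | None = None


def partner_block(values: np.ndarray, order: int) -> np.ndarray:
    """Constrained Legendre block for one partner's abundance values.

    Columns are ``P_k(u) - P_k(u0)`` for ``k = 1..order``, where ``u``
    affinely maps the value range onto [-1, 1] and ``u0`` is the image of
    zero abundance: every basis function vanishes when the partner is
    absent, so the block carries no constant column (the unpenalized
    intercept block owns the constants).
    """
    lo, hi = float(values.min()), float(values.max())
    V = legendre_design(affine_map(values, lo, hi), order)
    at_zero = legendre_design(affine_map(np.array([0.0]), lo, hi), order)[0]
    return V[:, 1:] - at_zero[1:]


def build_design(
    matrix: AbundanceMatrix,
    fits: dict[str, PowerFit | None],
    focal: str,
    order: int = 3,
    self_order: int | None = None,
    weights: str = "plateau",
    predictor: str = "observed",
) -> DesignMatrices:
    """Assemble the regression design for one focal taxon.

    Partner kernels are evaluated at the partner's observed abundance by
    default (``predictor="observed"``): the sample-to-sample variation a
    partner actually shows is what identifies its influence on the focal
    taxon.  ``predictor="smoothed"`` substitutes the partner's power-fit
    curve (a purely shape-based variant).  Either way the values are
    affinely mapped to [-1, 1] so the Legendre columns sit on their
    natural domain.  A partner whose values are constant carries no
    information: its block degenerates to a single constant column and
    the partner is flagged.
    """
    if order < 1:
        raise ValueError("order must be >= 1 (partner blocks need a non-constant term)")
    if predictor not in ("observed", "smoothed"):
        raise ValueError(f"unknown predictor source {predictor!r}")
    H = matrix.habitat_index()
    sample_order = np.argsort(H, kind="stable")
    if not np.all(sample_order == np.arange(len(H))):
        logger.info("sorting samples by habitat index (permutation %s)", sample_order)
    Hs = H[sample_order]
    j = matrix.taxon_ids.index(focal)
    y = matrix.values[sample_order, j]

    focal_fit = fits.get(focal)
    if focal_fit is None:
        raise ValueError(f"no power fit available for focal taxon {focal!r}")
    if self_order is None:
        self_order = order + 3
    # the intrinsic block responds to the habitat capacity provided by the
    # REST of the community: using the full row-sum here would hand the
    # regression the compositional identity y_j = H - sum(others) as an
    # exact zero-residual solution
    H_rest = np.maximum(Hs - y, 1e-12 * np.max(Hs))
    v0 = focal_fit.predict(H_rest)
    intercept = legendre_design(affine_map(v0, v0.min(), v0.max()), self_order)

    blocks: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    flagged: list[str] = []
    for partner in matrix.taxon_ids:
        if partner == focal:
            continue
        pfit = fits.get(partner)
        if pfit is None:
            continue
        if predictor == "observed":
            v = matrix.values[sample_order, matrix.taxon_ids.index(partner)]
        else:
            v = pfit.predict(Hs)
        if np.ptp(v) < 1e-12 * max(1.0, np.abs(v).max()):
            block = np.ones((len(Hs), 1))
            flagged.append(partner)
        else:
            block = partner_block(v, order)
        scale = float(np.linalg.norm(block))
        blocks[partner] = block / scale
        scales[partner] = scale

    return DesignMatrices(
        focal=focal, y=y, H=Hs, order=order, intercept=intercept,
        blocks=blocks, block_scales=scales,
        z=weight_function(Hs, weights, curve=v0), sample_order=sample_order,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# proximal solver


def _group_prox(b: np.ndarray, slices: list[slice], thresh: np.ndarray) -> np.ndarray:
    out = b.copy()
    for sl, t in zip(slices, thresh):
        g = b[sl]
        norm = np.linalg.norm(g)
        out[sl] = 0.0 if norm <= t else g * (1.0 - t / norm)
    return out


def _solve_path(
    yp: np.ndarray,
    Xp: np.ndarray,
    slices: list[slice],
    lam_grid: np.ndarray,
    group_w: np.ndarray,
    max_iter: int = 5000,
    tol: float = 1e-10,
) -> tuple[list[np.ndarray], list[bool]]:
    """Proximal gradient descent along a descending lambda grid (warm starts).

    The loss is the plain squared norm (weights and the intercept
    projection are already folded into ``yp``/``Xp``); each step is
    guaranteed non-increasing by the 1/L majorization.
    """
    L = 2.0 * np.linalg.norm(Xp, 2) ** 2
    step = 1.0 / max(L, 1e-300)
    b = np.zeros(Xp.shape[1])
    sols: list[np.ndarray] = []
    converged: list[bool] = []
    for lam in lam_grid:
        thresh = step * lam * group_w
        prev_obj = np.inf
        ok = False
        for _ in range(max_iter):
            r = yp - Xp @ b
            grad = -2.0 * Xp.T @ r
            b = _group_prox(b - step * grad, slices, thresh)
            pen = lam * sum(w * np.linalg.norm(b[sl]) for sl, w in zip(slices, group_w))
            obj = float(np.sum((yp - Xp @ b) ** 2)) + pen
            if abs(prev_obj - obj) <= tol * max(1.0, abs(prev_obj)):
                ok = True
                break
            prev_obj = obj
        sols.append(b.copy())
        converged.append(ok)
    return sols, converged


def support_criterion(
    yp: np.ndarray,
    Xp: np.ndarray,
    slices: list[slice],
    active: list[int],
    criterion: str = "bic",
    gamma: float = 0.5,
    n_groups_total: int | None = None,
    n_unpenalized: int = 0,
) -> float:
    """BIC/eBIC score of one candidate support, on the refit OLS solution.

    ``n * log(RSS / (n - df - p0)) + df * log(n)`` where RSS comes from an
    unpenalized refit on the active columns, df counts them, and p0 counts
    the projected-out intercept columns; the degrees-of-freedom-adjusted
    variance keeps the score honest when df approaches n (the plain
    ``RSS/n`` plug-in rewards saturated models).  ``criterion="ebic"``
    adds the standard ``2 * gamma * log C(G, k)`` model-space term.
    Supports too large to leave residual degrees of freedom score +inf.
    """
    n = len(yp)
    if active:
        cols = np.concatenate([np.arange(slices[i].start, slices[i].stop) for i in active])
        sol, *_ = np.linalg.lstsq(Xp[:, cols], yp, rcond=None)
        rss = float(np.sum((yp - Xp[:, cols] @ sol) ** 2))
        df = len(cols)
    else:
        rss = float(yp @ yp)
        df = 0
    resid_df = n - df - n_unpenalized
    if resid_df < 4:
        return math.inf
    value = n * math.log(max(rss, 1e-300) / resid_df) + df * math.log(n)
    if criterion == "ebic":
        G = n_groups_total if n_groups_total is not None else len(slices)
        k = len(active)
        value += 2.0 * gamma * (
            math.lgamma(G + 1) - math.lgamma(k + 1) - math.lgamma(G - k + 1)
        )
    return value


def _local_polish(
    yp: np.ndarray,
    Xp: np.ndarray,
    slices: list[slice],
    active: tuple[int, ...],
    criterion: str,
    gamma: float,
    n_groups_total: int,
    n_unpenalized: int,
    max_sweeps: int = 20,
) -> tuple[int, ...]:
    """Greedy add/drop refinement of a support under the BIC criterion.

    The lambda path proposes candidate supports; this forward-backward
    sweep then walks to a local optimum of the criterion itself (single-
    group additions and deletions), which closes most of the gap to an
    exhaustive best-subset search.
    """
    current = set(active)
    best = support_criterion(yp, Xp, slices, sorted(current), criterion, gamma,
                             n_groups_total, n_unpenalized)
    for _ in range(max_sweeps):
        improved = False
        for g in range(len(slices)):
            trial = current ^ {g}  # toggle membership
            value = support_criterion(yp, Xp, slices, sorted(trial), criterion,
                                      gamma, n_groups_total, n_unpenalized)
            if value < best - 1e-12:
                current, best = trial, value
                improved = True
        if not improved:
            break
    return tuple(sorted(current))


def _refit(
    yp: np.ndarray,
    Xp: np.ndarray,
    slices: list[slice],
    b: np.ndarray,
    polish: bool,
    criterion: str,
    gamma: float,
    n_groups_total: int,
    n_unpenalized: int,
) -> np.ndarray:
    """Optionally polish the support, then refit OLS coefficients on it."""
    active = tuple(i for i, sl in enumerate(slices) if np.linalg.norm(b[sl]) > 0)
    if polish:
        active = _local_polish(yp, Xp, slices, active, criterion, gamma,
                               n_groups_total, n_unpenalized)
    out = np.zeros_like(b)
    if active:
        cols = np.concatenate([np.arange(slices[i].start, slices[i].stop)
                               for i in active])
        sol, *_ = np.linalg.lstsq(Xp[:, cols], yp, rcond=None)
        out[cols] = sol
    return out


def _prepare(design: DesignMatrices, include: list[str]) -> tuple[np.ndarray, np.ndarray, list[slice]]:
    """sqrt(z)-scale, project out the intercept block, stack partner blocks."""
    sz = np.sqrt(design.z)
    ytil = sz * design.y
    X0 = sz[:, None] * design.intercept
    Q, _ = np.linalg.qr(X0)
    proj = lambda v: v - Q @ (Q.T @ v)  # noqa: E731
    yp = proj(ytil)
    mats, slices, start = [], [], 0
    for pid in include:
        Xg = proj(sz[:, None] * design.blocks[pid])
        mats.append(Xg)
        slices.append(slice(start, start + Xg.shape[1]))
        start += Xg.shape[1]
    Xp = np.hstack(mats) if mats else np.zeros((len(yp), 0))
    return yp, Xp, slices


def _finish(
    design: DesignMatrices,
    include: list[str],
    b: np.ndarray,
    slices: list[slice],
) -> tuple[list[str], dict[str, np.ndarray], np.ndarray]:
    """Back-transform coefficients and refit the intercept block."""
    beta_groups: dict[str, np.ndarray] = {}
    norms: dict[str, float] = {}
    for pid, sl in zip(include, slices):
        g = b[sl]
        if np.linalg.norm(g) > 0:
            beta_groups[pid] = g / design.block_scales[pid]
            norms[pid] = float(np.linalg.norm(g))
    selected = sorted(norms, key=lambda p: -norms[p])
    sz = np.sqrt(design.z)
    resid = sz * design.y
    for pid in selected:
        resid = resid - (sz[:, None] * design.blocks[pid]) @ (b[slices[include.index(pid)]])
    a, *_ = np.linalg.lstsq(sz[:, None] * design.intercept, resid, rcond=None)
    return selected, beta_groups, a


def lambda_grid_for(
    yp: np.ndarray, Xp: np.ndarray, slices: list[slice], group_w: np.ndarray,
    n_lambda: int = 50, lambda_min_ratio: float = 1e-3,
) -> np.ndarray:
    """Descending log-spaced grid from the critical all-zero lambda."""
    lam_max = 0.0
    for sl, w in zip(slices, group_w):
        lam_max = max(lam_max, 2.0 * np.linalg.norm(Xp[:, sl].T @ yp) / w)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)


def group_lasso(
    design: DesignMatrices,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 50,
    criterion: str = "bic",
    gamma: float = 0.5,
    max_iter: int = 5000,
    tol: float = 1e-10,
    polish: bool = True,
) -> SelectionResult:
    """Stage-1 selection with uniform group weights.

    ``polish`` runs a greedy add/drop refinement of the criterion around
    the path-chosen support (see :func:`_local_polish`); reported
    coefficients are the unpenalized refit on the final support.
    """
    if criterion not in ("bic", "ebic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    include = list(design.blocks)
    if len(include) < 2:
        raise ValueError("need at least 2 partner blocks")
    yp, Xp, slices = _prepare(design, include)
    group_w = np.ones(len(include))
    if lambda_grid is None:
        lambda_grid = lambda_grid_for(yp, Xp, slices, group_w, n_lambda)
    sols, conv = _solve_path(yp, Xp, slices, lambda_grid, group_w, max_iter, tol)

    p0 = design.intercept.shape[1]
    path: list[tuple[float, float, int]] = []
    best = None
    scored: dict[tuple[int, ...], float] = {}
    for lam, b, ok in zip(lambda_grid, sols, conv):
        if not ok:
            logger.warning("group lasso did not converge at lambda=%g; excluded", lam)
            continue
        active = tuple(i for i, sl in enumerate(slices) if np.linalg.norm(b[sl]) > 0)
        if active not in scored:
            scored[active] = support_criterion(yp, Xp, slices, list(active),
                                               criterion, gamma, len(include), p0)
        value = scored[active]
        path.append((float(lam), float(value), len(active)))
        if best is None or value < best[1]:
            best = (float(lam), value, b)
    if best is None:
        raise RuntimeError("no lambda converged on the stage-1 path")
    b_fin = _refit(yp, Xp, slices, best[2], polish, criterion, gamma,
                   len(include), p0)
    selected, beta_groups, a = _finish(design, include, b_fin, slices)
    return SelectionResult(
        focal=design.focal, selected=selected, beta_groups=beta_groups,
        lambda1=best[0], lambda2=None, bic_path=path,
        weights={pid: 1.0 for pid in include}, intercept_coef=a,
    )


def adaptive_group_lasso(
    design: DesignMatrices,
    stage1: SelectionResult,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 50,
    criterion: str = "bic",
    gamma: float = 0.5,
    max_iter: int = 5000,
    tol: float = 1e-10,
    polish: bool = True,
) -> SelectionResult:
    """Stage-2 selection with weights 1/||b_g|| from stage 1.

    Groups shrunk to zero in stage 1 have infinite weight and never
    re-enter; if stage 1 selected nothing, the final selection is empty
    (no solver call).
    """
    if not stage1.selected:
        return SelectionResult(
            focal=design.focal, selected=[], beta_groups={},
            lambda1=stage1.lambda1, lambda2=None, bic_path=[],
            weights={}, intercept_coef=stage1.intercept_coef,
        )
    include = list(stage1.selected)
    # weights on the standardized scale used by the penalty
    w = np.array([
        1.0 / (np.linalg.norm(stage1.beta_groups[pid]) * design.block_scales[pid])
        for pid in include
    ])
    yp, Xp, slices = _prepare(design, include)
    if lambda_grid is None:
        lambda_grid = lambda_grid_for(yp, Xp, slices, w, n_lambda)
    sols, conv = _solve_path(yp, Xp, slices, lambda_grid, w, max_iter, tol)
    p0 = design.intercept.shape[1]
    path: list[tuple[float, float, int]] = []
    best = None
    scored: dict[tuple[int, ...], float] = {}
    for lam, b, ok in zip(lambda_grid, sols, conv):
        if not ok:
            logger.warning("adaptive group lasso did not converge at lambda=%g", lam)
            continue
        active = tuple(i for i, sl in enumerate(slices) if np.linalg.norm(b[sl]) > 0)
        if active not in scored:
            scored[active] = support_criterion(yp, Xp, slices, list(active),
                                               criterion, gamma, len(design.blocks), p0)
        value = scored[active]
        path.append((float(lam), float(value), len(active)))
        if best is None or value < best[1]:
            best = (float(lam), value, b)
    if best is None:
        raise RuntimeError("no lambda converged on the stage-2 path")
    b_fin = _refit(yp, Xp, slices, best[2], polish, criterion, gamma,
                   len(design.blocks), p0)
    selected, beta_groups, a = _finish(design, include, b_fin, slices)
    return SelectionResult(
        focal=design.focal, selected=selected, beta_groups=beta_groups,
        lambda1=stage1.lambda1, lambda2=best[0], bic_path=path,
        weights={pid: float(wi) for pid, wi in zip(include, w)},
        intercept_coef=a,
    )


def select_links(
    matrix: AbundanceMatrix,
    fits: dict[str, PowerFit | None] | None = None,
    order: int = 3,
    self_order: int | None = None,
    weights: str = "plateau",
    criterion: str = "bic",
    gamma: float = 0.5,
    n_lambda: int = 50,
    max_links: int | None = None,
    predictor: str = "observed",
) -> dict[str, SelectionResult]:
    """Run both selection stages for every taxon.

    ``max_links`` optionally caps each focal taxon's partner count (a
    Dunbar-style ceiling), keeping the strongest groups by norm.
    """
    if fits is None:
        fits = fit_all(matrix)
    results: dict[str, SelectionResult] = {}
    for focal in matrix.taxon_ids:
        if fits.get(focal) is None:
            continue
        design = build_design(matrix, fits, focal, order=order, self_order=self_order,
                              weights=weights, predictor=predictor)
        stage1 = group_lasso(design, n_lambda=n_lambda, criterion=criterion, gamma=gamma)
        final = adaptive_group_lasso(design, stage1, n_lambda=n_lambda,
                                     criterion=criterion, gamma=gamma)
        if max_links is not None and len(final.selected) > max_links:
            keep = final.selected[:max_links]
            final.selected = keep
            final.beta_groups = {p: final.beta_groups[p] for p in keep}
        results[focal] = final
    return results
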