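"""Context comparison by permutation-calibrated likelihood ratio.

Do the interaction parameters differ between sample groups (contexts) —
diseased vs healthy guts, say?  The null model fits one set of component
coefficients to all samples pooled; the alternative refits the
coefficients separately per context while keeping the link support and
the smoothed-curve representation fixed (support is a model-class choice,
so varying it across permutations would break exchangeability).  The
statistic

    LR = -2 (loglik_pooled - sum_c loglik_context_c)

is calibrated by reshuffling the context labels uniformly while preserving
group sizes; the 95th percentile (nearest rank) of the permutation null is
the critical threshold and the p-value uses the add-one convention
``(1 + #{null >= observed}) / (n_perm + 1)``.

Because the component fit is closed-form weighted least squares and every
basis trajectory is an antiderivative along the pooled habitat grid, a
context fit only needs differenced antiderivative columns — the whole
permutation loop costs a few small least-squares solves per permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .allometry import PowerFit, fit_all
from .basis import CurveBasis, cumulative_rk4
from .io import AbundanceMatrix
from .qdode import _ensure_pd, _sorted_grid
from .selection import SelectionResult, select_links, weight_function

logger = logging.getLogger(__name__)


@dataclass
class ContextTestResult:
    lr: float
    null_lrs: np.ndarray
    threshold95: float
    pvalue: float
    n_perm: int
    seed: int
    per_context_fits: dict[str, dict[str, float]]

    @property
    def reject(self) -> bool:
        return self.lr > self.threshold95


class LRMachine:
    """Precomputed design state for fast repeated LR evaluation.

    The power-law smoothers, the selected link support and the integrated
    basis trajectories are computed once from the pooled data; every
    pooled or per-context coefficient fit afterwards is a closed-form
    weighted least squares on differenced trajectory columns.
    """

    def __init__(
        self,
        matrix: AbundanceMatrix,
        fits: dict[str, PowerFit | None] | None = None,
        links: Mapping[str, SelectionResult | Sequence[str]] | None = None,
        order: int = 3,
        self_order: int | None = None,
        weights: str = "none",
        engine: str = "pointwise",
        resolution: int = 400,
    ) -> None:
        self.order = order
        if self_order is None:
            self_order = order + 3
        self.weights = weights
        if fits is None:
            fits = fit_all(matrix)
        if links is None:
            links = select_links(matrix, fits, order=order, weights=weights)
        self.grid, self.sample_order = _sorted_grid(matrix)
        self.y = matrix.values[self.sample_order, :]
        self.taxa = [t for t in matrix.taxon_ids if fits.get(t) is not None]
        self._col = {t: matrix.taxon_ids.index(t) for t in self.taxa}

        bases = {t: CurveBasis.from_grid(fits[t], self.grid) for t in self.taxa}
        self._curves = {t: fits[t].predict(self.grid) for t in self.taxa}
        if engine == "integral":
            self_blocks = {
                t: cumulative_rk4(lambda h, cb=bases[t]: cb.self_design(h, self_order),
                                  self.grid, resolution)
                for t in self.taxa
            }
            partner_blocks = {
                t: cumulative_rk4(lambda h, cb=bases[t]: cb.partner_design(h, order),
                                  self.grid, resolution)
                for t in self.taxa
            }
        else:
            from .basis import affine_map, legendre_design
            from .selection import partner_block as _pblock
            self_blocks = {}
            partner_blocks = {}
            for t in self.taxa:
                v = self.y[:, self._col[t]]
                H_rest = np.maximum(self.grid - v, 1e-12 * float(self.grid.max()))
                vs = fits[t].predict(H_rest)
                self_blocks[t] = legendre_design(
                    affine_map(vs, float(vs.min()), float(vs.max())), self_order)
                if np.ptp(v) < 1e-12 * max(1.0, float(np.abs(v).max())):
                    partner_blocks[t] = np.zeros((len(self.grid), order))
                else:
                    partner_blocks[t] = _pblock(v, order)
        self.designs: dict[str, np.ndarray] = {}
        self.partners: dict[str, list[str]] = {}
        for t in self.taxa:
            raw = links.get(t)
            sel = list(raw.selected) if isinstance(raw, SelectionResult) else list(raw or [])
            sel = [p for p in sel if p in bases and p != t]
            self.partners[t] = sel
            self.designs[t] = np.hstack([self_blocks[t]] + [partner_blocks[p] for p in sel])

    # -- core fits -------------------------------------------------------
    def loglik_subset(self, idx: np.ndarray) -> float:
        """Plug-in Gaussian log-likelihood of a coefficient fit on ``idx``.

        ``idx`` indexes the pooled sorted grid (ascending).  The subset's
        basis trajectories restart from its own smallest habitat index by
        differencing the pooled antiderivatives.
        """
        idx = np.asarray(idx, dtype=int)
        n_c = idx.size
        R = np.empty((n_c, len(self.taxa)))
        for k, t in enumerate(self.taxa):
            z = weight_function(self.grid[idx], self.weights, curve=self._curves[t][idx])
            sz = np.sqrt(z)
            X = self.designs[t][idx] - self.designs[t][idx[0]]
            resp = self.y[idx, self._col[t]] - self.y[idx[0], self._col[t]]
            theta, *_ = np.linalg.lstsq(sz[:, None] * X, sz * resp, rcond=None)
            R[:, k] = resp - X @ theta
        n, m = R.shape
        C = R.T @ R / n
        d = np.diag(C).copy()
        floor = max(1e-12, 1e-10 * float(d.max())) if d.max() > 0 else 1e-12
        # an (almost) interpolated taxon carries no meaningful residual
        # correlation: floor its variance and drop its covariances
        degenerate = d < floor
        C[degenerate, :] = 0.0
        C[:, degenerate] = 0.0
        np.fill_diagonal(C, np.maximum(d, floor))
        C = _ensure_pd(C)
        sign, logdet = np.linalg.slogdet(C)
        quad = float(np.trace(np.linalg.solve(C, R.T @ R)))
        return -0.5 * n * m * np.log(2 * np.pi) - 0.5 * n * logdet - 0.5 * quad

    def lr(self, labels_sorted: np.ndarray, ll_null: float | None = None) -> float:
        if ll_null is None:
            ll_null = self.loglik_subset(np.arange(len(self.grid)))
        ll_alt = 0.0
        for lab in np.unique(labels_sorted):
            ll_alt += self.loglik_subset(np.flatnonzero(labels_sorted == lab))
        lr = -2.0 * (ll_null - ll_alt)
        if lr < 0:
            if lr < -1e-6:
                logger.warning("negative LR %.3g floored at 0", lr)
            lr = 0.0
        return lr


def _check_contexts(labels: np.ndarray) -> None:
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least 2 contexts")
    for v, c in zip(values, counts):
        if c < 3:
            raise ValueError(f"context {v!r} has only {c} samples (need >= 3)")


def _resolve_labels(matrix: AbundanceMatrix, contexts) -> np.ndarray:
    if contexts is None:
        contexts = matrix.context
    if contexts is None:
        raise ValueError("no context labels supplied or attached to the matrix")
    labels = np.asarray(contexts, dtype=object)
    if labels.shape != (matrix.n_samples,):
        raise ValueError("context labels must match the number of samples")
    return labels


def lr_statistic(
    matrix: AbundanceMatrix,
    contexts: Sequence | None = None,
    machine: LRMachine | None = None,
    **machine_kwargs,
) -> float:
    """Observed likelihood-ratio statistic for a context partition."""
    labels = _resolve_labels(matrix, contexts)
    _check_contexts(labels)
    if machine is None:
        machine = LRMachine(matrix, **machine_kwargs)
    return machine.lr(labels[machine.sample_order])


def permutation_test(
    matrix: AbundanceMatrix,
    contexts: Sequence | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    machine: LRMachine | None = None,
    **machine_kwargs,
) -> ContextTestResult:
    """Permutation-calibrated context test.

    Labels are reshuffled uniformly at random preserving group sizes; the
    LR is recomputed per permutation under the identical configuration.
    Permutations whose fit fails are dropped and counted; more than 5%
    failures aborts.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = _resolve_labels(matrix, contexts)
    _check_contexts(labels)
    if machine is None:
        machine = LRMachine(matrix, **machine_kwargs)
    labels_sorted = labels[machine.sample_order]
    ll_null = machine.loglik_subset(np.arange(len(machine.grid)))
    observed = machine.lr(labels_sorted, ll_null)

    rng = np.random.default_rng(seed)
    null_lrs: list[float] = []
    failures = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels_sorted)
        try:
            null_lrs.append(machine.lr(perm, ll_null))
        except Exception as err:  # noqa: BLE001 - count and continue
            failures += 1
            logger.warning("permutation failed: %s", err)
    if failures > 0.05 * n_perm:
        raise RuntimeError(f"{failures}/{n_perm} permutations failed")
    null = np.sort(np.asarray(null_lrs))
    k = len(null)
    threshold = float(null[int(np.ceil(0.95 * k)) - 1])  # nearest rank
    pvalue = (1.0 + float(np.sum(null >= observed))) / (k + 1.0)

    per_ctx: dict[str, dict[str, float]] = {}
    for lab in np.unique(labels_sorted):
        idx = np.flatnonzero(labels_sorted == lab)
        per_ctx[str(lab)] = {
            "n_samples": float(idx.size),
            "loglik": machine.loglik_subset(idx),
        }
    return ContextTestResult(
        lr=observed, null_lrs=null, threshold95=threshold, pvalue=pvalue,
        n_perm=k, seed=seed, per_context_fits=per_ctx,
    )
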