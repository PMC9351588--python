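"""EM functional clustering of taxa by power-curve shape.

Taxa are grouped into modules by the shape of their abundance-vs-habitat-
index profile under a finite mixture of power curves.  Because abundance
noise is close to multiplicative, the mixture is fitted on the log scale,
where the power law ``alpha_l * H**beta_l`` is exactly the line
``log alpha_l + beta_l log H`` and the residuals are homoscedastic:
module l has density

    log-profile_j ~ N(log alpha_l + beta_l * log H, sigma_l^2 I_n)

with mixing proportions pi_l.  Every M-step is closed form (the weighted
line fit reduces to ordinary least squares on the responsibility-weighted
mean profile), so the EM log-likelihood is monotone by construction.
Module number L is chosen by BIC; initial partitions come from k-means on
the per-taxon (log alpha, beta) allometric fits.  The module
mean-abundance profiles feed the coarse layer of a multilayer network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .allometry import fit_all
from .io import AbundanceMatrix

logger = logging.getLogger(__name__)

_PI_FLOOR = 1e-6


@dataclass
class ModuleParams:
    alpha: float
    beta: float
    sigma2: float   # log-scale residual variance
    pi: float

    def curve(self, H: np.ndarray) -> np.ndarray:
        return self.alpha * np.asarray(H, dtype=float) ** self.beta


@dataclass
class ModuleAssignment:
    """Hard labels, posterior responsibilities and module curve parameters."""

    labels: np.ndarray            # taxon -> module index 0..L-1
    L: int
    module_params: list[ModuleParams]
    loglik: float
    bic: float
    posterior: np.ndarray         # taxa x L, rows sum to 1
    taxon_ids: list[str]
    bic_path: list[tuple[int, float]] | None = None  # (L, BIC) when chosen by select_L

    def members(self, module: int) -> list[str]:
        return [t for t, lab in zip(self.taxon_ids, self.labels) if lab == module]


class DegenerateMixtureError(RuntimeError):
    """All restarts collapsed to an empty module."""


def _log_profiles(matrix: AbundanceMatrix) -> np.ndarray:
    """taxa x samples log-abundance; zeros get half the minimum positive."""
    prof = matrix.values.T.copy()
    if np.any(prof <= 0):
        pos_min = prof[prof > 0].min() if np.any(prof > 0) else 1.0
        logger.warning("replacing non-positive abundances with %g for log-scale "
                       "clustering", pos_min / 2)
        prof[prof <= 0] = pos_min / 2
    return np.log(prof)


def _line_fit(mean_profile: np.ndarray, lH: np.ndarray) -> tuple[float, float]:
    """OLS of one (weighted-mean) log profile on [1, log H]."""
    A = np.column_stack([np.ones_like(lH), lH])
    (a, b), *_ = np.linalg.lstsq(A, mean_profile, rcond=None)
    return float(a), float(b)


def _sse_rows(logprof: np.ndarray, lH: np.ndarray, a: float, b: float) -> np.ndarray:
    d = logprof - (a + b * lH)[None, :]
    return np.sum(d * d, axis=1)


def _log_resp(logprof, lH, params: list[ModuleParams]) -> np.ndarray:
    n = logprof.shape[1]
    cols = []
    for p in params:
        sse = _sse_rows(logprof, lH, np.log(p.alpha), p.beta)
        cols.append(np.log(p.pi) - 0.5 * n * np.log(2 * np.pi * p.sigma2)
                    - 0.5 * sse / p.sigma2)
    return np.column_stack(cols)


def _em_once(
    logprof: np.ndarray,
    lH: np.ndarray,
    L: int,
    init_labels: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> tuple[float, list[ModuleParams], np.ndarray]:
    m, n = logprof.shape
    params: list[ModuleParams] = []
    for l in range(L):
        members = init_labels == l
        if not members.any():
            members = np.zeros(m, dtype=bool)
            members[l % m] = True
        sub = logprof[members]
        a, b = _line_fit(sub.mean(axis=0), lH)
        sse = _sse_rows(sub, lH, a, b).sum()
        params.append(ModuleParams(float(np.exp(a)), b,
                                   max(sse / (sub.shape[0] * n), var_floor),
                                   members.mean()))
    total = sum(p.pi for p in params)
    for p in params:
        p.pi /= total

    prev_ll = -np.inf
    for _ in range(max_iter):
        logr = _log_resp(logprof, lH, params)
        norm = logsumexp(logr, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logr - norm[:, None])
        if ll + 1e-8 < prev_ll:
            logger.warning("EM log-likelihood decreased (%.6g -> %.6g)", prev_ll, ll)
        if abs(ll - prev_ll) <= tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
        nk = resp.sum(axis=0)
        if np.any(nk / m < _PI_FLOOR):
            raise DegenerateMixtureError("empty module during EM")
        for l, p in enumerate(params):
            p.pi = nk[l] / m
            mean_prof = resp[:, l] @ logprof / nk[l]
            a, b = _line_fit(mean_prof, lH)
            p.alpha, p.beta = float(np.exp(a)), b
            sse = float(resp[:, l] @ _sse_rows(logprof, lH, a, b))
            p.sigma2 = max(sse / (nk[l] * n), var_floor)
    logr = _log_resp(logprof, lH, params)
    norm = logsumexp(logr, axis=1)
    resp = np.exp(logr - norm[:, None])
    return float(norm.sum()), params, resp


def functional_cluster(
    matrix: AbundanceMatrix,
    L: int,
    seed: int = 0,
    n_starts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ModuleAssignment:
    """Cluster taxa into ``L`` modules by mixture-of-power-curves EM.

    Best of ``n_starts`` seeded restarts (k-means on the per-taxon
    allometric (log alpha, beta) features, perturbed per start) is
    returned; restarts whose mixture degenerates are discarded, and if all
    of them do the call fails.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    m = matrix.n_taxa
    if m < L:
        raise ValueError("cannot fit more modules than taxa")
    lH = np.log(matrix.habitat_index())
    logprof = _log_profiles(matrix)
    var_floor = 1e-8 * max(float(logprof.var()), 1e-30)

    # allometric feature space for initialization
    fits = fit_all(matrix)
    feats = np.zeros((m, 2))
    rng = np.random.default_rng(seed)
    for j, t in enumerate(matrix.taxon_ids):
        f = fits[t]
        feats[j] = (np.log(f.alpha), f.beta) if f is not None else rng.normal(size=2)
    std = feats.std(axis=0)
    feats = (feats - feats.mean(axis=0)) / np.where(std > 0, std, 1.0)

    best: tuple[float, list[ModuleParams], np.ndarray] | None = None
    for start in range(max(1, n_starts)):
        if L == 1:
            init = np.zeros(m, dtype=int)
        else:
            km = KMeans(n_clusters=L, n_init=1, random_state=seed + start)
            jitter = rng.normal(0, 0.05 * start, size=feats.shape)
            init = km.fit_predict(feats + jitter)
        try:
            ll, params, resp = _em_once(logprof, lH, L, init, tol, max_iter, var_floor)
        except DegenerateMixtureError:
            continue
        if best is None or ll > best[0]:
            best = (ll, params, resp)
    if best is None:
        raise DegenerateMixtureError(f"all {n_starts} restarts degenerated for L={L}")
    ll, params, resp = best
    n_params = 4 * L - 1
    bic = -2.0 * ll + n_params * np.log(matrix.n_samples * m)
    labels = np.argmax(resp, axis=1)  # argmax ties resolve to lowest index
    return ModuleAssignment(
        labels=labels, L=L, module_params=params, loglik=ll, bic=float(bic),
        posterior=resp, taxon_ids=list(matrix.taxon_ids),
    )


def select_L(
    matrix: AbundanceMatrix,
    L_max: int,
    seed: int = 0,
    n_starts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ModuleAssignment:
    """Fit L = 1..L_max and return the BIC-minimizing assignment."""
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    best: ModuleAssignment | None = None
    path: list[tuple[int, float]] = []
    for L in range(1, min(L_max, matrix.n_taxa) + 1):
        try:
            fit = functional_cluster(matrix, L, seed=seed, n_starts=n_starts,
                                     tol=tol, max_iter=max_iter)
        except DegenerateMixtureError:
            logger.warning("mixture degenerate at L=%d; skipped", L)
            continue
        path.append((L, fit.bic))
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise DegenerateMixtureError("no module number converged")
    best.bic_path = path
    return best


def module_profiles(matrix: AbundanceMatrix, assignment: ModuleAssignment,
                    agg: str = "mean") -> AbundanceMatrix:
    """Per-sample mean (or summed) abundance of each module's member taxa.

    The coarse-grained matrix has one column per module, labeled ``M1..``;
    with the default mean, the size-weighted mean of its columns
    reproduces the mean taxon abundance of every sample (``agg="sum"``
    only rescales each module curve by its size).
    """
    if agg not in ("mean", "sum"):
        raise ValueError(f"unknown profile aggregation {agg!r}")
    if list(assignment.taxon_ids) != list(matrix.taxon_ids):
        raise ValueError("assignment does not cover this matrix's taxa")
    cols, names = [], []
    for l in range(assignment.L):
        idx = np.flatnonzero(assignment.labels == l)
        if idx.size == 0:
            continue
        reducer = np.mean if agg == "mean" else np.sum
        cols.append(reducer(matrix.values[:, idx], axis=1))
        names.append(f"M{l + 1}")
    return AbundanceMatrix(
        np.column_stack(cols), list(matrix.sample_ids), names,
        context=matrix.context, position=matrix.position, subject=matrix.subject,
    )


def recursive_cluster(
    matrix: AbundanceMatrix,
    max_module_size: int = 15,
    L_max: int = 8,
    seed: int = 0,
    **kwargs,
) -> dict[str, list[str]]:
    """Split modules recursively until each holds a trackable number of taxa.

    Returns a flat mapping of hierarchical module labels (``M2.1`` is the
    first submodule of module 2) to member taxon ids.
    """
    out: dict[str, list[str]] = {}

    def _split(sub: AbundanceMatrix, prefix: str) -> None:
        if sub.n_taxa <= max_module_size:
            out[prefix or "M1"] = list(sub.taxon_ids)
            return
        fit = select_L(sub, min(L_max, sub.n_taxa), seed=seed, **kwargs)
        if fit.L == 1:
            out[prefix or "M1"] = list(sub.taxon_ids)
            return
        for l in range(fit.L):
            members = fit.members(l)
            if not members:
                continue
            label = f"{prefix}.{l + 1}" if prefix else f"M{l + 1}"
            _split(sub.subset_taxa(members), label)

    _split(matrix, "")
    return out
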