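"""Allometric power-law fits of niche index against habitat index.

Each taxon's abundance (niche index) y is modelled against the sample's
total abundance (habitat index) H by the part-whole power law

    y = alpha * H ** beta

with alpha > 0 an intercept constant and beta the scaling exponent.  The
default fit is ordinary least squares of log y on log H (closed form,
robust); an optional nonlinear refinement minimizes squared error on the
original scale starting from the log-log solution.  The fitted smooth curve
``y_hat(H)`` is the quasi-dynamic representation used by every downstream
stage (link selection and the component ODEs), which is how a purely
cross-sectional table acquires a dynamic axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class PowerFit:
    """Result of fitting ``y = alpha * H**beta`` for one taxon.

    ``r2`` is the coefficient of determination on the fitting scale
    (``scale`` says which); both conventions are kept in ``r2_log`` /
    ``r2_original`` because fit quality is conventionally quoted on either.
    """

    alpha: float
    beta: float
    r2: float
    scale: str  # "log-log" or "original"
    n_used: int
    r2_log: float = float("nan")
    r2_original: float = float("nan")

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not (0.0 <= self.r2 <= 1.0 or np.isnan(self.r2)):
            # clamp tiny numerical overshoot rather than fail
            self.r2 = float(min(max(self.r2, 0.0), 1.0))

    def predict(self, H: np.ndarray) -> np.ndarray:
        return predict_power(self, H)


def _r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    resid = observed - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((observed - observed.mean()) ** 2))
    if tss == 0.0:
        # degenerate flat response: perfect if residual-free, else 0
        return 1.0 if rss < 1e-24 else 0.0
    return max(0.0, 1.0 - rss / tss)


def fit_power(
    y: np.ndarray,
    H: np.ndarray,
    method: str = "loglog",
    pseudocount: float = 0.0,
) -> PowerFit:
    """Fit the power law for one taxon.

    Parameters
    ----------
    y
        Non-negative abundances; zeros are dropped on the log scale (or
        shifted by ``pseudocount`` when one is supplied).
    H
        Strictly positive habitat indices, same length as ``y``.
    method
        ``"loglog"`` — OLS of log y on log H (closed form).
        ``"nls"`` — original-scale least squares initialized at the
        log-log solution.
    """
    y = np.asarray(y, dtype=float)
    H = np.asarray(H, dtype=float)
    if y.shape != H.shape or y.ndim != 1:
        raise ValueError("y and H must be 1-D vectors of equal length")
    if np.any(H <= 0):
        raise ValueError("habitat index must be strictly positive")
    if method not in ("loglog", "nls"):
        raise ValueError(f"unknown method {method!r}")

    y_work = y + pseudocount
    mask = y_work > 0
    n_used = int(mask.sum())
    if n_used < 3:
        raise ValueError("insufficient positive abundance (need >= 3 samples with y > 0)")
    ly, lH = np.log(y_work[mask]), np.log(H[mask])

    # closed-form log-log OLS; degenerate (constant H) cannot happen since
    # habitat index varies across retained samples in practice, but guard it
    if np.ptp(lH) == 0:
        slope, intercept = 0.0, float(ly.mean())
    else:
        slope, intercept = np.polyfit(lH, ly, 1)
    alpha, beta = float(np.exp(intercept)), float(slope)
    r2_log = _r2(ly, intercept + slope * lH)
    r2_orig = _r2(y_work[mask], alpha * H[mask] ** beta)

    if method == "loglog":
        return PowerFit(alpha, beta, r2_log, "log-log", n_used,
                        r2_log=r2_log, r2_original=r2_orig)

    # original-scale refinement, parameterized in (log alpha, beta) so that
    # alpha stays positive; started at the log-log solution
    Hm, ym = H[mask], y_work[mask]

    def resid(p: np.ndarray) -> np.ndarray:
        return np.exp(p[0]) * Hm ** p[1] - ym

    sol = least_squares(resid, x0=[np.log(alpha), beta], method="lm")
    a_nls, b_nls = float(np.exp(sol.x[0])), float(sol.x[1])
    # least_squares started at the loglog solution can only improve the
    # original-scale objective; keep the better of the two defensively
    if np.sum(resid(sol.x) ** 2) > np.sum(resid([np.log(alpha), beta]) ** 2):
        a_nls, b_nls = alpha, beta
    r2_orig = _r2(ym, a_nls * Hm ** b_nls)
    r2_log_nls = _r2(np.log(ym), np.log(a_nls) + b_nls * np.log(Hm))
    return PowerFit(a_nls, b_nls, r2_orig, "original", n_used,
                    r2_log=r2_log_nls, r2_original=r2_orig)


def predict_power(fit: PowerFit, H: np.ndarray) -> np.ndarray:
    """Evaluate ``alpha * H**beta`` elementwise (H must be positive)."""
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise ValueError("habitat index must be strictly positive")
    return fit.alpha * H ** fit.beta


def fit_all(
    matrix: AbundanceMatrix,
    method: str = "loglog",
    pseudocount: float = 0.0,
) -> dict[str, PowerFit | None]:
    """Fit the power law for every taxon against the shared habitat index.

    Taxa with fewer than 3 positive observations get ``None`` and a logged
    warning; failures never abort the batch.
    """
    H = matrix.habitat_index()
    fits: dict[str, PowerFit | None] = {}
    for j, taxon in enumerate(matrix.taxon_ids):
        try:
            fits[taxon] = fit_power(matrix.values[:, j], H, method=method,
                                    pseudocount=pseudocount)
        except ValueError as err:
            logger.warning("power fit failed for %s: %s", taxon, err)
            fits[taxon] = None
    return fits
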