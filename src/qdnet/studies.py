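"""Reproducible benchmark studies for every pipeline stage.

Each study generates its own synthetic data (deterministically from one
seed), runs the relevant stage end to end, and reports the quantities a
reader would check first: parameter-recovery errors, support-recovery F1,
sign accuracy, clustering accuracy, permutation-test calibration, and
byte-level determinism of the pipeline.  Problem sizes are desk scale —
tens of taxa, tens of samples — chosen so a full battery runs in minutes
on one core; docs/methods.md records the sizes and the reasoning.
"""

from __future__ import annotations

import hashlib
import tempfile
from itertools import combinations
from pathlib import Path

import numpy as np

from .allometry import fit_all, fit_power
from .context import permutation_test
from .funclust import select_L
from .io import AbundanceMatrix, TaxonomyMap, aggregate
from .network import build_network, interaction_label
from .pipeline import PipelineConfig, run_pipeline
from .qdode import fit_qdode
from .selection import (
    adaptive_group_lasso,
    build_design,
    group_lasso,
    select_links,
    _prepare,
    support_criterion,
)
from .synth import ContextEffect, GeneratorConfig, PlantedLink, generate


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# allometry


def allometry_recovery(seed: int = 0, n_taxa: int = 20, n_samples: int = 50,
                       sigma_log: float = 0.1) -> dict:
    """Power-law parameter recovery under multiplicative noise.

    Each taxon gets known (alpha, beta); abundances are alpha*H**beta with
    lognormal noise of the given log-sd; the log-log fit must land within
    |beta_hat - beta| < 0.05 and |log alpha_hat - log alpha| < 0.1, and
    the noiseless fit must be exact to 1e-6.  Habitat indices span two
    decades centered on unity (abundance units are arbitrary): the wide
    span pins the slope (standard error sigma_log / (sqrt(n) sd(log H))
    ~ 0.011) and centering makes the intercept alpha — the abundance at
    unit habitat — an interpolated quantity rather than an edge
    extrapolation.
    """
    rng = _rng(seed)
    H = np.exp(rng.uniform(np.log(0.2), np.log(20.0), size=n_samples))
    alphas = np.exp(rng.uniform(np.log(0.3), np.log(3.0), size=n_taxa))
    betas = rng.uniform(-1.5, 1.5, size=n_taxa)
    beta_err, logalpha_err, noiseless_err = [], [], []
    for a, b in zip(alphas, betas):
        clean = a * H ** b
        noisy = clean * np.exp(rng.normal(0.0, sigma_log, size=n_samples))
        fit = fit_power(noisy, H)
        beta_err.append(abs(fit.beta - b))
        logalpha_err.append(abs(np.log(fit.alpha) - np.log(a)))
        exact = fit_power(clean, H)
        noiseless_err.append(max(abs(exact.beta - b),
                                 abs(np.log(exact.alpha) - np.log(a))))
    return {
        "n_taxa": n_taxa,
        "max_beta_err": float(np.max(beta_err)),
        "max_logalpha_err": float(np.max(logalpha_err)),
        "n_within_tolerance": int(np.sum((np.array(beta_err) < 0.05)
                                         & (np.array(logalpha_err) < 0.1))),
        "noiseless_max_err": float(np.max(noiseless_err)),
    }


def grid_search_power_oracle(seed: int = 0) -> dict:
    """Closed-form log-log OLS against an independent 2-D grid search."""
    rng = _rng(seed)
    H = np.exp(rng.uniform(0.0, np.log(10.0), size=50))
    y = 0.35 * H ** 1.2 * np.exp(rng.normal(0, 0.1, size=50))
    fit = fit_power(y, H)
    # coarse-to-fine grid search over (log alpha, beta) minimizing log-SSE
    la_grid = np.linspace(np.log(0.1), np.log(1.0), 241)
    b_grid = np.linspace(0.5, 2.0, 301)
    ly, lH = np.log(y), np.log(H)
    sse = ((ly[None, None, :] - (la_grid[:, None, None]
                                 + b_grid[None, :, None] * lH[None, None, :])) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    for _ in range(3):  # refine around the incumbent
        la_grid = np.linspace(la_grid[max(i - 1, 0)], la_grid[min(i + 1, len(la_grid) - 1)], 201)
        b_grid = np.linspace(b_grid[max(j - 1, 0)], b_grid[min(j + 1, len(b_grid) - 1)], 201)
        sse = ((ly[None, None, :] - (la_grid[:, None, None]
                                     + b_grid[None, :, None] * lH[None, None, :])) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return {
        "beta_fit": fit.beta, "beta_grid": float(b_grid[j]),
        "logalpha_fit": float(np.log(fit.alpha)), "logalpha_grid": float(la_grid[i]),
        "beta_abs_err_vs_truth": abs(fit.beta - 1.2),
    }


# ---------------------------------------------------------------------------
# conservation


def conservation_check(seed: int = 0, n_matrices: int = 100) -> dict:
    """Habitat index = exact row sum; aggregation conserves sample totals."""
    rng = _rng(seed)
    max_hab_err = 0.0
    max_agg_err = 0.0
    for k in range(n_matrices):
        n, m = int(rng.integers(3, 12)), int(rng.integers(2, 25))
        vals = rng.gamma(1.0, 2.0, size=(n, m))
        vals[rng.random(size=(n, m)) < 0.2] = 0.0
        vals[:, 0] += 0.1  # keep rows positive
        mat = AbundanceMatrix(vals, [f"s{i}" for i in range(n)], [f"t{j}" for j in range(m)])
        max_hab_err = max(max_hab_err,
                          float(np.max(np.abs(mat.habitat_index() - vals.sum(axis=1)))))
        phyla = {f"t{j}": {"phylum": f"P{j % max(2, m // 3)}"} for j in range(m)}
        agg = aggregate(mat, TaxonomyMap(phyla), "phylum",
                        top_k=int(rng.integers(1, max(2, m // 3) + 1)))
        max_agg_err = max(max_agg_err,
                          float(np.max(np.abs(agg.habitat_index() - mat.habitat_index()))))
    return {"n_matrices": n_matrices, "max_habitat_err": max_hab_err,
            "max_aggregation_err": max_agg_err}


# ---------------------------------------------------------------------------
# qdode


def qdode_reduction(seed: int = 0, n_taxa: int = 10, n_samples: int = 30) -> dict:
    """Additivity of the component decomposition and the isolated-taxon case.

    The additivity error is checked on a fitted noisy system; the
    isolated-taxon reproduction uses noiseless power-law data, where the
    independent component alone must track the observed curve.
    """
    cfg = GeneratorConfig(n_samples=n_samples, n_taxa=n_taxa, seed=seed,
                          n_partners=2, sigma_log=0.02)
    matrix, _ = generate(cfg)
    fits = fit_all(matrix)
    links = {t: [p for p in matrix.taxon_ids if p != t][:2] for t in matrix.taxon_ids}
    qfits = fit_qdode(matrix, fits, links, order=2)
    add_err = 0.0
    for f in qfits.values():
        total = f.independent_traj + f.dependent_total()
        scale = np.maximum(np.abs(f.fitted), 1e-12)
        add_err = max(add_err, float(np.max(np.abs(f.fitted - total) / scale)))

    clean_cfg = GeneratorConfig(n_samples=n_samples, n_taxa=n_taxa, seed=seed + 1,
                                n_partners=0, sigma_bio=0.0, sigma_log=0.0)
    clean, _ = generate(clean_cfg)
    qclean = fit_qdode(clean, fit_all(clean), links=None, order=3)
    r2_min = 1.0
    for f in qclean.values():
        resid = f.observed - f.independent_traj
        tss = float(np.sum((f.observed - f.observed.mean()) ** 2))
        r2_min = min(r2_min, 1.0 - float(resid @ resid) / tss)
    return {"n_taxa": n_taxa, "additivity_max_rel_err": add_err,
            "isolated_min_r2": r2_min}


# ---------------------------------------------------------------------------
# link and sign recovery


def link_recovery(seed: int = 0, n_replicates: int = 20, n_taxa: int = 20,
                  n_samples: int = 60, n_partners: int = 3) -> dict:
    """Support-recovery F1 and edge-sign accuracy on planted networks."""
    f1s, snrs = [], []
    sign_ok = sign_tot = 0
    for rep in range(n_replicates):
        cfg = GeneratorConfig(n_samples=n_samples, n_taxa=n_taxa,
                              seed=seed * 1000 + rep, n_partners=n_partners,
                              sigma_log=0.01, beta_range=(-0.3, 0.5), h_max=4.0)
        matrix, truth = generate(cfg)
        snrs.append(float(np.median(list(truth.snr.values()))))
        fits = fit_all(matrix)
        links = select_links(matrix, fits, order=2, criterion="ebic", gamma=0.5)
        true_sets: dict[str, set] = {}
        for lk in truth.links:
            true_sets.setdefault(matrix.taxon_ids[lk.target], set()).add(
                matrix.taxon_ids[lk.source])
        per_focal = []
        for focal, res in links.items():
            sel, tr = set(res.selected), true_sets.get(focal, set())
            tp = len(sel & tr)
            prec = tp / len(sel) if sel else 1.0
            rec = tp / len(tr) if tr else 1.0
            per_focal.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
        f1s.append(float(np.mean(per_focal)))
        qfits = fit_qdode(matrix, fits, links, order=2)
        net = build_network(qfits)
        for lk in truth.links:
            sign = net.edge_sign(matrix.taxon_ids[lk.source], matrix.taxon_ids[lk.target])
            if sign != 0:
                sign_tot += 1
                sign_ok += int(sign == np.sign(lk.strength))
    return {
        "n_replicates": n_replicates,
        "mean_f1": float(np.mean(f1s)),
        "sign_accuracy": sign_ok / max(sign_tot, 1),
        "n_recovered_edges": sign_tot,
        "median_snr": float(np.median(snrs)),
    }


# ---------------------------------------------------------------------------
# best-subset agreement


def bestsubset_agreement(seed: int = 0, n_replicates: int = 20,
                         n_samples: int = 40) -> dict:
    """Group-LASSO + BIC support vs exhaustive best-subset BIC (6 partners)."""
    agree = 0
    for rep in range(n_replicates):
        links = [PlantedLink(0, 1, 1.0), PlantedLink(0, 2, -1.0)]
        cfg = GeneratorConfig(n_samples=n_samples, n_taxa=7,
                              seed=seed * 1000 + rep, links=links, sigma_log=0.02)
        matrix, _ = generate(cfg)
        fits = fit_all(matrix)
        design = build_design(matrix, fits, matrix.taxon_ids[0], order=2)
        stage1 = group_lasso(design)
        final = adaptive_group_lasso(design, stage1)
        lasso_support = frozenset(final.selected)

        include = list(design.blocks)
        yp, Xp, slices = _prepare(design, include)
        p0 = design.intercept.shape[1]
        best = (np.inf, frozenset())
        for k in range(len(include) + 1):
            for combo in combinations(range(len(include)), k):
                value = support_criterion(yp, Xp, slices, list(combo),
                                          n_unpenalized=p0)
                if value < best[0]:
                    best = (value, frozenset(include[i] for i in combo))
        agree += int(lasso_support == best[1])
    return {"n_replicates": n_replicates, "agreement_rate": agree / n_replicates}


# ---------------------------------------------------------------------------
# interaction taxonomy


def interaction_taxonomy() -> dict:
    """Exhaustive enumeration of the 3x3 sign table."""
    labels = {(sf, sr): interaction_label(sf, sr)
              for sf in (-1, 0, 1) for sr in (-1, 0, 1)}
    expected = {"mutualism", "antagonism", "commensalism", "amensalism",
                "parasitism", "altruism", "neutral"}
    return {
        "n_combinations": len(labels),
        "n_labels": len(set(labels.values())),
        "complete": set(labels.values()) == expected,
        "table": {f"{k[0]},{k[1]}": v for k, v in labels.items()},
    }


# ---------------------------------------------------------------------------
# clustering


def clustering_recovery(seed: int = 0, n_replicates: int = 20) -> dict:
    """Three planted curve modules: ARI and BIC-chosen module number."""
    from sklearn.metrics import adjusted_rand_score

    hits = 0
    aris = []
    for rep in range(n_replicates):
        cfg = GeneratorConfig(n_samples=30, n_taxa=30, n_modules=3,
                              seed=seed * 1000 + rep, sigma_bio=0.1, sigma_log=0.05,
                              module_alpha_jitter=0.0, module_beta_jitter=0.0)
        matrix, truth = generate(cfg)
        fit = select_L(matrix, 6, seed=seed * 1000 + rep)
        ari = adjusted_rand_score(truth.module_labels, fit.labels)
        aris.append(ari)
        hits += int(fit.L == 3 and ari == 1.0)
    return {"n_replicates": n_replicates, "success_rate": hits / n_replicates,
            "mean_ari": float(np.mean(aris))}


# ---------------------------------------------------------------------------
# context test calibration


def lr_calibration(seed: int = 0, n_replicates: int = 100, n_perm: int = 200) -> dict:
    """Type-I error of the permutation LR test on null two-context data."""
    rejections = 0
    for rep in range(n_replicates):
        cfg = GeneratorConfig(n_samples=24, n_taxa=4, seed=seed * 10000 + rep,
                              n_partners=1, sigma_log=0.05,
                              contexts=ContextEffect(sizes={"A": 12, "B": 12}))
        matrix, _ = generate(cfg)
        result = permutation_test(matrix, n_perm=n_perm, seed=seed * 10000 + rep,
                                  order=2)
        rejections += int(result.reject)
    return {"n_replicates": n_replicates, "n_perm": n_perm,
            "rejection_rate": rejections / n_replicates}


# ---------------------------------------------------------------------------
# determinism


def _tree_hash(root: Path) -> str:
    digest = hashlib.sha256()
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.suffix != ".log":
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()


def determinism_check(seed: int = 0, workdir: str | Path | None = None) -> dict:
    """Identical config + seed must reproduce byte-identical outputs."""
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="qdnet-det-"))
    hashes = []
    for run in ("a", "b"):
        out = base / run
        cfg = PipelineConfig(out_dir=str(out), scenario_name="phylum17", seed=seed,
                             order=2, compare=False)
        run_pipeline(cfg)
        hashes.append(_tree_hash(out))
    return {"identical": hashes[0] == hashes[1], "hash": hashes[0]}


def run_all(seed: int = 0, workdir: str | Path | None = None) -> dict:
    """Full battery; returns one nested dict (used by the acceptance script)."""
    return {
        "allometry": allometry_recovery(seed),
        "allometry_oracle": grid_search_power_oracle(seed),
        "conservation": conservation_check(seed),
        "qdode": qdode_reduction(seed),
        "links": link_recovery(seed),
        "bestsubset": bestsubset_agreement(seed),
        "taxonomy": interaction_taxonomy(),
        "clustering": clustering_recovery(seed),
        "lr": lr_calibration(seed),
        "determinism": determinism_check(seed, workdir),
    }
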