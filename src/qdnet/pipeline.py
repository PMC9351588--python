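"""End-to-end pipeline: power fits -> selection -> components -> networks.

`run_pipeline` chains the four analysis steps (allometric fitting,
LASSO-based link selection, component-ODE reconstruction, and optional
functional clustering / context comparison) over one configuration, writes
every stage's tables plus GraphML networks into a run directory, and
records a manifest of output hashes so that a rerun with the same config
and seed is byte-identical.  Timestamps go only to the log file; every
data output is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import fit_all
from .context import permutation_test
from .funclust import select_L
from .io import AbundanceMatrix, load_abundance, load_metadata
from .network import build_multilayer, build_network, pair_table, role_table, write_graphml
from .qdode import decompose, fit_qdode
from .selection import select_links
from .synth import generate, scenario

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One documented home for every pipeline knob.

    Either ``abundance`` (a TSV/CSV path, with optional ``metadata``) or
    ``scenario_name`` (a built-in synthetic scenario) must be set.
    """

    out_dir: str
    abundance: str | None = None
    metadata: str | None = None
    scenario_name: str | None = None
    seed: int = 0
    order: int = 3                  # Legendre degree of all kernels
    weights: str = "plateau"        # boundary-vanishing selection weights
    criterion: str = "bic"          # selection criterion (bic | ebic)
    n_lambda: int = 50
    max_links: int | None = None
    eps_factor: float = 0.05        # neutrality threshold factor
    cluster: bool = False
    cluster_L_max: int = 8
    n_perm: int = 1000              # context permutation count
    compare: bool = True            # run the context test when labels exist
    scope: str = "all"              # evaluation scope: all | position | context | subject

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scopes(matrix: AbundanceMatrix, scope: str) -> dict[str, list[str]]:
    if scope == "all":
        return {"all": list(matrix.sample_ids)}
    labels = getattr(matrix, scope if scope != "sample" else "sample_ids")
    if scope == "sample":
        return {s: [s] for s in matrix.sample_ids}
    if labels is None:
        raise ValueError(f"matrix carries no {scope!r} labels")
    out: dict[str, list[str]] = {}
    for s, lab in zip(matrix.sample_ids, labels):
        out.setdefault(str(lab), []).append(s)
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the chained pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("qdnet")
    root.addHandler(handler)
    outputs: list[Path] = []
    try:
        # ---- inputs
        logger.info("== stage: load ==")
        if config.abundance is not None:
            matrix = load_abundance(config.abundance)
            if config.metadata is not None:
                matrix = load_metadata(matrix, config.metadata)
        elif config.scenario_name is not None:
            matrix, _truth = generate(scenario(config.scenario_name, seed=config.seed))
        else:
            raise ValueError("config needs either an abundance path or a scenario name")

        # ---- step i: power fits
        logger.info("== stage: fit-power ==")
        fits = fit_all(matrix)
        rows = []
        for t in matrix.taxon_ids:
            f = fits[t]
            rows.append({"taxon": t,
                         "alpha": f.alpha if f else np.nan,
                         "beta": f.beta if f else np.nan,
                         "r2_log": f.r2_log if f else np.nan,
                         "r2_original": f.r2_original if f else np.nan,
                         "n_used": f.n_used if f else 0})
        p = out / "power_fits.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        outputs.append(p)

        # ---- step ii: link selection
        logger.info("== stage: select ==")
        links = select_links(matrix, fits, order=config.order, weights=config.weights,
                             criterion=config.criterion, n_lambda=config.n_lambda,
                             max_links=config.max_links)
        rows = []
        for focal, res in links.items():
            for rank, pid in enumerate(res.selected, start=1):
                rows.append({"focal": focal, "partner": pid,
                             "group_norm": float(np.linalg.norm(res.beta_groups[pid])),
                             "rank": rank, "lambda1": res.lambda1, "lambda2": res.lambda2})
        p = out / "selection.tsv"
        pd.DataFrame(rows, columns=["focal", "partner", "group_norm", "rank",
                                    "lambda1", "lambda2"]).to_csv(p, sep="\t", index=False)
        outputs.append(p)

        # ---- step iii: component reconstruction
        logger.info("== stage: fit ==")
        qfits = fit_qdode(matrix, fits, links, order=config.order)
        summary = pd.DataFrame(
            [{"taxon": t, "rss": f.rss, "sigma2": f.sigma2,
              "n_partners": len(f.partners), "converged": f.converged}
             for t, f in qfits.items()]
        )
        p = out / "qdode_summary.tsv"
        summary.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        traj = pd.concat(
            [decompose(f).assign(taxon=t) for t, f in qfits.items()],
            ignore_index=True,
        )
        lead = ["taxon", "sample", "H", "observed", "independent",
                "dependent_pos", "dependent_neg"]
        traj = traj[lead + [c for c in traj.columns if c not in lead]]
        p = out / "trajectories.tsv"
        traj.to_csv(p, sep="\t", index=False)
        outputs.append(p)

        # ---- networks per scope
        logger.info("== stage: network ==")
        for label, subset in sorted(_scopes(matrix, config.scope).items()):
            net = build_network(qfits, sample_subset=subset,
                                eps_factor=config.eps_factor, scope=label)
            tag = "" if label == "all" else f".{label}"
            for name, frame in (("network_edges", net.edge_table()),
                                ("roles", role_table(net)),
                                ("pairs", pair_table(net))):
                p = out / f"{name}{tag}.tsv"
                frame.to_csv(p, sep="\t", index=False)
                outputs.append(p)
            p = out / f"network{tag}.graphml"
            write_graphml(net, p)
            outputs.append(p)

        # ---- step iv: functional clustering (optional)
        if config.cluster:
            logger.info("== stage: cluster ==")
            assignment = select_L(matrix, config.cluster_L_max, seed=config.seed)
            p = out / "modules.tsv"
            pd.DataFrame({
                "taxon": assignment.taxon_ids,
                "module": [f"M{l + 1}" for l in assignment.labels],
                "posterior_max": assignment.posterior.max(axis=1),
            }).to_csv(p, sep="\t", index=False)
            outputs.append(p)
            p = out / "module_params.tsv"
            pd.DataFrame(
                [{"module": f"M{l + 1}", "alpha": mp.alpha, "beta": mp.beta,
                  "sigma2": mp.sigma2, "pi": mp.pi}
                 for l, mp in enumerate(assignment.module_params)]
            ).to_csv(p, sep="\t", index=False)
            outputs.append(p)
            p = out / "bic_path.tsv"
            pd.DataFrame(assignment.bic_path or [], columns=["L", "bic"]).to_csv(
                p, sep="\t", index=False)
            outputs.append(p)
            multilayer = build_multilayer(matrix, assignment, order=config.order,
                                          eps_factor=config.eps_factor)
            p = out / "network_modules.graphml"
            write_graphml(multilayer.coarse, p)
            outputs.append(p)

        # ---- context comparison (optional, graceful when labels missing)
        if config.compare:
            if matrix.context is None:
                logger.warning("no context labels; skipping context comparison")
            else:
                logger.info("== stage: compare ==")
                result = permutation_test(matrix, n_perm=config.n_perm,
                                          seed=config.seed, order=config.order,
                                          weights=config.weights)
                p = out / "compare.json"
                p.write_text(json.dumps({
                    "lr": result.lr, "threshold95": result.threshold95,
                    "pvalue": result.pvalue, "n_perm": result.n_perm,
                    "seed": result.seed,
                }, indent=2, sort_keys=True))
                outputs.append(p)
                p = out / "null_lrs.tsv"
                pd.DataFrame({"lr": result.null_lrs}).to_csv(p, sep="\t", index=False)
                outputs.append(p)

        # ---- manifest (deterministic: no timestamps)
        config_echo = asdict(config)
        config_echo.pop("out_dir")  # keep the manifest location-independent
        manifest = {
            "qdnet_version": __version__,
            "seed": config.seed,
            "config": config_echo,
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
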