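"""Directed, signed, weighted interaction networks from component fits.

Nodes are taxa weighted by their mean independent component; the edge
j' -> j carries the mean of the dependent trajectory G_jj' over an
evaluation sample set (all samples, one gut position, one subject, or a
single sample for an instantaneous "personalized" network).  Edge support
comes from the selection stage, so restricting the evaluation set changes
weights but never the edge set.

An edge whose |weight| falls below the neutrality threshold epsilon keeps
sign 0: it still participates in pair classification (the one-sided
interaction types need a neutral direction) but is excluded from the
degree counts that define node roles.  Pairwise interaction types follow
the standard ecological taxonomy — mutualism, antagonism, commensalism,
amensalism, parasitism, altruism, neutral — as a pure function of the two
thresholded signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .funclust import ModuleAssignment, module_profiles
from .io import AbundanceMatrix
from .qdode import QdODEFit

#: (sign of A->B, sign of B->A) -> interaction label
_PAIR_TABLE = {
    (1, 1): "mutualism",
    (-1, -1): "antagonism",
    (1, 0): "commensalism",
    (0, 1): "commensalism",
    (-1, 0): "amensalism",
    (0, -1): "amensalism",
    (-1, 1): "parasitism",
    (1, -1): "altruism",
    (0, 0): "neutral",
}


@dataclass
class InteractionNetwork:
    """Signed, weighted, directed graph over taxa (or modules)."""

    graph: nx.DiGraph
    scope: str = "all"
    epsilon: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_sign(self, source: str, target: str) -> int:
        """Thresholded sign of source -> target (missing edge -> 0)."""
        data = self.graph.get_edge_data(source, target)
        return 0 if data is None else int(data["sign"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "weight": d["weight"],
             "sign": d["sign"], "strength": d["strength"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "strength"])


@dataclass
class PairClassification:
    pair: tuple[str, str]
    forward_sign: int   # sign of pair[0] -> pair[1]
    reverse_sign: int
    label: str
    note: str


@dataclass
class NodeRole:
    taxon: str
    out_degree: int    # active (outgoing) links
    in_degree: int     # passive (incoming) links
    leader: bool
    hub: bool
    solitary: bool

    @property
    def ordinary(self) -> bool:
        return not (self.leader or self.hub or self.solitary)


def build_network(
    fits: Mapping[str, QdODEFit],
    sample_subset: Sequence[str] | None = None,
    epsilon: float | None = None,
    eps_factor: float = 0.05,
    scope: str = "all",
    agg: str = "mean",
) -> InteractionNetwork:
    """Encode component fits as a graph over one evaluation sample set.

    ``epsilon`` fixes one absolute neutrality threshold for every edge;
    by default the threshold is ``eps_factor`` times the target taxon's
    mean observed abundance over the subset (neutrality is judged relative
    to how abundant the influenced taxon is).  ``agg`` chooses the edge
    aggregation over the subset: ``"mean"`` of the dependent level, or
    ``"terminal"`` — its value at the largest habitat index, the
    instantaneous end-of-gradient view.
    """
    if agg not in ("mean", "terminal"):
        raise ValueError(f"unknown edge aggregation {agg!r}")
    if not fits:
        raise ValueError("no fits supplied")
    first = next(iter(fits.values()))
    if sample_subset is None:
        idx = np.arange(len(first.grid))
    else:
        wanted = set(sample_subset)
        idx = np.array([i for i, s in enumerate(first.sample_ids) if s in wanted])
        if idx.size == 0:
            raise ValueError("empty evaluation sample subset")

    g = nx.DiGraph()
    eps_map: dict[str, float] = {}
    for focal, fit in fits.items():
        eps = epsilon if epsilon is not None else eps_factor * float(fit.observed[idx].mean())
        eps_map[focal] = eps
        g.add_node(
            focal,
            weight=float(fit.independent_traj[idx].mean()),
            abundance=float(fit.observed[idx].mean()),
        )
    for focal, fit in fits.items():
        for partner, lvl in fit.dependent_level.items():
            w = float(lvl[idx].mean()) if agg == "mean" else float(lvl[idx[-1]])
            sign = 0 if abs(w) < eps_map[focal] else int(np.sign(w))
            if partner not in g:
                g.add_node(partner, weight=float("nan"), abundance=float("nan"))
            g.add_edge(partner, focal, weight=w, sign=sign, strength=abs(w))
    return InteractionNetwork(graph=g, scope=scope, epsilon=eps_map)


def interaction_label(forward: int, reverse: int) -> str:
    """Label for a thresholded sign pair (A->B, B->A)."""
    key = (int(np.sign(forward)), int(np.sign(reverse)))
    return _PAIR_TABLE[key]


def classify_pair(net: InteractionNetwork, a: str, b: str) -> PairClassification:
    """Classify the ecological interaction between taxa ``a`` and ``b``."""
    if a == b:
        raise ValueError("cannot classify a taxon against itself")
    sf = net.edge_sign(a, b)
    sr = net.edge_sign(b, a)
    label = interaction_label(sf, sr)
    notes = {
        "mutualism": f"{a} and {b} promote each other",
        "antagonism": f"{a} and {b} inhibit each other",
        "commensalism": (f"{a} promotes {b}; {b} is neutral" if sf > 0
                         else f"{b} promotes {a}; {a} is neutral"),
        "amensalism": (f"{a} inhibits {b}; {b} is neutral" if sf < 0
                       else f"{b} inhibits {a}; {a} is neutral"),
        "parasitism": f"{a} inhibits {b} while {b} promotes {a} ({a} parasitizes {b})",
        "altruism": f"{a} promotes {b} while {b} inhibits {a} ({a} is the altruist)",
        "neutral": f"no effective interaction between {a} and {b}",
    }
    return PairClassification(pair=(a, b), forward_sign=sf, reverse_sign=sr,
                              label=label, note=notes[label])


def classify_roles(net: InteractionNetwork) -> list[NodeRole]:
    """Leader / hub / solitary flags from thresholded degree counts.

    Only edges with nonzero thresholded sign count.  A leader has more
    active (outgoing) than passive (incoming) links; a hub's active links
    exceed the mean total connectivity; a solitary node's total links fall
    strictly below it.  On an edgeless graph the mean is zero and every
    node is ordinary.
    """
    nodes = net.nodes
    out_deg = {v: 0 for v in nodes}
    in_deg = {v: 0 for v in nodes}
    for u, v, d in net.graph.edges(data=True):
        if d["sign"] != 0:
            out_deg[u] += 1
            in_deg[v] += 1
    total = {v: out_deg[v] + in_deg[v] for v in nodes}
    mean_conn = float(np.mean(list(total.values()))) if nodes else 0.0
    return [
        NodeRole(
            taxon=v,
            out_degree=out_deg[v],
            in_degree=in_deg[v],
            leader=out_deg[v] > in_deg[v],
            hub=out_deg[v] > mean_conn,
            solitary=total[v] < mean_conn,
        )
        for v in nodes
    ]


def role_table(net: InteractionNetwork) -> pd.DataFrame:
    rows = [
        {"taxon": r.taxon, "out_degree": r.out_degree, "in_degree": r.in_degree,
         "leader": r.leader, "hub": r.hub, "solitary": r.solitary,
         "ordinary": r.ordinary}
        for r in classify_roles(net)
    ]
    return pd.DataFrame(rows)


def pair_table(net: InteractionNetwork) -> pd.DataFrame:
    nodes = net.nodes
    rows = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            c = classify_pair(net, a, b)
            rows.append({"a": a, "b": b, "sign_ab": c.forward_sign,
                         "sign_ba": c.reverse_sign, "label": c.label,
                         "note": c.note})
    return pd.DataFrame(rows, columns=["a", "b", "sign_ab", "sign_ba", "label", "note"])


def write_graphml(net: InteractionNetwork, path: str | Path) -> None:
    """GraphML export (attribute types coerced for the writer)."""
    g = nx.DiGraph()
    g.graph["scope"] = net.scope
    for v, d in net.graph.nodes(data=True):
        g.add_node(str(v), weight=float(d.get("weight", float("nan"))),
                   abundance=float(d.get("abundance", float("nan"))))
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(str(u), str(v), weight=float(d["weight"]), sign=int(d["sign"]),
                   strength=float(d["strength"]))
    nx.write_graphml(g, str(path))


@dataclass
class MultilayerNetwork:
    """Coarse module-module network plus per-module fine networks."""

    coarse: InteractionNetwork
    fine: dict[str, InteractionNetwork]
    assignment: ModuleAssignment


def build_multilayer(
    matrix: AbundanceMatrix,
    assignment: ModuleAssignment,
    order: int = 3,
    eps_factor: float = 0.05,
    **selection_kwargs,
) -> MultilayerNetwork:
    """Two-layer network: between modules and within each module.

    The coarse layer runs the full selection + component pipeline on the
    module mean-abundance profiles; each fine layer reruns it on the
    member submatrix of one module.  Modules with a single member yield a
    single-node, edgeless network (logged).
    """
    from .allometry import fit_all
    from .qdode import fit_qdode
    from .selection import select_links

    profiles = module_profiles(matrix, assignment)
    pfits = fit_all(profiles)
    plinks = select_links(profiles, pfits, order=order, **selection_kwargs)
    pfit_q = fit_qdode(profiles, pfits, plinks, order=order)
    coarse = build_network(pfit_q, eps_factor=eps_factor, scope="modules")

    fine: dict[str, InteractionNetwork] = {}
    for label in profiles.taxon_ids:
        members = [t for t, lab in zip(matrix.taxon_ids, assignment.labels) if f"M{lab + 1}" == label]
        if len(members) < 2:
            logger.info("module %s has a single member; edgeless fine network", label)
            g = nx.DiGraph()
            if members:
                g.add_node(members[0], weight=float("nan"), abundance=float("nan"))
            fine[label] = InteractionNetwork(graph=g, scope=label)
            continue
        sub = matrix.subset_taxa(members)
        sfits = fit_all(sub)
        if len(members) == 2:
            # selection needs >= 2 partner blocks; with one partner the
            # support question is trivial and both links are carried forward
            slinks = {members[0]: [members[1]], members[1]: [members[0]]}
        else:
            slinks = select_links(sub, sfits, order=order, **selection_kwargs)
        sfit_q = fit_qdode(sub, sfits, slinks, order=order)
        fine[label] = build_network(sfit_q, eps_factor=eps_factor, scope=label)
    return MultilayerNetwork(coarse=coarse, fine=fine, assignment=assignment)
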