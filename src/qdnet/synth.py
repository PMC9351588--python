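"""Synthetic abundance data with known ground truth.

The generator emulates the generative assumptions of the whole pipeline so
that every stage can be tested without external data:

* habitat indices are drawn (log-uniformly by default) over a range, not
  derived from column sums — the quasi-dynamic axis must exist before the
  abundances it generates, so the circularity between the drawn H and the
  realized row sums is left open and both are recorded in the truth bundle;
* each taxon has a baseline power-law curve ``alpha_j * H**beta_j``; its
  *realized* independent component ``x_j`` multiplies that curve by
  sample-specific biological variation (lognormal, ``sigma_bio``) — the
  sample-to-sample variation real communities show around their trend;
* a planted sparse signed adjacency couples taxa multiplicatively, in the
  log-linear Lotka-Volterra equilibrium form: with ``delta_j = log(A_j /
  baseline_j)`` the realized log-deviation, each sample solves the linear
  system ``delta = eps + S delta`` where ``S`` holds the signed couplings
  — promotion (s > 0) lifts the target when its partner sits above the
  partner's habitat-expected abundance, inhibition suppresses it, and
  abundances are positive by construction.  Partners form an undirected
  pair graph (each direction with its own sign), the way ecological
  interactions are catalogued; stability of the equilibrium is enforced
  by rejection (redraw until Re(eig(S)) < 1 and I - S is well
  conditioned).  The truth bundle stores the first-order additive
  attribution ``dep_jj'(i) = A_j(i) * s_jj' * delta_j'(i)`` of each link,
  which is what the additive inference stages estimate;
* optional module structure groups taxa around shared curve shapes;
* optional contexts rescale or sign-flip chosen links per group;
* measurement noise (multiplicative lognormal ``sigma_log``, optionally
  plus additive Gaussian) is applied last.

The truth bundle records per-link signal-to-noise as the ratio of the
dependent component's spread to the measurement-noise spread; biological
variation is signal-bearing (it is what propagates through interactions),
not noise.  Every draw flows from a mandatory integer seed, so identical
configs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AbundanceMatrix


@dataclass(frozen=True)
class PlantedLink:
    """Directed influence ``source -> target`` with signed strength.

    ``strength`` is the dimensionless log-scale coupling ``s`` of the
    multiplicative kernel; its sign is the planted interaction sign.
    """

    target: int
    source: int
    strength: float


@dataclass
class ContextEffect:
    """Per-context modulation of planted links.

    ``sizes`` maps context label -> number of samples; ``multipliers`` maps
    context label -> {(target, source): factor} applied to the link strength
    in that context (e.g. ``-1.0`` flips promotion to inhibition).  Links
    not named keep their base strength.
    """

    sizes: dict[str, int]
    multipliers: dict[str, dict[tuple[int, int], float]] = field(default_factory=dict)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset (seed mandatory)."""

    n_samples: int
    n_taxa: int
    seed: int
    n_modules: int = 1
    h_min: float = 1.0
    h_max: float = 6.0
    h_law: str = "loguniform"  # or "uniform"
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    beta_range: tuple[float, float] = (-0.8, 1.4)
    module_alpha_jitter: float = 0.1   # within-module lognormal spread of alpha
    module_beta_jitter: float = 0.05   # within-module spread of beta
    links: list[PlantedLink] | None = None
    n_partners: int = 0       # used to draw a random adjacency when links is None
    link_strength: float = 0.5  # per-link |s|, the log-scale coupling
    p_opposite: float = 0.5     # fraction of opposite-sign (exploiter/victim) pairs
    same_sign_factor: float = 1.0  # relative coupling scale of same-sign pairs
    stability_margin: float = 0.3  # distance kept from the instability point
    sigma_bio: float | np.ndarray = 0.25  # biological lognormal spread (scalar or per-taxon)
    sigma_log: float = 0.05   # multiplicative measurement noise
    sigma_add: float = 0.0
    contexts: ContextEffect | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_partners >= self.n_taxa:
            raise ValueError("n_partners must be < n_taxa")
        if self.contexts is not None:
            total = sum(self.contexts.sizes.values())
            if total != self.n_samples:
                raise ValueError("context sizes must sum to n_samples")


@dataclass
class SynthTruth:
    """Ground truth emitted alongside a generated matrix."""

    H: np.ndarray                      # drawn habitat indices (sorted)
    alpha: np.ndarray
    beta: np.ndarray
    links: list[PlantedLink]
    module_labels: np.ndarray
    context_labels: np.ndarray | None
    independent: np.ndarray            # (n, m) realized baseline component x
    dependent: dict[tuple[int, int], np.ndarray]  # (target, source) -> (n,) first-order values
    noiseless: np.ndarray              # (n, m) pre-measurement-noise abundances
    row_sum_vs_H: np.ndarray           # realized row sums minus drawn H
    snr: dict[tuple[int, int], float]  # per-link dependent sd / measurement-noise sd

    def adjacency_sign(self) -> np.ndarray:
        m = len(self.alpha)
        A = np.zeros((m, m))
        for link in self.links:
            A[link.source, link.target] = np.sign(link.strength)
        return A

    def promotion_inhibition_ratio(self) -> float:
        """Total planted promotion mass over total inhibition mass."""
        pos = sum(np.clip(d, 0, None).sum() for d in self.dependent.values())
        neg = -sum(np.clip(d, None, 0).sum() for d in self.dependent.values())
        return float(pos / neg) if neg > 0 else float("inf")


def _draw_curves(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline (alpha, beta) per taxon, plus module labels.

    Exponents span decreasing and increasing scaling (the field observes
    both signs across phyla); with modules, taxa in a module share a curve
    shape up to small jitter.
    """
    m, L = cfg.n_taxa, cfg.n_modules
    lo, hi = cfg.beta_range
    if L > 1:
        labels = np.sort(rng.integers(0, L, size=m))
        labels[:L] = np.arange(L)  # every module populated
        labels = labels[rng.permutation(m)]
        beta_mod = np.linspace(lo, hi, L)
        alpha_mod = np.exp(np.linspace(np.log(0.5), np.log(5.0), L))
        beta = beta_mod[labels] + rng.normal(0, cfg.module_beta_jitter, size=m)
        alpha = alpha_mod[labels] * np.exp(rng.normal(0, cfg.module_alpha_jitter, size=m))
    else:
        labels = np.zeros(m, dtype=int)
        beta = rng.permutation(np.linspace(lo, hi, m)) + rng.normal(0, 0.05, size=m)
        alpha = np.exp(rng.normal(np.log(2.0), 0.4, size=m))
    if cfg.alpha is not None:
        alpha = np.asarray(cfg.alpha, dtype=float)
    if cfg.beta is not None:
        beta = np.asarray(cfg.beta, dtype=float)
    if len(alpha) != m or len(beta) != m:
        raise ValueError("alpha/beta must have length n_taxa")
    return alpha, beta, labels


def _pair_partners(m: int, k: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random k-regular (or near-regular) undirected partner graph.

    Edge-swap construction on a stacked permutation; falls back to
    near-regularity when parity forbids an exact k-regular graph.
    """
    edges: set[tuple[int, int]] = set()
    degree = np.zeros(m, dtype=int)
    # greedy pairing with retries: repeatedly match lowest-degree nodes
    for _ in range(20 * m * k):
        if degree.min() >= k:
            break
        cands = np.flatnonzero(degree < k)
        a = int(cands[rng.integers(len(cands))])
        others = [b for b in cands if b != a and (min(a, b), max(a, b)) not in edges]
        if not others:
            others = [b for b in range(m) if b != a and (min(a, b), max(a, b)) not in edges]
            if not others:
                break
        b = int(others[rng.integers(len(others))])
        edges.add((min(a, b), max(a, b)))
        degree[a] += 1
        degree[b] += 1
    return sorted(edges)


def _draw_links(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[PlantedLink]:
    """Random sparse signed adjacency with +/- couplings of ``link_strength``.

    The default topology is *paired*: partners form an undirected graph
    with ``n_partners`` neighbors per taxon, and each direction of a pair
    gets its own independent sign — so mutualism, antagonism and the
    mixed-sign pairs all arise.  Pairedness reflects how ecological
    interactions are described (the classic interaction taxonomy is about
    pairs) and matches what cross-sectional data can identify.
    """
    if cfg.links is not None:
        return list(cfg.links)
    links: list[PlantedLink] = []
    if cfg.n_partners > 0:
        for a, b in _pair_partners(cfg.n_taxa, cfg.n_partners, rng):
            # Pair types follow community-stability theory: opposite-sign
            # (exploiter/victim) pairs stabilize and can couple strongly;
            # same-sign pairs (mutualism, competition) destabilize per unit
            # coupling and carry proportionally weaker strengths.
            u = rng.random()
            if u < cfg.p_opposite:
                sgn = rng.choice([-1.0, 1.0])
                s_ab, s_ba = sgn, -sgn
                scale = cfg.link_strength
            else:
                sgn = rng.choice([-1.0, 1.0])
                s_ab = s_ba = sgn
                scale = cfg.same_sign_factor * cfg.link_strength
            links.append(PlantedLink(target=b, source=a, strength=float(s_ab * scale)))
            links.append(PlantedLink(target=a, source=b, strength=float(s_ba * scale)))
    if cfg.contexts is not None:
        # links referenced by a context multiplier must exist
        wanted = {key for table in cfg.contexts.multipliers.values() for key in table}
        present = {(lk.target, lk.source) for lk in links}
        for tgt, src in sorted(wanted - present):
            links.append(PlantedLink(target=tgt, source=src,
                                     strength=float(cfg.link_strength)))
    return links


def generate(cfg: GeneratorConfig) -> tuple[AbundanceMatrix, SynthTruth]:
    """Draw one dataset and its truth bundle (deterministic in the seed)."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_taxa

    if cfg.h_law == "loguniform":
        H = np.exp(rng.uniform(np.log(cfg.h_min), np.log(cfg.h_max), size=n))
    elif cfg.h_law == "uniform":
        H = rng.uniform(cfg.h_min, cfg.h_max, size=n)
    else:
        raise ValueError(f"unknown habitat sampling law {cfg.h_law!r}")
    H = np.sort(H)
    H[0], H[-1] = cfg.h_min, cfg.h_max  # anchor the range so curves span it

    alpha, beta, module_labels = _draw_curves(cfg, rng)
    baseline = alpha[None, :] * H[:, None] ** beta[None, :]
    base_mean = baseline.mean(axis=0)

    context_labels: np.ndarray | None = None
    if cfg.contexts is not None:
        labs: list[str] = []
        for lab, size in cfg.contexts.sizes.items():
            labs.extend([lab] * size)
        context_labels = np.array(labs, dtype=object)[rng.permutation(n)]

    def _mult(link: PlantedLink) -> np.ndarray:
        out = np.ones(n)
        if context_labels is not None:
            for lab, table in cfg.contexts.multipliers.items():
                factor = table.get((link.target, link.source))
                if factor is not None:
                    out[context_labels == lab] = factor
        return out

    # Realized community state: interactions couple *log deviations* from
    # the habitat-expected baseline, delta_j = log(A_j / baseline_j), via
    # the linear system delta = eps + S delta per sample (S holds the
    # signed couplings).  This is the log-linear Lotka-Volterra-style
    # equilibrium: solvable exactly, always positive, and every link
    # responds to its partner's realized abundance.
    sigma_bio = np.broadcast_to(np.asarray(cfg.sigma_bio, dtype=float), (m,))
    eps = rng.normal(0.0, 1.0, size=(n, m)) * sigma_bio[None, :]
    eye = np.eye(m)

    def _coupling_rows(links: list[PlantedLink], mults) -> list[np.ndarray] | None:
        """Per-sample coupling matrices, or None if any is unstable."""
        out = []
        base = np.zeros((m, m))
        for lk in links:
            base[lk.target, lk.source] += lk.strength
        varying = any(np.ptp(v) > 0 for v in mults.values())
        for i in range(n):
            if varying or i == 0:
                S = np.zeros((m, m))
                for lk in links:
                    S[lk.target, lk.source] += lk.strength * mults[(lk.target, lk.source)][i]
            if i == 0 or varying:
                # dynamic stability of the equilibrium needs Re(eig) < 1;
                # a well-posed response solve needs I - S far from singular
                # (the margin caps the community's response amplification)
                eig = np.linalg.eigvals(S)
                if (np.max(eig.real) >= 1.0 - cfg.stability_margin
                        or np.min(np.abs(1.0 - eig)) < cfg.stability_margin):
                    return None
            out.append(S)
        return out

    # draw adjacencies until the planted system is stable (deterministic
    # in the seed); a fixed user-supplied adjacency must be stable itself
    for attempt in range(40):
        links = _draw_links(cfg, rng)
        mults = {(lk.target, lk.source): _mult(lk) for lk in links}
        rows = _coupling_rows(links, mults)
        if rows is not None:
            break
        if cfg.links is not None:
            raise ValueError(
                "planted interaction system is unstable (spectral radius of "
                "the coupling matrix >= 0.95); reduce link strengths"
            )
    else:
        raise ValueError(
            "could not draw a stable interaction system; reduce "
            "link_strength or n_partners"
        )
    delta = np.empty((n, m))
    for i in range(n):
        delta[i] = np.linalg.solve(eye - rows[i], eps[i])
    x = baseline * np.exp(eps)  # realized independent component
    A = baseline * np.exp(delta)
    noiseless = A
    g_link = {
        (lk.target, lk.source):
            lk.strength * mults[(lk.target, lk.source)] * delta[:, lk.source]
        for lk in links
    }
    # first-order additive attribution of each link's effect
    dependent = {key: A[:, key[0]] * g for key, g in g_link.items()}

    noisy = noiseless * np.exp(rng.normal(0.0, cfg.sigma_log, size=(n, m)))
    if cfg.sigma_add > 0:
        noisy = np.clip(noisy + rng.normal(0.0, cfg.sigma_add, size=(n, m)), 0.0, None)

    meas_sd = np.maximum(np.std(noisy - noiseless, axis=0), 1e-300)
    snr = {key: float(np.std(dep) / meas_sd[key[0]]) for key, dep in dependent.items()}

    matrix = AbundanceMatrix(
        noisy,
        sample_ids=[f"S{i + 1:03d}" for i in range(n)],
        taxon_ids=[f"T{j + 1:03d}" for j in range(m)],
        context=context_labels,
    )
    truth = SynthTruth(
        H=H, alpha=alpha, beta=beta, links=links,
        module_labels=module_labels, context_labels=context_labels,
        independent=x, dependent=dependent, noiseless=noiseless,
        row_sum_vs_H=noisy.sum(axis=1) - H, snr=snr,
    )
    return matrix, truth


def scenario(name: str, seed: int = 0) -> GeneratorConfig:
    """Ready-made configs mimicking the motivating study's dimensions.

    * ``phylum17`` — 23 samples x 17 taxa (16 abundant groups plus an
      aggregate remainder), sparse planted links.
    * ``species65_7mod`` — 65 taxa in 7 curve-shape modules, 23 samples.
    * ``two_context`` — a diseased-vs-healthy style design (16 vs 7
      samples) in which one strong link flips sign between contexts.
    """
    if name == "phylum17":
        return GeneratorConfig(n_samples=23, n_taxa=17, seed=seed,
                               n_partners=2, link_strength=0.5)
    if name == "species65_7mod":
        return GeneratorConfig(n_samples=23, n_taxa=65, n_modules=7, seed=seed,
                               n_partners=2, link_strength=0.4, sigma_bio=0.15)
    if name == "two_context":
        contexts = ContextEffect(
            sizes={"UC": 16, "HC": 7},
            multipliers={"HC": {(0, 1): -1.0}},
        )
        return GeneratorConfig(n_samples=23, n_taxa=10, seed=seed,
                               n_partners=2, link_strength=0.6,
                               contexts=contexts)
    raise ValueError(f"unknown scenario {name!r}")
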