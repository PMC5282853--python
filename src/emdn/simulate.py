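"""Synthetic data generators for benchmarking the whole pipeline.

Three generators:

* :func:`make_artificial` — the multiplex community benchmark: networks of
  256 nodes in eight equal clusters, every node with degree exactly 32, a
  per-network mixing parameter mu controlling the fraction of each node's
  edges that leave its cluster, and one shared ground-truth partition.
* :func:`implant_module_simulation` — a scale-free background network
  (~7000 genes) with an implanted 11-gene star module (hub + 10
  neighbors).  Per layer, differential statistics for module genes are
  resampled from the extreme 5% tails of a standard-normal reference
  pool and background genes from the middle 90%, mapped to two-sided
  p-values, and turned into differential-network edge weights on the
  fixed topology.
* :func:`synth_omics` — paired expression/methylation matrices with
  planted correlated modules (positive or negative methylation-
  expression coupling) and tumor/normal group structure, for end-to-end
  tests of the full matrix-to-modules pipeline.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special

from emdn.diffnet import eq1_weights, PValueVector, bh_adjust
from emdn.netio import (
    DifferentialNetwork,
    OmicsMatrix,
    SampleLabels,
    ValidationError,
)

__all__ = [
    "SimulationSpec",
    "ImplantSpec",
    "make_artificial",
    "implant_module_simulation",
    "synth_omics",
]


# ---------------------------------------------------------------------------
# multiplex community benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one benchmark network.

    mixing is the fraction of each node's edges leaving its cluster;
    intra-cluster stubs per node are round((1 - mixing) * degree), the
    remainder inter-cluster.
    """

    n_nodes: int = 256
    n_clusters: int = 8
    degree: int = 32
    mixing: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes % self.n_clusters != 0:
            raise ValidationError("n_nodes must be divisible by n_clusters")
        if not (0 <= self.mixing <= 1):
            raise ValidationError("mixing must lie in [0, 1]")
        size = self.n_nodes // self.n_clusters
        if self.intra_degree > size - 1:
            raise ValidationError(
                f"intra-cluster degree {self.intra_degree} exceeds cluster capacity"
            )
        inter_capacity = self.n_nodes - size
        if self.degree - self.intra_degree > inter_capacity:
            raise ValidationError("inter-cluster degree exceeds capacity")

    @property
    def intra_degree(self) -> int:
        return int(round((1.0 - self.mixing) * self.degree))

    @property
    def inter_degree(self) -> int:
        return self.degree - self.intra_degree


def _regular_subgraph(nodes: list, d: int, rng: np.random.Generator) -> list[tuple]:
    """Random d-regular graph on ``nodes`` (d * len even required)."""
    n = len(nodes)
    if d == 0:
        return []
    if (d * n) % 2 == 1:
        raise ValidationError("degree sequence has odd sum; adjust parameters")
    seed = int(rng.integers(2**31 - 1))
    if d > (n - 1) / 2:
        # dense: draw the sparse complement and invert (still uniform)
        comp = nx.random_regular_graph(n - 1 - d, n, seed=seed)
        g = nx.complement(comp)
    else:
        g = nx.random_regular_graph(d, n, seed=seed)
    return [(nodes[u], nodes[v]) for u, v in g.edges()]


def _match_inter_stubs(
    cluster_of: dict, stubs_per_node: int, rng: np.random.Generator,
    forbidden: set, max_restarts: int = 200,
) -> list[tuple]:
    """Uniform random matching of inter-cluster stubs.

    Every node contributes ``stubs_per_node`` stubs; stubs are shuffled
    and paired; pairs that would create a self-loop, a multi-edge or an
    intra-cluster edge are re-drawn by local swaps, with full restarts as
    a fallback.
    """
    nodes = list(cluster_of)
    stubs = np.array([n for n in nodes for _ in range(stubs_per_node)], dtype=object)
    if len(stubs) % 2 == 1:
        raise ValidationError("odd total of inter-cluster stubs; adjust parameters")

    def bad_pairs(pairs: list[tuple]) -> list[int]:
        seen: set = set()
        bad = []
        for i, (u, v) in enumerate(pairs):
            key = frozenset((u, v))
            if u == v or cluster_of[u] == cluster_of[v] or key in forbidden or key in seen:
                bad.append(i)
            else:
                seen.add(key)
        return bad

    for _ in range(max_restarts):
        s = stubs[rng.permutation(len(stubs))]
        pairs = list(zip(s[0::2], s[1::2]))
        for _repair in range(20 * len(pairs) + 20):
            bad = bad_pairs(pairs)
            if not bad:
                return [tuple(sorted(p, key=str)) for p in pairs]
            i = bad[0]
            j = int(rng.integers(len(pairs)))
            if i == j:
                continue
            (u1, v1), (u2, v2) = pairs[i], pairs[j]
            pairs[i], pairs[j] = (u1, v2), (u2, v1)
    raise ValidationError(
        "could not match inter-cluster stubs; try a different mixing/degree"
    )


def make_artificial(
    specs: list[SimulationSpec],
) -> tuple[list[DifferentialNetwork], list[set]]:
    """Generate benchmark networks sharing one ground-truth partition.

    Every network in ``specs`` must agree on n_nodes / n_clusters /
    degree; each gets round((1-mu) * degree) intra-cluster and the
    remaining inter-cluster unit-weight edges per node, so node degrees
    are exactly ``degree``.  Cluster membership is assigned by a random
    permutation of node labels (driven by the first spec's seed) and is
    identical across networks.

    Returns (networks, partition) with the partition as a list of node
    sets.
    """
    if not specs:
        raise ValidationError("need at least one SimulationSpec")
    first = specs[0]
    for s in specs[1:]:
        if (s.n_nodes, s.n_clusters, s.degree) != (
            first.n_nodes, first.n_clusters, first.degree,
        ):
            raise ValidationError("all networks must share n_nodes/n_clusters/degree")

    width = len(str(first.n_nodes))
    names = [f"n{i:0{width}d}" for i in range(first.n_nodes)]
    size = first.n_nodes // first.n_clusters
    label_rng = np.random.default_rng(first.rng_seed)
    shuffled = list(label_rng.permutation(names))
    blocks = [sorted(shuffled[c * size : (c + 1) * size])
              for c in range(first.n_clusters)]
    clusters = [set(b) for b in blocks]
    # iterate sorted lists, never sets: node names are strings and set
    # order would leak per-process hash randomization into the RNG stream
    cluster_of = {n: c for c, block in enumerate(blocks) for n in block}

    nets = []
    for s in specs:
        rng = np.random.default_rng(s.rng_seed + 1)
        edges: list[tuple] = []
        for block in blocks:
            edges.extend(_regular_subgraph(block, s.intra_degree, rng))
        if s.inter_degree > 0:
            forbidden = {frozenset(e) for e in edges}
            edges.extend(
                _match_inter_stubs(cluster_of, s.inter_degree, rng, forbidden)
            )
        g = nx.Graph()
        g.add_nodes_from(names)
        g.add_edges_from((u, v, {"weight": 1.0}) for u, v in edges)
        nets.append(DifferentialNetwork(graph=g, layer_tag="expression", delta=None))
    return nets, clusters


# ---------------------------------------------------------------------------
# implanted-module differential-statistics simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImplantSpec:
    """Parameters of the implanted-module recovery simulation.

    The background is a preferential-attachment network (a stand-in for a
    protein-interaction scaffold); its size sets the granularity of the
    false-positive rate (~1/background_size).
    """

    background_size: int = 7000
    attachment: int = 3
    module_genes: int = 11
    tail_quantile: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tail_quantile < 0.5):
            raise ValidationError("tail_quantile must lie in (0, 0.5)")
        if self.module_genes < 2:
            raise ValidationError("module_genes must be >= 2")


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.clip(special.erfc(np.abs(z) / math.sqrt(2.0)), 1e-300, 1.0)


def implant_module_simulation(
    spec: ImplantSpec,
) -> tuple[pd.Series, pd.Series, list[DifferentialNetwork], set]:
    """Build the implanted-module multiplex.

    Returns (expression statistics, methylation statistics, networks,
    truth gene set).  The two layers share one topology: the scale-free
    background with a star module (hub + module_genes - 1 leaves) wired
    in.  Per layer, a reference pool of 10 * n standard-normal statistics
    is drawn; module genes resample from the pool values at or beyond
    the tail_quantile / 1 - tail_quantile quantiles, background genes
    from the middle portion.  Statistics map to two-sided normal
    p-values, and edge weights follow the differential-network rule.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.background_size
    width = len(str(n))
    names = [f"g{i:0{width}d}" for i in range(n)]
    g = nx.barabasi_albert_graph(n, spec.attachment,
                                 seed=int(rng.integers(2**31 - 1)))
    g = nx.relabel_nodes(g, {i: names[i] for i in range(n)})

    members = rng.choice(n, size=spec.module_genes, replace=False)
    hub, leaves = names[members[0]], [names[i] for i in members[1:]]
    for leaf in leaves:
        g.add_edge(hub, leaf)
    truth = {hub, *leaves}

    genes = list(g.nodes)
    stats_per_layer = []
    nets = []
    for layer in ("expression", "methylation"):
        pool = rng.standard_normal(10 * n)
        lo, hi = np.quantile(pool, [spec.tail_quantile, 1.0 - spec.tail_quantile])
        tails = pool[(pool <= lo) | (pool >= hi)]
        middle = pool[(pool > lo) & (pool < hi)]
        z = pd.Series(index=genes, dtype=float)
        is_member = z.index.isin(truth)
        z[is_member] = rng.choice(tails, size=int(is_member.sum()), replace=True)
        z[~is_member] = rng.choice(middle, size=int((~is_member).sum()), replace=True)
        stats_per_layer.append(z)

        raw = pd.Series(_two_sided_p(z.to_numpy()), index=genes)
        pv = PValueVector(raw=raw, adjusted=pd.Series(bh_adjust(raw), index=genes))
        edges = {(u, v): 1.0 for u, v in g.edges()}
        nets.append(
            eq1_weights(genes, edges, pv, layer_tag=layer, delta=None)
        )
    return stats_per_layer[0], stats_per_layer[1], nets, truth


# ---------------------------------------------------------------------------
# paired omics matrices with planted modules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedModule:
    genes: tuple[str, ...]
    sign: str  # positive / negative methylation-expression coupling

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative"):
            raise ValidationError("sign must be 'positive' or 'negative'")
        if len(self.genes) < 5:
            raise ValidationError("planted modules need >= 5 genes")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def synth_omics(
    n_genes: int = 200,
    n_samples_tumor: int = 40,
    n_samples_normal: int = 40,
    planted_modules: list[tuple[int, str]] | None = None,
    noise_sd: float = 0.3,
    effect: float = 1.0,
    rng_seed: int = 0,
) -> tuple[OmicsMatrix, OmicsMatrix, SampleLabels, list[PlantedModule]]:
    """Paired expression/methylation matrices with planted modules.

    ``planted_modules`` lists (size, sign) pairs (default: one positive
    and one negative module of 10 genes).  Genes of a module share a
    latent per-sample factor whose mean is shifted by ``effect`` (in
    units of the latent's standard deviation; default one SD) in tumor
    samples; expression tracks the factor, methylation tracks +factor or
    -factor according to the module sign and is squashed into [0, 1] by a
    logistic.  Background genes are independent noise.  Sample order is
    tumor samples first, then normal.  Distinct modules share only the
    tumor shift, so the shift must stay moderate: a large shift makes
    genes of different modules co-vary across the pooled samples and the
    planted modules stop being separable coexpression clusters.

    Returns (expression, methylation, labels, truth).
    """
    if planted_modules is None:
        planted_modules = [(10, "positive"), (10, "negative")]
    rng = np.random.default_rng(rng_seed)
    n_samples = n_samples_tumor + n_samples_normal
    gw = len(str(n_genes))
    genes = [f"g{i:0{gw}d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    labels = SampleLabels(
        labels={
            s: ("tumor" if j < n_samples_tumor else "normal")
            for j, s in enumerate(samples)
        }
    )

    expr = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    meth_raw = rng.normal(0.0, 1.0, size=(n_genes, n_samples))

    total = sum(size for size, _ in planted_modules)
    if total > n_genes:
        raise ValidationError("planted modules exceed gene count")
    member_idx = rng.choice(n_genes, size=total, replace=False)
    truth: list[PlantedModule] = []
    pos = 0
    for size, sign in planted_modules:
        idx = member_idx[pos : pos + size]
        pos += size
        latent = rng.normal(0.0, 1.0, size=n_samples)
        latent[:n_samples_tumor] += effect
        loadings = rng.uniform(0.8, 1.2, size=size)
        noise_e = rng.normal(0.0, noise_sd, size=(size, n_samples)) if noise_sd > 0 else 0.0
        noise_m = rng.normal(0.0, noise_sd, size=(size, n_samples)) if noise_sd > 0 else 0.0
        expr[idx] = loadings[:, None] * latent[None, :] + noise_e
        s = 1.0 if sign == "positive" else -1.0
        meth_raw[idx] = s * loadings[:, None] * latent[None, :] + noise_m
        truth.append(
            PlantedModule(genes=tuple(sorted(genes[i] for i in idx)), sign=sign)
        )

    expr_m = OmicsMatrix(
        data=pd.DataFrame(expr, index=genes, columns=samples), layer_tag="expression"
    )
    meth_m = OmicsMatrix(
        data=pd.DataFrame(_logistic(meth_raw), index=genes, columns=samples),
        layer_tag="methylation",
    )
    return expr_m, meth_m, labels, truth
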