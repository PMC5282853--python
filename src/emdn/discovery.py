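"""Common-module discovery across multiple differential networks.

The search has three stages, run on the multiplex formed by the
differential coexpression and comethylation networks (any number of
layers is supported):

1. *Seed prioritization.*  Genes are scored per layer by network
   propagation, the fixed point of f = alpha A' f + (1 - alpha) Y with
   A' = D^{-1/2} W D^{-1/2} the symmetrically normalized adjacency and Y
   a prior vector (uniform by default: with an all-zero prior the fixed
   point is identically zero, so "no prior" is expressed as a uniform
   restart in the random-walk-with-restart sense).  Per-layer scores are
   z-scored across genes and summed row-wise over layers; the top
   fraction (default 5%) become expansion seeds.

2. *Entropy-greedy expansion.*  For a gene set C, each layer k gets an
   internal-weight fraction

       p_k(C) = sum_{i,j in C} w_ijk / sum_{i in C} strength_k(i)

   (both sums count internal weight in both directions), a binary entropy
   H_k = -p_k log p_k - (1-p_k) log(1-p_k), and the combined objective
   H(C) = sum_k H_k / |C|.  Each module starts as the seed plus its
   all-layer neighborhood and grows greedily within the seed's locality:
   a gene is added only if H strictly decreases and the total internal
   fraction sum_k p_k does not drop (the binary entropy is symmetric in
   p_k <-> 1-p_k, so without the cohesion guard the minimization would
   equally reward driving p_k toward 0 by absorbing weakly attached
   high-strength nodes).  Candidates must be adjacent to C in every
   layer (a common module is linked in all networks).

3. *Refinement and significance.*  Modules smaller than 5 genes are
   dropped, pairs with Jaccard index > 0.5 are merged (highest first),
   and surviving modules are tested against a null score distribution
   obtained by re-running the search on degree-preserving randomizations
   of every layer (double-edge swaps, weights traveling with edges),
   with Benjamini-Hochberg correction across modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import scipy.sparse as sp

from emdn.diffnet import bh_adjust
from emdn.netio import DifferentialNetwork, Module, ModuleSet, ValidationError

__all__ = [
    "DiscoveryParams",
    "GeneRanking",
    "Multiplex",
    "normalize_adjacency",
    "rank_genes",
    "select_seeds",
    "module_entropy",
    "greedy_expand",
    "expand_seed",
    "refine",
    "randomize_network",
    "assess_significance",
    "discover",
]


@dataclass(frozen=True)
class DiscoveryParams:
    """Tunable knobs of the module search.

    alpha : restart weight of the propagation (0, 1).
    seed_fraction : fraction of top-ranked genes used as seeds.
    min_size : modules smaller than this are dropped in refinement.
    jaccard_merge : merge modules whose Jaccard index strictly exceeds this.
    max_size : hard cap on greedy module growth.
    n_random : degree-preserving randomizations per layer for the null
        distribution (0 skips significance assessment).
    rng_seed : seed for the randomization RNG.
    tol, max_iter : propagation convergence controls.
    """

    alpha: float = 0.85
    seed_fraction: float = 0.05
    min_size: int = 5
    jaccard_merge: float = 0.5
    max_size: int = 100
    n_random: int = 100
    rng_seed: int = 0
    tol: float = 1e-6
    max_iter: int = 1000


# ---------------------------------------------------------------------------
# multiplex container
# ---------------------------------------------------------------------------


class Multiplex:
    """Index-aligned sparse view of several networks over one node universe.

    Nodes are the sorted union of all layer node sets; each layer is a CSR
    adjacency over that universe (absent nodes have degree 0).
    """

    def __init__(self, nets: list[DifferentialNetwork]):
        if not nets:
            raise ValidationError("need at least one network")
        universe: set = set()
        for net in nets:
            universe |= set(net.graph.nodes)
        self.nodes: list = sorted(universe, key=str)
        self.index = {g: i for i, g in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.layers: list[sp.csr_matrix] = []
        self.layer_tags = [net.layer_tag for net in nets]
        for net in nets:
            A = sp.lil_matrix((self.n, self.n))
            for u, v, d in net.graph.edges(data=True):
                i, j = self.index[u], self.index[v]
                A[i, j] = d["weight"]
                A[j, i] = d["weight"]
            self.layers.append(A.tocsr())
        self.strengths = [np.asarray(A.sum(axis=1)).ravel() for A in self.layers]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def row(self, k: int, i: int) -> tuple[np.ndarray, np.ndarray]:
        A = self.layers[k]
        sl = slice(A.indptr[i], A.indptr[i + 1])
        return A.indices[sl], A.data[sl]


# ---------------------------------------------------------------------------
# seed prioritization
# ---------------------------------------------------------------------------


def normalize_adjacency(W: np.ndarray | sp.spmatrix) -> np.ndarray | sp.csr_matrix:
    """Symmetric normalization A' = D^{-1/2} W D^{-1/2}.

    Rows/columns of zero-degree nodes are left zero.
    """
    sparse = sp.issparse(W)
    d = np.asarray(W.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    if sparse:
        Dinv = sp.diags(inv_sqrt)
        return (Dinv @ W @ Dinv).tocsr()
    return inv_sqrt[:, None] * np.asarray(W, dtype=float) * inv_sqrt[None, :]


@dataclass
class GeneRanking:
    """Per-layer propagation scores, their z-scores, and the aggregate."""

    nodes: list
    scores: np.ndarray  # n x M, column per layer (matrix R)
    zscores: np.ndarray  # n x M
    aggregate: np.ndarray  # row sums of zscores
    alpha: float
    iterations_used: int


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def rank_genes(
    nets: list[DifferentialNetwork] | Multiplex,
    alpha: float = 0.85,
    Y: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    method: str = "iterative",
) -> GeneRanking:
    """Propagation-based gene ranking over all layers.

    Solves f = alpha A' f + (1 - alpha) Y per layer, starting from f = 0
    (equivalently f = (1-alpha)(I - alpha A')^{-1} Y), z-scores every
    layer's scores across genes and sums them row-wise.

    ``Y`` defaults to the uniform vector 1/n; an all-zero prior is
    rejected because its fixed point is identically zero.
    ``method="direct"`` solves the linear system densely (for testing and
    small graphs).
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    mx = nets if isinstance(nets, Multiplex) else Multiplex(nets)
    n = mx.n
    if Y is None:
        Y = np.full(n, 1.0 / n)
    else:
        Y = np.asarray(Y, dtype=float)
        if Y.shape != (n,):
            raise ValidationError(f"prior Y must have length {n}")
        if not np.any(Y):
            raise ValidationError(
                "degenerate prior: Y = 0 has the all-zero fixed point; "
                "use a uniform or informative prior"
            )

    cols, iters_used = [], 0
    for A in mx.layers:
        An = normalize_adjacency(A)
        if method == "direct":
            f = np.linalg.solve(
                np.eye(n) - alpha * An.toarray(), (1.0 - alpha) * Y
            )
        else:
            f = np.zeros(n)
            for it in range(1, max_iter + 1):
                f_new = alpha * (An @ f) + (1.0 - alpha) * Y
                delta = np.max(np.abs(f_new - f))
                f = f_new
                if delta < tol:
                    break
            else:
                raise ValidationError(
                    f"propagation did not converge in {max_iter} iterations "
                    f"(residual {delta:.3g})"
                )
            iters_used = max(iters_used, it)
        cols.append(f)
    R = np.column_stack(cols)
    Z = np.column_stack([_zscore(R[:, k]) for k in range(R.shape[1])])
    return GeneRanking(
        nodes=mx.nodes,
        scores=R,
        zscores=Z,
        aggregate=Z.sum(axis=1),
        alpha=alpha,
        iterations_used=iters_used,
    )


def select_seeds(r: GeneRanking, fraction: float = 0.05) -> list:
    """Top ceil(fraction * n) genes by aggregate score, descending.

    Ties are broken lexicographically (smaller id first).
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    n_seeds = math.ceil(fraction * len(r.nodes))
    order = sorted(range(len(r.nodes)), key=lambda i: (-r.aggregate[i], str(r.nodes[i])))
    return [r.nodes[i] for i in order[:n_seeds]]


# ---------------------------------------------------------------------------
# entropy objective
# ---------------------------------------------------------------------------


def _binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """-p log p - (1-p) log(1-p) with 0 log 0 = 0, natural log."""
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) - np.where(
            (1 - p) > 0, (1 - p) * np.log(1 - p), 0.0
        )
    return h


def module_entropy(
    C, nets: list[DifferentialNetwork] | Multiplex
) -> tuple[list[float], list[float], float]:
    """Internal fractions, per-layer entropies and combined objective.

    p_k is the fraction of C's total incident weight (in layer k) that is
    internal to C; internal edges are counted in both directions in both
    sums.  A layer where C has zero incident strength contributes p_k = 0,
    H_k = 0.  The combined objective is H = sum_k H_k / |C|.
    """
    C = set(C)
    if not C:
        raise ValidationError("module must be nonempty")
    mx = nets if isinstance(nets, Multiplex) else Multiplex(nets)
    idx = [mx.index[g] for g in C if g in mx.index]
    if not idx:
        raise ValidationError("no module gene appears in any network")
    p_list, h_list = [], []
    for k, A in enumerate(mx.layers):
        sub = A[idx][:, idx]
        internal = float(sub.sum())  # both directions
        total = float(mx.strengths[k][idx].sum())
        p = internal / total if total > 0 else 0.0
        p_list.append(p)
        h_list.append(float(_binary_entropy(p)))
    H = float(sum(h_list) / len(C))
    return p_list, h_list, H


# ---------------------------------------------------------------------------
# greedy expansion
# ---------------------------------------------------------------------------


def greedy_expand(
    initial,
    nets: list[DifferentialNetwork] | Multiplex,
    max_size: int = 100,
    seed=None,
    allowed=None,
) -> Module:
    """Greedy entropy-minimizing growth from an initial gene set.

    Candidates are the genes adjacent to the module in every layer whose
    addition strictly decreases H without decreasing the total internal
    fraction sum_k p_k; among them, the most cohesion-increasing one
    (largest resulting sum_k p_k) is added, up to ``max_size`` genes.
    The entropy decides when growth stops, the internal fraction which
    gene joins: because the binary entropy is symmetric around
    p_k = 1/2, ranking candidates by H alone would favor the *weakest*
    attachments whenever p_k < 1/2, so the selection is pinned to the
    cohesive branch explicitly.  H decreases strictly at every accepted
    step.  ``allowed`` optionally restricts the candidate universe (used
    to keep seed expansion local).
    """
    mx = nets if isinstance(nets, Multiplex) else Multiplex(nets)
    n, L = mx.n, mx.n_layers
    init_idx = sorted(mx.index[g] for g in initial)
    if not init_idx:
        raise ValidationError("initial gene set absent from all networks")
    allowed_mask = None
    if allowed is not None:
        allowed_mask = np.zeros(n, dtype=bool)
        allowed_mask[[mx.index[g] for g in allowed if g in mx.index]] = True

    in_C = np.zeros(n, dtype=bool)
    wc = [np.zeros(n) for _ in range(L)]  # weight from each node into C
    internal = [0.0] * L
    total = [0.0] * L

    # lexicographic tie-breaks: nodes are sorted by str, and np.argmin /
    # np.argmax return the first (= smallest-id) minimizer/maximizer.
    def add(i: int) -> None:
        for k in range(L):
            internal[k] += 2.0 * wc[k][i]
            total[k] += mx.strengths[k][i]
            cols, vals = mx.row(k, i)
            wc[k][cols] += vals
        in_C[i] = True

    for i in init_idx:
        add(i)

    def candidate_mask() -> np.ndarray:
        m = ~in_C
        if allowed_mask is not None:
            m = m & allowed_mask
        for k in range(L):
            m &= wc[k] > 0
        return m

    def current() -> tuple[float, float]:
        ps = [internal[k] / total[k] if total[k] > 0 else 0.0 for k in range(L)]
        H = sum(float(_binary_entropy(p)) for p in ps) / int(in_C.sum())
        return H, sum(ps)

    H_cur, psum_cur = current()
    while int(in_C.sum()) < max_size:
        cand = candidate_mask()
        if not cand.any():
            break
        size_new = int(in_C.sum()) + 1
        H_new = np.zeros(n)
        psum_new = np.zeros(n)
        for k in range(L):
            tot = total[k] + mx.strengths[k]
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(tot > 0, (internal[k] + 2.0 * wc[k]) / np.where(tot > 0, tot, 1.0), 0.0)
            H_new += _binary_entropy(p)
            psum_new += p
        H_new /= size_new
        admissible = cand & (H_new < H_cur) & (psum_new >= psum_cur - 1e-12)
        if not admissible.any():
            break
        psum_masked = np.where(admissible, psum_new, -np.inf)
        best = int(np.argmax(psum_masked))
        add(best)
        H_cur, psum_cur = current()

    genes = frozenset(mx.nodes[i] for i in np.nonzero(in_C)[0])
    p_k, H_k, H = module_entropy(genes, mx)
    return Module(genes=genes, p_k=tuple(p_k), H_k=tuple(H_k), H=H, seed=seed)


def expand_seed(
    seed,
    nets: list[DifferentialNetwork] | Multiplex,
    max_size: int = 100,
) -> Module:
    """Grow a module around ``seed``.

    The module is initialized as the seed plus its all-layer
    neighborhood (genes adjacent to the seed in every network), the
    seed-centered starting set customary for seed-expansion module
    search; the size-normalized entropy H is not informative on one or
    two genes (any first addition raises it from the degenerate value at
    a singleton), so growth by strict H decrease starts from this
    neighborhood.  Greedy growth (:func:`greedy_expand`) is confined to
    the seed's locality — genes adjacent to the seed in at least one
    layer — because the 1/|C| size normalization of H makes unrestricted
    growth absorb arbitrarily large cohesive regions; structures larger
    than one locality are reassembled by the Jaccard merge during
    refinement.  When the all-layer neighborhood exceeds
    ``max_size - 1`` genes only the most strongly attached neighbors are
    kept.  An isolated seed (no all-layer neighbor) yields a singleton
    module.
    """
    mx = nets if isinstance(nets, Multiplex) else Multiplex(nets)
    if seed not in mx.index:
        raise ValidationError(f"seed {seed!r} not present in any network")
    s = mx.index[seed]
    weight_to_seed = np.zeros(mx.n)
    adjacent_all = np.ones(mx.n, dtype=bool)
    adjacent_any = np.zeros(mx.n, dtype=bool)
    for k in range(mx.n_layers):
        cols, vals = mx.row(k, s)
        row = np.zeros(mx.n)
        row[cols] = vals
        weight_to_seed += row
        adjacent_all &= row > 0
        adjacent_any |= row > 0
    nbrs = np.nonzero(adjacent_all)[0]
    if nbrs.size == 0:
        L = mx.n_layers
        return Module(genes=frozenset([seed]), p_k=(0.0,) * L,
                      H_k=(0.0,) * L, H=0.0, seed=seed)
    if nbrs.size > max_size - 1:
        order = np.argsort(-weight_to_seed[nbrs], kind="stable")
        nbrs = nbrs[order[: max_size - 1]]
    initial = [seed] + [mx.nodes[i] for i in nbrs]
    pool = [mx.nodes[i] for i in np.nonzero(adjacent_any)[0]] + [seed]
    mod = greedy_expand(initial, mx, max_size=max_size, allowed=pool)
    return replace(mod, seed=seed)


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def refine(
    modules: list[Module],
    nets: list[DifferentialNetwork] | Multiplex,
    min_size: int = 5,
    jaccard_merge: float = 0.5,
) -> ModuleSet:
    """Drop undersized modules, merge heavily overlapping ones.

    Exact duplicates collapse first; modules with fewer than ``min_size``
    genes are removed; then the pair with the highest Jaccard index is
    merged (union, entropies recomputed) while some pair strictly exceeds
    ``jaccard_merge``.
    """
    mx = nets if isinstance(nets, Multiplex) else Multiplex(nets)
    seen: dict[frozenset, Module] = {}
    for mod in modules:
        seen.setdefault(mod.genes, mod)
    pool = [m for m in seen.values() if len(m) >= min_size]

    def remeasure(genes: frozenset, seed) -> Module:
        p_k, H_k, H = module_entropy(genes, mx)
        return Module(genes=genes, p_k=tuple(p_k), H_k=tuple(H_k), H=H, seed=seed)

    while True:
        best, best_j = None, jaccard_merge
        for a in range(len(pool)):
            for b in range(a + 1, len(pool)):
                j = _jaccard(pool[a].genes, pool[b].genes)
                if j > best_j:
                    best, best_j = (a, b), j
        if best is None:
            break
        a, b = best
        merged = remeasure(pool[a].genes | pool[b].genes, pool[a].seed)
        pool = [m for i, m in enumerate(pool) if i not in (a, b)] + [merged]
        # collapse any duplicate created by the merge
        uniq: dict[frozenset, Module] = {}
        for mod in pool:
            uniq.setdefault(mod.genes, mod)
        pool = list(uniq.values())

    pool.sort(key=lambda m: (m.H, sorted(str(g) for g in m.genes)))
    for i, mod in enumerate(pool, start=1):
        mod.name = f"module_{i}"
    return ModuleSet(modules=pool)


# ---------------------------------------------------------------------------
# randomization + significance
# ---------------------------------------------------------------------------


def randomize_network(
    net: DifferentialNetwork,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> DifferentialNetwork:
    """Degree-preserving randomization by weighted double-edge swaps.

    Repeatedly picks two edges (u,v), (x,y) and rewires them to (u,x),
    (v,y), each new edge inheriting the weight of the edge contributing
    its first endpoint, so both the degree sequence and the weight
    multiset are preserved exactly.  Performs ``swaps_per_edge * |E|``
    successful swaps (attempts capped at 100x that).
    """
    edges = [(u, v, d["weight"]) for u, v, d in net.graph.edges(data=True)]
    m = len(edges)
    if m < 2:
        raise ValidationError("network too sparse to randomize (|E| < 2)")
    edge_set = {frozenset((u, v)) for u, v, _ in edges}
    target = swaps_per_edge * m
    done = attempts = 0
    max_attempts = 100 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        a, b = rng.integers(0, m, size=2)
        if a == b:
            continue
        u, v, w1 = edges[a]
        x, y, w2 = edges[b]
        if rng.random() < 0.5:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        if frozenset((u, x)) in edge_set or frozenset((v, y)) in edge_set:
            continue
        edge_set.discard(frozenset((u, v)))
        edge_set.discard(frozenset((x, y)))
        edge_set.add(frozenset((u, x)))
        edge_set.add(frozenset((v, y)))
        edges[a] = (u, x, w1)
        edges[b] = (v, y, w2)
        done += 1
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return DifferentialNetwork(graph=g, layer_tag=net.layer_tag, delta=net.delta)


def _search(mx: Multiplex, params: DiscoveryParams) -> ModuleSet:
    ranking = rank_genes(
        mx, alpha=params.alpha, tol=params.tol, max_iter=params.max_iter
    )
    seeds = select_seeds(ranking, params.seed_fraction)
    mods = [expand_seed(s, mx, max_size=params.max_size) for s in seeds]
    return refine(
        mods, mx, min_size=params.min_size, jaccard_merge=params.jaccard_merge
    )


def assess_significance(
    modules: ModuleSet,
    nets: list[DifferentialNetwork],
    params: DiscoveryParams | None = None,
    n_random: int | None = None,
    rng_seed: int | None = None,
) -> ModuleSet:
    """Empirical module significance against degree-preserving nulls.

    Every layer is randomized ``n_random`` times; the full search runs on
    each randomized multiplex and all resulting module scores S = -H form
    a pooled null.  empirical_p = (1 + #{null >= S_obs}) / (1 + #null),
    BH-corrected across the observed modules.
    """
    params = params or DiscoveryParams()
    n_random = params.n_random if n_random is None else n_random
    rng_seed = params.rng_seed if rng_seed is None else rng_seed
    if n_random < 1:
        raise ValidationError("n_random must be >= 1")
    rng = np.random.default_rng(rng_seed)
    null_scores: list[float] = []
    for _ in range(n_random):
        rand_nets = [randomize_network(net, rng) for net in nets]
        null_mods = _search(Multiplex(rand_nets), params)
        null_scores.extend(m.score for m in null_mods)
    null = np.asarray(null_scores)
    out = []
    for mod in modules:
        emp = (1.0 + float((null >= mod.score).sum())) / (1.0 + null.size)
        out.append(replace(mod, empirical_p=emp))
    if out:
        adj = bh_adjust([m.empirical_p for m in out])
        out = [replace(m, adjusted_p=float(a)) for m, a in zip(out, adj)]
    return ModuleSet(
        modules=out,
        provenance={**modules.provenance, "n_random": n_random,
                    "n_null_scores": int(null.size), "rng_seed": rng_seed},
    )


def discover(
    nets: list[DifferentialNetwork],
    params: DiscoveryParams | None = None,
) -> ModuleSet:
    """Full pipeline: rank -> seeds -> expand -> refine -> significance.

    Deterministic given ``params.rng_seed``.  With ``params.n_random = 0``
    the significance stage is skipped and modules carry no p-values.
    """
    params = params or DiscoveryParams()
    mx = Multiplex(nets)
    modules = _search(mx, params)
    modules.provenance.update(
        {
            "alpha": params.alpha,
            "seed_fraction": params.seed_fraction,
            "min_size": params.min_size,
            "jaccard_merge": params.jaccard_merge,
            "max_size": params.max_size,
            "rng_seed": params.rng_seed,
            "layers": mx.layer_tags,
        }
    )
    if params.n_random > 0:
        modules = assess_significance(modules, nets, params)
    return modules
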