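"""Post-discovery statistics for epigenetic modules.

Eigengenes, expression-methylation correlation sign calls, module
activity features, prognostic indices with median risk stratification,
log-rank survival comparison, hypergeometric enrichment, Fisher's exact
test, normalized mutual information between partitions, and module
recovery metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from emdn.diffnet import bh_adjust
from emdn.netio import ClinicalTable, Module, ModuleSet, OmicsMatrix, ValidationError


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------


@dataclass
class Eigengene:
    """Unit-norm first right-singular vector of a module's gene x sample
    submatrix; the one-dimensional summary profile of the module.

    The SVD sign is arbitrary, so the vector is flipped (``sign_flipped``)
    to correlate non-negatively with the module's mean profile.
    """

    module_id: str
    values: pd.Series  # indexed by sample id, unit Euclidean norm
    sign_flipped: bool = False


def eigengene(m: OmicsMatrix, genes, module_id: str = "module") -> Eigengene:
    """First right-singular vector of the module submatrix X = U D V^T."""
    genes = [g for g in genes if g in m.data.index]
    if len(genes) < 2:
        raise ValidationError("need >= 2 module genes present in the matrix")
    X = m.data.loc[genes].to_numpy()
    if X.shape[1] < 2:
        raise ValidationError("need >= 2 samples")
    if np.ptp(X) == 0:
        raise ValidationError("constant submatrix: eigengene direction undefined")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if len(s) > 1 and s[0] > 0 and (s[0] - s[1]) / s[0] < 1e-12:
        raise ValidationError(
            "degenerate spectrum: two equal leading singular values, "
            "eigengene direction undefined"
        )
    v = Vt[0]
    mean_profile = X.mean(axis=0)
    flipped = False
    c = float(np.dot(v, mean_profile - mean_profile.mean()))
    if c < 0:
        v = -v
        flipped = True
    return Eigengene(
        module_id=module_id,
        values=pd.Series(v, index=m.data.columns),
        sign_flipped=flipped,
    )


# ---------------------------------------------------------------------------
# correlation sign calls
# ---------------------------------------------------------------------------


@dataclass
class CorrelationCall:
    """Expression-vs-methylation eigengene correlation for one module."""

    module_id: str
    pearson_r: float
    raw_p: float
    adjusted_p: float
    call: str  # positive / negative / none

    def __post_init__(self) -> None:
        if self.call not in ("positive", "negative", "none"):
            raise ValidationError(f"bad call {self.call!r}")


def _pair_correlation(expr_eig: Eigengene, meth_eig: Eigengene) -> tuple[float, float]:
    if list(expr_eig.values.index) != list(meth_eig.values.index):
        raise ValidationError("eigengenes have mismatched sample order")
    if len(expr_eig.values) < 3:
        raise ValidationError("need >= 3 samples for a correlation call")
    r, p = stats.pearsonr(expr_eig.values.to_numpy(), meth_eig.values.to_numpy())
    return float(r), float(max(p, 1e-300))


def correlation_calls(
    pairs: list[tuple[Eigengene, Eigengene]], cutoff: float = 0.05
) -> list[CorrelationCall]:
    """Per-module Pearson correlation between expression and methylation
    eigengenes, with BH correction across modules and a sign call.

    A module is called positive (negative) when its adjusted p-value is
    below ``cutoff`` and r > 0 (r < 0); otherwise the call is none.
    """
    if not pairs:
        return []
    rs, ps = zip(*(_pair_correlation(e, m) for e, m in pairs))
    adj = bh_adjust(ps)
    calls = []
    for (e, _), r, p, a in zip(pairs, rs, ps, adj):
        if a < cutoff and r != 0:
            call = "positive" if r > 0 else "negative"
        else:
            call = "none"
        calls.append(
            CorrelationCall(
                module_id=e.module_id,
                pearson_r=r,
                raw_p=p,
                adjusted_p=float(a),
                call=call,
            )
        )
    return calls


def module_correlation(
    expr_eig: Eigengene,
    meth_eig: Eigengene,
    all_modules_p: list[float],
    cutoff: float = 0.05,
) -> CorrelationCall:
    """Correlation call for one module given the other modules' raw
    p-values (the BH correction runs across all of them together)."""
    r, p = _pair_correlation(expr_eig, meth_eig)
    ps = [p, *all_modules_p]
    a = float(bh_adjust(ps)[0])
    call = ("positive" if r > 0 else "negative") if (a < cutoff and r != 0) else "none"
    return CorrelationCall(expr_eig.module_id, r, p, a, call)


# ---------------------------------------------------------------------------
# activity features
# ---------------------------------------------------------------------------


def activity_scores(
    meth: OmicsMatrix,
    modules: ModuleSet | list[Module],
    normalization: str = "sqrt",
) -> pd.DataFrame:
    """Module activity feature matrix (modules x samples).

    ``sqrt`` mode divides the per-sample sum of member-gene values by
    sqrt(|C|); ``mean`` divides by |C|.  Genes absent from the matrix are
    excluded with a warning and |C| adjusted accordingly.
    """
    if normalization not in ("sqrt", "mean"):
        raise ValidationError("normalization must be 'sqrt' or 'mean'")
    rows = {}
    for i, mod in enumerate(modules, start=1):
        name = mod.name or f"module_{i}"
        genes = [g for g in sorted(mod.genes, key=str) if g in meth.data.index]
        if len(genes) < len(mod.genes):
            warnings.warn(
                f"{name}: {len(mod.genes) - len(genes)} genes absent from matrix",
                stacklevel=2,
            )
        if not genes:
            raise ValidationError(f"{name}: no module gene present in the matrix")
        total = meth.data.loc[genes].sum(axis=0)
        denom = math.sqrt(len(genes)) if normalization == "sqrt" else len(genes)
        rows[name] = total / denom
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# prognostic index and survival
# ---------------------------------------------------------------------------


def prognostic_index(beta: np.ndarray, module_means: pd.DataFrame) -> pd.Series:
    """index_i = sum_c beta_c X_ci.

    ``module_means`` is modules x patients (average methylation of module
    genes per patient); ``beta`` holds one Cox regression coefficient per
    module, supplied externally.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (module_means.shape[0],):
        raise ValidationError(
            f"beta length {beta.shape} does not match {module_means.shape[0]} modules"
        )
    return pd.Series(beta @ module_means.to_numpy(), index=module_means.columns)


def split_risk_groups(index: pd.Series) -> pd.Series:
    """Median split: index > median -> 'high', else 'low'.

    With a degenerate (constant) index everything lands in the low group;
    the stable input order is preserved.
    """
    med = float(index.median())
    return pd.Series(
        np.where(index.to_numpy() > med, "high", "low"), index=index.index
    )


def km_curves(groups: pd.Series, clinical: ClinicalTable) -> pd.DataFrame:
    """Kaplan-Meier survival estimates per risk group.

    Returns a tidy DataFrame with columns group, time, survival.
    """
    from lifelines import KaplanMeierFitter

    common = [s for s in groups.index if s in clinical.table.index]
    g = groups.loc[common]
    t = clinical.table.loc[common]
    frames = []
    for name in sorted(g.unique()):
        sel = (g == name).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(t.loc[sel, "time"], event_observed=t.loc[sel, "event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "group", name)
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)


def logrank_test(groups: pd.Series, clinical: ClinicalTable) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic and p-value."""
    common = [s for s in groups.index if s in clinical.table.index]
    g = groups.loc[common]
    t = clinical.table.loc[common]
    names = sorted(g.unique())
    if len(names) != 2:
        raise ValidationError(f"need exactly 2 nonempty groups, got {names}")
    if int(t["event"].sum()) == 0:
        raise ValidationError("all observations censored: log-rank undefined")
    a, b = (g == names[0]), (g == names[1])
    res = _ll_logrank(
        t.loc[a.values, "time"], t.loc[b.values, "time"],
        event_observed_A=t.loc[a.values, "event"],
        event_observed_B=t.loc[b.values, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def hypergeometric_enrichment(
    module, gene_sets: dict[str, set], universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a module in gene sets.

    Returns a DataFrame indexed by set name with columns overlap,
    set_size, p, adjusted_p (BH across the supplied sets).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    module = set(module)
    if not module <= universe:
        raise ValidationError("module must be a subset of the universe")
    M, N = len(universe), len(module)
    names, ps, overlaps, sizes = [], [], [], []
    for name, genes in gene_sets.items():
        K = len(set(genes) & universe)
        k = len(module & set(genes))
        # P(X >= k) under sampling N genes from a universe with K marked
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        names.append(name)
        ps.append(min(max(p, 1e-300), 1.0))
        overlaps.append(k)
        sizes.append(K)
    adj = bh_adjust(ps)
    return pd.DataFrame(
        {"overlap": overlaps, "set_size": sizes, "p": ps, "adjusted_p": adj},
        index=pd.Index(names, name="gene_set"),
    )


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> float:
    """Exact hypergeometric tail p-value for a 2x2 contingency table."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValidationError("counts must be nonnegative")
    if table.sum() == 0:
        raise ValidationError("all-zero table")
    return float(stats.fisher_exact(table, alternative=alternative)[1])


# ---------------------------------------------------------------------------
# partition comparison and recovery metrics
# ---------------------------------------------------------------------------


def _as_blocks(P) -> list[set]:
    if isinstance(P, dict):
        blocks: dict = {}
        for el, lab in P.items():
            blocks.setdefault(lab, set()).add(el)
        return list(blocks.values())
    return [set(b) for b in P]


def nmi(P, P_star) -> float:
    """Normalized mutual information between two partitions.

    Computed from the confusion matrix N (N_ij = overlap of block i of P
    with block j of P*) as

        NMI = -2 sum_ij N_ij log(N_ij N / (N_i. N_.j))
              / [sum_i N_i. log(N_i./N) + sum_j N_.j log(N_.j/N)]

    with 0 log 0 = 0.  Equals 1 iff the partitions are identical up to
    relabeling; if either partition is a single block the value is
    defined as 0 unless both are the identical single block (then 1).
    Partitions may be given as label dicts or iterables of blocks over
    the same element universe.
    """
    A, B = _as_blocks(P), _as_blocks(P_star)
    ua = set().union(*A) if A else set()
    ub = set().union(*B) if B else set()
    if ua != ub:
        raise ValidationError("partitions cover different element universes")
    if sum(len(b) for b in A) != len(ua) or sum(len(b) for b in B) != len(ub):
        raise ValidationError("blocks overlap: not a partition")
    if len(A) == 1 or len(B) == 1:
        return 1.0 if (len(A) == 1 and len(B) == 1) else 0.0
    n = len(ua)
    conf = np.array([[len(a & b) for b in B] for a in A], dtype=float)
    ni = conf.sum(axis=1)
    nj = conf.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = conf * np.log(np.where(conf > 0, conf * n / np.outer(ni, nj), 1.0))
    numerator = -2.0 * num.sum()
    denom = float(
        np.sum(ni[ni > 0] * np.log(ni[ni > 0] / n))
        + np.sum(nj[nj > 0] * np.log(nj[nj > 0] / n))
    )
    if denom == 0.0:
        return 1.0
    return float(numerator / denom)


def partition_from_modules(modules: ModuleSet | list[Module], universe) -> list[set]:
    """Turn (possibly overlapping, non-covering) modules into a partition.

    Each node goes to the tightest module containing it (smallest H, ties
    by module order); nodes covered by no module form a single leftover
    block: the search asserts no structure among them, so they are not
    split into singletons.
    """
    universe = set(universe)
    mods = list(modules)
    order = sorted(
        range(len(mods)),
        key=lambda i: (mods[i].H if not math.isnan(mods[i].H) else math.inf, i),
    )
    assigned: dict = {}
    for rank, i in enumerate(order):
        for g in mods[i].genes:
            if g in universe and g not in assigned:
                assigned[g] = i
    blocks: dict[int, set] = {}
    for g, i in assigned.items():
        blocks.setdefault(i, set()).add(g)
    leftovers = universe - set(assigned)
    out = [b for _, b in sorted(blocks.items())]
    if leftovers:
        out.append(leftovers)
    return out


def module_recovery_metrics(
    found, truth, n_genes: int
) -> tuple[float, float, float, float]:
    """(ACC, FPR, PPV, FDR) of a recovered module against the truth.

    ACC = |found & truth| / |truth| (recall), PPV = |found & truth| /
    |found| (0 for an empty found set), FPR = |found - truth| /
    (n_genes - |truth|), FDR = 1 - PPV.
    """
    found, truth = set(found), set(truth)
    if not truth:
        raise ValidationError("truth set must be nonempty")
    if n_genes <= len(truth):
        raise ValidationError("n_genes must exceed |truth|")
    tp = len(found & truth)
    acc = tp / len(truth)
    ppv = tp / len(found) if found else 0.0
    fpr = len(found - truth) / (n_genes - len(truth))
    return acc, fpr, ppv, 1.0 - ppv
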