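"""Differential network construction for one omics layer.

A differential coexpression (or comethylation) network couples two pieces
of evidence:

1. *Topology* — gene pairs whose absolute Pearson correlation across all
   samples reaches a threshold delta, optionally pruned by first-order
   partial correlation so that indirect correlations explained by a third
   gene are removed.
2. *Edge weights* — how differentially expressed (methylated) both
   endpoints are between tumor and normal samples.  With per-gene p-values
   P_i, a retained edge (i, j) gets

       w_ij = sqrt(|log P_i + log P_j|) / sqrt(2 * max_l |log P_l|),

   which lies in [0, 1] and equals 1 exactly when both endpoints attain
   the layer-wide minimum p-value.  The weight is invariant to the log
   base because the base factor cancels between numerator and denominator.

Differential tests are pluggable; the default is Welch's two-sample t-test
on per-gene values, with Benjamini-Hochberg adjusted p-values reported
alongside.  Raw p-values enter the edge weights.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from emdn.netio import (
    DifferentialNetwork,
    OmicsMatrix,
    SampleLabels,
    ValidationError,
)

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # floor before taking logs


@dataclass(frozen=True)
class PValueVector:
    """Per-gene raw and BH-adjusted differential p-values."""

    raw: pd.Series
    adjusted: pd.Series

    def __post_init__(self) -> None:
        if not self.raw.index.equals(self.adjusted.index):
            raise ValidationError("raw/adjusted p-value indices differ")
        if ((self.raw <= 0) | (self.raw > 1)).any():
            raise ValidationError("raw p-values must lie in (0, 1]")
        if (self.adjusted + 1e-12 < self.raw).any():
            raise ValidationError("adjusted p-values must be >= raw p-values")

    def __getitem__(self, gene) -> float:
        return float(self.raw[gene])


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_pvalues(tumor: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample t-test p-values (tumor vs normal).

    Genes with zero variance in both groups carry no evidence and get
    p = 1, per the container contract.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    both_flat = (np.ptp(tumor, axis=1) == 0) & (np.ptp(normal, axis=1) == 0)
    if both_flat.any():
        logger.info("%d genes with zero variance in both groups: p set to 1",
                    int(both_flat.sum()))
        p[both_flat] = 1.0
    p = np.where(np.isnan(p), 1.0, p)
    return np.clip(p, P_FLOOR, 1.0)


def differential_pvalues(
    m: OmicsMatrix,
    labels: SampleLabels,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_pvalues,
) -> PValueVector:
    """Per-gene two-sample differential p-values with BH adjustment.

    ``test`` maps (tumor matrix, normal matrix) row-wise to raw p-values;
    the default is Welch's t.  A moderated-t plugin can be passed instead.
    """
    labels.require_two_conditions()
    if m.data.isna().to_numpy().any():
        raise ValidationError("matrix has missing cells; impute first")
    tumor_cols = [s for s in m.col_ids if labels.labels.get(s) == "tumor"]
    normal_cols = [s for s in m.col_ids if labels.labels.get(s) == "normal"]
    if len(tumor_cols) < 2 or len(normal_cols) < 2:
        raise ValidationError("need >= 2 samples per condition in the matrix")
    raw = test(
        m.data[tumor_cols].to_numpy(), m.data[normal_cols].to_numpy()
    )
    raw = np.clip(raw, P_FLOOR, 1.0)
    adjusted = bh_adjust(raw)
    idx = m.data.index
    return PValueVector(
        raw=pd.Series(raw, index=idx), adjusted=pd.Series(adjusted, index=idx)
    )


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


def _partial_corr_prune(
    R: np.ndarray,
    edges: list[tuple[int, int]],
    delta: float,
    top_q: int,
    exhaustive_limit: int,
) -> list[tuple[int, int]]:
    """Keep edges whose minimum first-order |partial correlation| over the
    conditioning set still reaches delta.

    pcor(i,j|z) = (r_ij - r_iz r_jz) / sqrt((1 - r_iz^2)(1 - r_jz^2)).
    Conditioning genes with |r_iz| = 1 or |r_jz| = 1 are skipped (zero
    denominator).  For small problems every third gene is a conditioning
    candidate; above ``exhaustive_limit`` genes the set is restricted to
    the union of the top-q most correlated partners of i and of j.
    """
    n = R.shape[0]
    exhaustive = n <= exhaustive_limit
    absR = np.abs(R)
    if not exhaustive:
        # precompute top-q partners per gene (excluding self)
        order = np.argsort(-absR, axis=1)
        top = order[:, 1 : top_q + 1]
    kept: list[tuple[int, int]] = []
    for i, j in edges:
        if exhaustive:
            zs = np.arange(n)
        else:
            zs = np.union1d(top[i], top[j])
        zs = zs[(zs != i) & (zs != j)]
        if zs.size == 0:
            kept.append((i, j))
            continue
        riz, rjz = R[i, zs], R[j, zs]
        denom_sq = (1.0 - riz**2) * (1.0 - rjz**2)
        ok = denom_sq > 1e-12  # |r| == 1 conditioning genes skipped
        if not ok.any():
            kept.append((i, j))
            continue
        pc = (R[i, j] - riz[ok] * rjz[ok]) / np.sqrt(denom_sq[ok])
        if np.min(np.abs(pc)) >= delta:
            kept.append((i, j))
    return kept


def coexpression_topology(
    m: OmicsMatrix,
    delta: float = 0.4,
    partial: bool = True,
    top_q: int = 50,
    exhaustive_limit: int = 2000,
) -> tuple[list, dict]:
    """Correlation-thresholded topology for one layer.

    Returns ``(genes, edges)`` where ``genes`` is the list of non-constant
    genes and ``edges`` maps (gene_i, gene_j) (i < j in matrix order) to
    the Pearson correlation.  An edge is retained iff |cor| >= delta and,
    when ``partial`` is on, the minimum first-order |partial correlation|
    over the conditioning set also reaches delta.
    """
    if not (0 < delta < 1):
        raise ValidationError("delta must lie in (0, 1)")
    if m.data.shape[1] < 3:
        raise ValidationError("need >= 3 samples for correlation topology")
    if m.data.isna().to_numpy().any():
        raise ValidationError("matrix has missing cells; impute first")

    X = m.data.to_numpy()
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-variance genes excluded from topology",
            stacklevel=2,
        )
    genes = [g for g, k in zip(m.row_ids, keep) if k]
    X = X[keep]
    if len(genes) < 2:
        return genes, {}
    R = np.corrcoef(X)
    np.fill_diagonal(R, 0.0)
    ii, jj = np.nonzero(np.triu(np.abs(R) >= delta, k=1))
    edges = list(zip(ii.tolist(), jj.tolist()))
    if partial and edges:
        edges = _partial_corr_prune(R, edges, delta, top_q, exhaustive_limit)
    return genes, {(genes[i], genes[j]): float(R[i, j]) for i, j in edges}


# ---------------------------------------------------------------------------
# Eq-1 style weighting
# ---------------------------------------------------------------------------


def eq1_weights(
    genes: list,
    edges: dict,
    p: PValueVector,
    layer_tag: str,
    delta: float | None = None,
    use_adjusted: bool = False,
) -> DifferentialNetwork:
    """Assign differential-significance weights to a retained topology.

    ``genes`` is the topology node universe (the max over |log P_l| ranges
    over these genes); ``edges`` maps gene pairs to correlations.  Weights
    of exactly 0 (both endpoint p-values equal to 1) are dropped, since
    the differential network stores only positive-weight edges.
    """
    if not genes:
        raise ValidationError("empty topology: no gene carries any signal")
    series = p.adjusted if use_adjusted else p.raw
    missing = [g for g in genes if g not in series.index]
    if missing:
        raise ValidationError(f"no p-value for topology genes {missing[:5]}...")
    logp = np.log(np.clip(series.loc[genes].to_numpy(), P_FLOOR, 1.0))
    max_abs = np.max(np.abs(logp))
    if max_abs == 0.0:
        raise ValidationError(
            "degenerate layer: every p-value equals 1, no differential signal"
        )
    lp = dict(zip(genes, logp))
    g = nx.Graph()
    g.add_nodes_from(genes)
    denom = math.sqrt(2.0 * max_abs)
    for (u, v), cor in edges.items():
        w = math.sqrt(abs(lp[u] + lp[v])) / denom
        if w > 0:
            g.add_edge(u, v, weight=min(w, 1.0), cor=cor)
    return DifferentialNetwork(graph=g, layer_tag=layer_tag, delta=delta)


def build_differential_network(
    m: OmicsMatrix,
    labels: SampleLabels,
    delta: float = 0.4,
    partial: bool = True,
    use_adjusted: bool = False,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_pvalues,
    top_q: int = 50,
    exhaustive_limit: int = 2000,
) -> tuple[DifferentialNetwork, PValueVector]:
    """Full single-layer construction: topology + differential weighting."""
    pvals = differential_pvalues(m, labels, test=test)
    genes, edges = coexpression_topology(
        m, delta=delta, partial=partial, top_q=top_q,
        exhaustive_limit=exhaustive_limit,
    )
    net = eq1_weights(
        genes, edges, pvals, layer_tag=m.layer_tag, delta=delta,
        use_adjusted=use_adjusted,
    )
    return net, pvals
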