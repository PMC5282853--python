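"""Probe filtering, imputation, and probe-to-gene methylation collapsing.

Rows (probes or genes) with more than ``max_missing_frac`` missing values
are removed; the remaining missing cells are filled by k-nearest-row
imputation.  Probe-level beta values are then summarized per gene with the
promoter-region priority rule used for Illumina 450k annotations:
TSS200 probes if any, else first-exon probes, else TSS1500 probes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from emdn.netio import OmicsMatrix, ProbeAnnotation, ValidationError, REGIONS


def filter_and_impute(
    m: OmicsMatrix,
    max_missing_frac: float = 0.3,
    k_neighbors: int = 10,
    seed: int | None = None,
) -> OmicsMatrix:
    """Drop rows with too many missing values, impute the rest.

    Parameters
    ----------
    m : OmicsMatrix
        Input matrix; missing values are NaN.
    max_missing_frac : float
        Rows whose missing fraction strictly exceeds this are removed
        (default 0.3, i.e. "more than 30% missing").
    k_neighbors : int
        Number of nearest rows (Euclidean distance on shared observed
        columns) whose mean fills each missing cell.
    seed : int, optional
        Accepted for interface uniformity; the imputation is deterministic.

    Returns
    -------
    OmicsMatrix with zero missing cells.
    """
    if not (0 <= max_missing_frac < 1):
        raise ValidationError("max_missing_frac must be in [0, 1)")
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be >= 1")

    frac = m.data.isna().mean(axis=1)
    kept = m.data.loc[frac <= max_missing_frac]
    if kept.shape[0] < 2:
        raise ValidationError(
            f"only {kept.shape[0]} rows survive the missing-value filter; "
            "k-nearest-row imputation needs at least 2"
        )
    if not kept.isna().to_numpy().any():
        return m.with_data(kept.copy())

    k = min(k_neighbors, kept.shape[0] - 1)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(kept.to_numpy())
    out = pd.DataFrame(filled, index=kept.index, columns=kept.columns)
    if m.layer_tag == "methylation":
        out = out.clip(0.0, 1.0)
    return m.with_data(out)


def collapse_methylation_to_genes(
    m: OmicsMatrix, ann: ProbeAnnotation
) -> OmicsMatrix:
    """Collapse a probe-level methylation matrix to gene level.

    Per gene and sample: mean of TSS200 probes when at least one exists,
    else mean of first-exon probes, else mean of TSS1500 probes.  Genes
    with no probe in any class are absent from the output.  Annotation
    records pointing at probes absent from the matrix are skipped with a
    warning.  The input must already be imputed (no missing cells).
    """
    if m.layer_tag != "methylation":
        raise ValidationError("collapse applies to the methylation layer only")
    if m.data.isna().to_numpy().any():
        raise ValidationError("matrix has missing cells; run filter_and_impute first")

    present = set(m.data.index)
    missing_probes = {p for p, _, _ in ann.records if p not in present}
    if missing_probes:
        warnings.warn(
            f"{len(missing_probes)} annotated probes absent from matrix; "
            "those mappings are skipped",
            stacklevel=2,
        )

    rows: dict[str, np.ndarray] = {}
    for gene, regions in sorted(ann.by_gene().items()):
        for region in REGIONS:  # priority order TSS200 > FirstExon > TSS1500
            probes = [p for p in regions[region] if p in present]
            if probes:
                rows[gene] = m.data.loc[probes].mean(axis=0).to_numpy()
                break
    if not rows:
        raise ValidationError("no annotated probe present in the matrix")
    data = pd.DataFrame.from_dict(rows, orient="index", columns=m.data.columns)
    return OmicsMatrix(data=data, layer_tag="methylation")
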