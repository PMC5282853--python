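"""Typed containers and TSV/GMT readers/writers for every pipeline artifact.

All readers validate strictly and raise rather than silently coercing
out-of-domain values.  Write/read round-trips are identity on content.

File dialects
-------------
* Omics matrices: TSV, one header row of sample ids, first column gene or
  probe ids.  Empty cells and ``NA`` (case-insensitive) mark missing values.
* Sample labels: two-column TSV ``sample_id<TAB>condition`` with conditions
  ``tumor``/``normal``.
* Probe annotation: three-column TSV ``probe_id<TAB>gene_id<TAB>region``
  with region one of ``TSS200``, ``FirstExon``, ``TSS1500``.
* Clinical table: TSV ``sample_id<TAB>time<TAB>event``.
* Networks: three-column edge-list TSV, one line per undirected edge with
  endpoints in lexicographic order.
* Modules: GMT (name, description, genes...), scores carried in the
  description field as ``key=value`` pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

EXPRESSION = "expression"
METHYLATION = "methylation"
LAYER_TAGS = (EXPRESSION, METHYLATION)

REGIONS = ("TSS200", "FirstExon", "TSS1500")

_MISSING_SENTINELS = {"", "na"}


class ValidationError(ValueError):
    """Input violates a domain invariant (duplicate ids, out-of-range values...)."""


class ParseError(ValueError):
    """Input file is syntactically malformed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """Genes/probes x samples real matrix with an explicit missing mask.

    ``data`` is a float DataFrame whose NaN entries are the missing values;
    ``layer_tag`` is ``"expression"`` or ``"methylation"``.  Methylation
    values are beta values and must lie in [0, 1] where present.
    """

    data: pd.DataFrame
    layer_tag: str

    def __post_init__(self) -> None:
        if self.layer_tag not in LAYER_TAGS:
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate row ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)
        if self.layer_tag == METHYLATION:
            vals = self.data.to_numpy()
            bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                i, j = np.argwhere(bad & ~np.isnan(vals))[0]
                raise ValidationError(
                    "methylation beta value outside [0,1] at "
                    f"row {self.data.index[i]!r}, sample {self.data.columns[j]!r}: "
                    f"{vals[i, j]}"
                )

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the value is missing."""
        return self.data.isna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def with_data(self, data: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(data=data, layer_tag=self.layer_tag)


@dataclass(frozen=True)
class SampleLabels:
    """sample_id -> condition in {tumor, normal}."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.labels.values() if c not in ("tumor", "normal")}
        if bad:
            raise ValidationError(f"unknown conditions: {sorted(bad)}")

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.labels.items() if c == condition]

    def require_two_conditions(self, min_per_group: int = 2) -> None:
        for cond in ("tumor", "normal"):
            n = len(self.samples(cond))
            if n < min_per_group:
                raise ValidationError(
                    f"condition {cond!r} has {n} samples, need >= {min_per_group}"
                )


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe-to-gene mapping with region class.

    ``records`` holds (probe_id, gene_id, region) triples; a probe may map
    to several genes, one record per mapping.
    """

    records: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        for probe, gene, region in self.records:
            if region not in REGIONS:
                raise ValidationError(
                    f"region {region!r} for probe {probe!r} is not one of {REGIONS}"
                )

    def by_gene(self) -> dict[str, dict[str, list[str]]]:
        """gene -> region -> list of probe ids."""
        out: dict[str, dict[str, list[str]]] = {}
        for probe, gene, region in self.records:
            out.setdefault(gene, {r: [] for r in REGIONS})[region].append(probe)
        return out


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival time (>= 0) and binary event indicator."""

    table: pd.DataFrame  # index sample_id, columns time, event

    def __post_init__(self) -> None:
        t = self.table
        if not {"time", "event"} <= set(t.columns):
            raise ValidationError("clinical table needs 'time' and 'event' columns")
        if (t["time"] < 0).any():
            raise ValidationError("negative survival time")
        if not t["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0/1")


@dataclass
class DifferentialNetwork:
    """Undirected weighted graph over genes for one omics layer.

    Edge weights are the differential-significance weights in [0, 1]; edges
    with weight 0 are not stored.  ``delta`` records the correlation
    threshold used to build the topology (None when unknown, e.g. for
    simulated or re-read networks).
    """

    graph: nx.Graph
    layer_tag: str
    delta: float | None = None

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop at {u!r}")
            w = d.get("weight")
            if w is None or not (0 < w <= 1):
                raise ValidationError(f"edge ({u!r},{v!r}) weight {w!r} not in (0,1]")

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# matrix / table readers and writers
# ---------------------------------------------------------------------------


def _parse_cell(raw: str, row: str, col: str) -> float:
    if raw.strip().lower() in _MISSING_SENTINELS:
        return math.nan
    try:
        return float(raw)
    except ValueError:
        raise ParseError(
            f"nonnumeric cell {raw!r} at row {row!r}, sample {col!r}"
        ) from None


def read_omics_matrix(path: str | Path, layer_tag: str) -> OmicsMatrix:
    """Read a genes/probes x samples TSV into a validated :class:`OmicsMatrix`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")[1:]
        rows: list[str] = []
        values: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols) + 1} fields, got {len(fields)}"
                )
            rid = fields[0]
            rows.append(rid)
            values.append([_parse_cell(v, rid, c) for v, c in zip(fields[1:], cols)])
    data = pd.DataFrame(values, index=rows, columns=cols, dtype=float)
    return OmicsMatrix(data=data, layer_tag=layer_tag)


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_sample_labels(path: str | Path) -> SampleLabels:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
    sample_col, cond_col = df.columns
    if df[sample_col].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    return SampleLabels(labels=dict(zip(df[sample_col], df[cond_col])))


def write_sample_labels(labels: SampleLabels, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.labels), "condition": list(labels.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 3:
        raise ParseError(f"{path}: expected 3 columns, got {df.shape[1]}")
    records = tuple(df.itertuples(index=False, name=None))
    return ProbeAnnotation(records=records)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    pd.DataFrame(ann.records, columns=["probe_id", "gene_id", "region"]).to_csv(
        path, sep="\t", index=False
    )


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    return ClinicalTable(table=df[["time", "event"]])


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    df = clin.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def write_network(net: DifferentialNetwork, path: str | Path) -> None:
    """Write a 3-column edge list, one line per undirected edge, endpoints
    in lexicographic order, weights with >= 6 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        delta = "" if net.delta is None else repr(net.delta)
        fh.write(f"# layer_tag={net.layer_tag}\tdelta={delta}\n")
        fh.write("gene_i\tgene_j\tweight\n")
        edges = sorted(
            (min(str(u), str(v)), max(str(u), str(v)), d["weight"])
            for u, v, d in net.graph.edges(data=True)
        )
        for u, v, w in edges:
            fh.write(f"{u}\t{v}\t{w:.8g}\n")


def read_network(path: str | Path, layer_tag: str | None = None) -> DifferentialNetwork:
    path = Path(path)
    delta: float | None = None
    g = nx.Graph()
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(
                kv.split("=", 1) for kv in first[1:].strip().split("\t") if "=" in kv
            )
            if layer_tag is None:
                layer_tag = meta.get("layer_tag")
            if meta.get("delta"):
                delta = float(meta["delta"])
            header = fh.readline()
        else:
            header = first
        if header.rstrip("\n").split("\t") != ["gene_i", "gene_j", "weight"]:
            raise ParseError(f"{path}: bad edge-list header")
        for lineno, line in enumerate(fh, start=3):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            u, v, w = fields
            g.add_edge(u, v, weight=float(w))
    if layer_tag is None:
        raise ValidationError(f"{path}: layer_tag neither given nor recorded in file")
    return DifferentialNetwork(graph=g, layer_tag=layer_tag, delta=delta)


# ---------------------------------------------------------------------------
# modules / GMT
# ---------------------------------------------------------------------------


@dataclass
class Module:
    """A candidate common module: gene set plus entropy bookkeeping.

    ``p_k``/``H_k`` are the per-network internal-weight fractions and
    entropies, ``H`` the combined size-normalized entropy.  The module
    score used for significance testing is ``-H`` (larger = tighter).
    """

    genes: frozenset
    p_k: tuple[float, ...] = ()
    H_k: tuple[float, ...] = ()
    H: float = math.nan
    seed: str | None = None
    empirical_p: float | None = None
    adjusted_p: float | None = None
    name: str | None = None

    @property
    def score(self) -> float:
        return -self.H

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleSet:
    modules: list[Module]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def significant(self, cutoff: float = 0.05) -> "ModuleSet":
        keep = [
            m
            for m in self.modules
            if m.adjusted_p is not None and m.adjusted_p < cutoff
        ]
        return ModuleSet(modules=keep, provenance=dict(self.provenance))


_SCORE_FIELDS = ("H", "empirical_p", "adjusted_p")


def write_modules_gmt(modules: ModuleSet, path: str | Path) -> None:
    """One GMT line per module: name TAB description TAB gene...

    Scores are serialized into the description field as ``key=value``
    pairs so that a single standard format carries everything.
    """
    if not len(modules):
        raise ValidationError("refusing to write an empty module set")
    path = Path(path)
    with path.open("w") as fh:
        for i, mod in enumerate(modules, start=1):
            genes = sorted(str(g) for g in mod.genes)
            if any("\t" in g for g in genes):
                raise ValidationError("gene ids must not contain tab characters")
            name = mod.name or f"module_{i}"
            desc = ";".join(
                f"{k}={getattr(mod, k)}"
                for k in _SCORE_FIELDS
                if getattr(mod, k) is not None and not _isnan(getattr(mod, k))
            )
            fh.write("\t".join([name, desc or "-", *genes]) + "\n")


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


def read_modules_gmt(path: str | Path) -> ModuleSet:
    path = Path(path)
    mods: list[Module] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            scores: dict[str, float] = {}
            if desc and desc != "-":
                for kv in desc.split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        if k in _SCORE_FIELDS:
                            try:
                                scores[k] = float(v)
                            except ValueError:
                                pass
            mods.append(
                Module(
                    genes=frozenset(genes),
                    name=name,
                    H=scores.get("H", math.nan),
                    empirical_p=scores.get("empirical_p"),
                    adjusted_p=scores.get("adjusted_p"),
                )
            )
    return ModuleSet(modules=mods)


def read_gene_sets_gmt(path: str | Path) -> dict[str, set]:
    """Read plain GMT gene-set collections (e.g. pathway annotations)."""
    out: dict[str, set] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            out[fields[0]] = set(fields[2:])
    return out
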