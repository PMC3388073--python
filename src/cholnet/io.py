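"""Domain types and file I/O for the cholesterol-sensing expression pipeline.

All external formats are plain text: TSV expression matrices (header row of
sample ids, first column gene ids), two-column TSV design tables, SIF/TSV
interaction edge lists, GMT gene-set files, two-column TSV ortholog maps and
YAML run configuration.  Gene identifiers are case-sensitive symbols and
matching across files is exact string match; symbol-mapping quirks belong in
the ortholog-map input, not in the readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cholnet")

#: SIF interaction-kind tokens -> canonical edge kinds.
SIF_KINDS = {"pp": "ppi", "pd": "protein_dna"}
_KIND_TO_SIF = {v: k for k, v in SIF_KINDS.items()}

#: Columns of a serialized differential-expression table, in output order.
DEG_TABLE_COLUMNS = [
    "gene", "log2fc", "stat_t", "stat_m", "p_t", "p_m",
    "fdr_t", "fdr_m", "fdr_overall", "direction", "is_deg",
]


class CholnetError(Exception):
    """Base error for malformed inputs or invalid pipeline states."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Thresholds and numeric policy for a pipeline run.

    Parameters
    ----------
    alpha:
        Overall-FDR significance bound for DEG selection (strict ``<``).
    fc_threshold:
        Absolute log2 fold-change bound for DEG selection (strict ``>``);
        0.585 corresponds to a 1.5-fold change.
    permutation_cap:
        Maximum number of group relabelings; below the cap all distinct
        relabelings are enumerated, above it they are sampled with
        ``rng_seed``.
    rng_seed:
        Seed for every stochastic step of a run.
    storey_lambda:
        Grid of tuning values for the Storey null-proportion estimate.
    missing_policy:
        ``"error"`` rejects non-numeric/missing expression cells;
        ``"drop_gene"`` removes the offending gene rows at load time.
    null_mode:
        ``"pooled"`` builds the permutation null by pooling permuted
        statistics across genes (required for power at tiny replicate
        counts); ``"per_gene"`` uses each gene's own relabelings only.
    """

    alpha: float = 0.05
    fc_threshold: float = 0.585
    permutation_cap: int = 10_000
    rng_seed: int = 0
    storey_lambda: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.95, 0.05), 2))
    missing_policy: str = "error"
    null_mode: str = "pooled"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise CholnetError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_threshold < 0:
            raise CholnetError(f"fc_threshold must be >= 0, got {self.fc_threshold}")
        if self.permutation_cap < 1:
            raise CholnetError(f"permutation_cap must be >= 1, got {self.permutation_cap}")
        if self.missing_policy not in ("error", "drop_gene"):
            raise CholnetError(f"unknown missing_policy {self.missing_policy!r}")
        if self.null_mode not in ("pooled", "per_gene"):
            raise CholnetError(f"unknown null_mode {self.null_mode!r}")
        if any(not 0.0 <= lam < 1.0 for lam in self.storey_lambda):
            raise CholnetError("storey_lambda values must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "storey_lambda" in raw:
            raw["storey_lambda"] = tuple(raw["storey_lambda"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "alpha": self.alpha,
            "fc_threshold": self.fc_threshold,
            "permutation_cap": self.permutation_cap,
            "rng_seed": self.rng_seed,
            "storey_lambda": [float(x) for x in self.storey_lambda],
            "missing_policy": self.missing_policy,
            "null_mode": self.null_mode,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2-scale genes x samples expression values with a sample design.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample ids
    as columns; ``design`` maps every sample id to a non-empty group or
    timepoint label.
    """

    values: pd.DataFrame
    design: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise CholnetError(f"duplicate gene id {dup!r} in expression matrix")
        cols = self.values.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise CholnetError(f"duplicate sample id {dup!r} in expression matrix")
        missing = [s for s in cols if s not in self.design]
        if missing:
            raise CholnetError(f"samples missing from design: {missing}")
        empties = [s for s, lab in self.design.items() if not str(lab)]
        if empties:
            raise CholnetError(f"empty design label for samples: {empties}")
        if self.values.isna().any().any():
            raise CholnetError("expression matrix contains missing values")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> dict[str, list[str]]:
        """Map each design label to its samples, in first-appearance order."""
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            out.setdefault(self.design[s], []).append(s)
        return out


def read_expression_matrix(
    path: str | Path,
    design_path: str | Path,
    missing_policy: str = "error",
) -> ExpressionMatrix:
    """Load a TSV expression matrix together with its sample design.

    The matrix file has a header row of sample ids and gene ids in the first
    column; the design file has columns ``sample_id`` and ``label``.  File
    ordering of genes and samples is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise CholnetError(f"duplicate gene id {dup!r} in {path}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        if missing_policy == "error":
            gene = numeric.index[bad.any(axis=1)][0]
            col = numeric.columns[bad.loc[gene]][0]
            raise CholnetError(
                f"non-numeric or missing value at gene {gene!r}, sample {col!r} in {path}"
            )
        dropped = numeric.index[bad.any(axis=1)]
        logger.info("dropping %d genes with missing values", len(dropped))
        numeric = numeric.drop(index=dropped)

    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    if not {"sample_id", "label"} <= set(design_df.columns):
        raise CholnetError(f"design file {design_path} needs columns sample_id, label")
    design = dict(zip(design_df["sample_id"], design_df["label"]))
    absent = [s for s in numeric.columns if s not in design]
    if absent:
        raise CholnetError(f"samples {absent} in {path} missing from design {design_path}")
    design = {s: design[s] for s in numeric.columns}
    return ExpressionMatrix(values=numeric, design=design)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            design_path: str | Path | None = None) -> None:
    """Write a matrix (and optionally its design) in the format read back."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")
    if design_path is not None:
        pd.DataFrame(
            {"sample_id": matrix.sample_ids,
             "label": [matrix.design[s] for s in matrix.sample_ids]}
        ).to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ortholog maps
# ---------------------------------------------------------------------------

@dataclass
class OrthologMap:
    """Many-to-many symbol mapping between two gene namespaces.

    ``pairs`` holds (source_gene, target_gene) tuples; ``resolution_policy``
    decides how one-to-many mappings are collapsed during integration:
    ``max_abs_fc`` keeps the partner with the strongest fold change (ties
    alphabetical), ``first_alphabetical`` keeps the alphabetically first.
    """

    pairs: list[tuple[str, str]]
    resolution_policy: str = "max_abs_fc"

    def __post_init__(self) -> None:
        if self.resolution_policy not in ("max_abs_fc", "first_alphabetical"):
            raise CholnetError(f"unknown resolution_policy {self.resolution_policy!r}")
        seen = set()
        deduped = []
        for p in self.pairs:
            if p not in seen:
                seen.add(p)
                deduped.append(tuple(p))
        self.pairs = deduped

    def targets_of(self, source: str) -> list[str]:
        return [t for s, t in self.pairs if s == source]


def read_ortholog_map(path: str | Path, resolution_policy: str = "max_abs_fc") -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise CholnetError(f"ortholog map {path} needs two columns")
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return OrthologMap(pairs=pairs, resolution_policy=resolution_policy)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    pd.DataFrame(omap.pairs, columns=["source_gene", "target_gene"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------

@dataclass
class InteractionNetwork:
    """Undirected gene/protein interaction graph.

    Node attributes: ``role`` ("deg" or "neighbor"), ``regulator`` (bool),
    ``module_label`` (optional str).  Edge attribute: ``kind`` ("ppi" for
    protein-protein, "protein_dna" for protein-DNA).  Self-loops and
    duplicate unordered edges are rejected.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            if u == v:
                raise CholnetError(f"self-loop on node {u!r}")
        for u, v, kind in self.graph.edges(data="kind"):
            if kind not in SIF_KINDS.values():
                raise CholnetError(
                    f"edge {u!r}-{v!r} has unknown kind {kind!r}; "
                    f"accepted: {sorted(SIF_KINDS.values())}")

    def add_edge(self, u: str, v: str, kind: str) -> None:
        if u == v:
            raise CholnetError(f"self-loop on node {u!r}")
        if kind not in SIF_KINDS.values():
            raise CholnetError(
                f"unknown interaction kind {kind!r}; accepted: {sorted(SIF_KINDS.values())}")
        self.graph.add_edge(u, v, kind=kind)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes())

    def edge_set(self) -> set[tuple[str, str, str]]:
        """Canonical (sorted-endpoint) edge set with kinds, for comparison."""
        return {(min(u, v), max(u, v), d["kind"]) for u, v, d in self.graph.edges(data=True)}

    def deg_nodes(self) -> list[str]:
        return [n for n, r in self.graph.nodes(data="role") if r == "deg"]


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Parse a SIF-style edge list: ``node  kind  node`` per line.

    Accepted kind tokens are ``pp`` (protein-protein) and ``pd``
    (protein-DNA); duplicate unordered edges collapse to one, self-loop
    lines are errors.
    """
    net = InteractionNetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise CholnetError(f"{path}:{lineno}: expected 'node kind node', got {line!r}")
            u, token, v = fields
            if token not in SIF_KINDS:
                raise CholnetError(
                    f"{path}:{lineno}: unknown interaction token {token!r}; "
                    f"accepted: {sorted(SIF_KINDS)}")
            if u == v:
                raise CholnetError(f"{path}:{lineno}: self-loop on {u!r}")
            net.add_edge(u, v, kind=SIF_KINDS[token])
    return net


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, kind in sorted(net.edge_set()):
            fh.write(f"{u}\t{_KIND_TO_SIF[kind]}\t{v}\n")


def write_graphml(net: InteractionNetwork, path: str | Path) -> None:
    """Export with node attributes role/regulator/module_label/direction_*."""
    g = net.graph.copy()
    for n, data in g.nodes(data=True):
        data.setdefault("role", "neighbor")
        data.setdefault("regulator", False)
        data.setdefault("module_label", "unassigned")
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{term: member gene set}``.

    Each line is ``term<TAB>description<TAB>gene...``; member lists are
    deduplicated, duplicate term names and lines with fewer than three
    fields are errors.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CholnetError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term = fields[0]
            if term in sets:
                raise CholnetError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = set(g for g in fields[2:] if g)
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path,
                    descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in sets:
            desc = (descriptions or {}).get(term, "na")
            members = "\t".join(sorted(set(sets[term])))
            fh.write(f"{term}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a per-gene statistics table (gene column first)."""
    out = table.copy()
    if out.index.name == "gene" or "gene" not in out.columns:
        out = out.reset_index().rename(columns={out.index.name or "index": "gene"})
    cols = [c for c in DEG_TABLE_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")
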