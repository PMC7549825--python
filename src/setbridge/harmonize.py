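"""Cross-platform dataset harmonization: gene matching and sample alignment.

Microarray and RNA-Seq datasets of the same biological samples typically carry
different primary gene identifiers (e.g. Entrez vs Ensembl).  Matching goes
through a user-supplied many-to-many mapping table; ambiguous mappings are
resolved by exact agreement of a secondary gene symbol, and genes that remain
inconclusive are removed from both datasets rather than merged or averaged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "MappingTable",
    "match_genes",
    "align_samples",
    "read_expression_tsv",
]

Platform = Literal["array", "seq", "other"]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with identifiers and a platform tag.

    ``values`` holds microarray intensities or RNA-Seq counts; missing entries
    must be resolved upstream.  ``symbols`` is an optional secondary per-gene
    symbol (may repeat or be empty) used only for duplicate resolution during
    gene matching.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    platform: Platform = "other"
    symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")
        if self.platform == "seq" and (self.values < 0).any():
            raise ValueError("seq platform values must be non-negative")
        if self.symbols is not None:
            self.symbols = [str(s) for s in self.symbols]
            if len(self.symbols) != len(self.gene_ids):
                raise ValueError("symbols length must match gene_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[rows, :],
            list(gene_ids),
            list(self.sample_ids),
            self.platform,
            [self.symbols[i] for i in rows] if self.symbols is not None else None,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, cols],
            list(self.gene_ids),
            list(sample_ids),
            self.platform,
            list(self.symbols) if self.symbols is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        return df

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        if self.symbols is not None:
            df.insert(0, "symbol", self.symbols)
        df.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, platform: Platform = "other") -> ExpressionMatrix:
    """Read a genes-in-rows TSV: first column gene IDs, optional ``symbol`` column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    symbols = None
    if "symbol" in df.columns:
        symbols = df.pop("symbol").astype(str).tolist()
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        df.index.astype(str).tolist(),
        df.columns.astype(str).tolist(),
        platform,
        symbols,
    )


@dataclass
class MappingTable:
    """(source_id, target_id) pairs; many-to-many allowed, exact duplicates not."""

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.pairs)
        if df.shape[1] != 2:
            raise ValueError("mapping table must have exactly two columns")
        df.columns = ["source_id", "target_id"]
        df = df.astype(str)
        if df.duplicated().any():
            raise ValueError("mapping table contains fully duplicated rows")
        self.pairs = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MappingTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class MatchReport:
    """Per-step bookkeeping of the gene-matching procedure."""

    n_input_a: int = 0
    n_input_b: int = 0
    n_unmapped_a: int = 0
    n_unmapped_b: int = 0
    n_one_to_one: int = 0
    n_symbol_resolved: int = 0
    n_dropped_ambiguous_a: int = 0
    n_dropped_ambiguous_b: int = 0
    n_matched: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _components(edges: list[tuple[str, str]]) -> list[tuple[set[str], set[str], list[tuple[str, str]]]]:
    """Connected components of the bipartite a-gene/b-gene mapping graph."""
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for a, b in edges:
        na, nb = ("a", a), ("b", b)
        parent.setdefault(na, na)
        parent.setdefault(nb, nb)
        union(na, nb)

    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for a, b in edges:
        groups.setdefault(find(("a", a)), []).append((a, b))
    out = []
    for comp_edges in groups.values():
        out.append(
            (
                {a for a, _ in comp_edges},
                {b for _, b in comp_edges},
                comp_edges,
            )
        )
    return out


def match_genes(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    map_ab: MappingTable,
) -> tuple[ExpressionMatrix, ExpressionMatrix, MatchReport]:
    """Match genes of two datasets through a mapping table.

    Procedure: (1) genes without any mapping are removed from both sides;
    (2) within ambiguous (non-1:1) mapping components, pairs whose gene symbols
    agree exactly (after whitespace trimming, case-sensitive) are kept when the
    agreeing pairs form an unambiguous matching; (3) components that remain
    inconclusive — no agreeing pair, or a gene with two or more agreeing
    partners — are removed entirely from both datasets.

    Returns gene-aligned copies of both matrices (identical gene count and
    pairing order; ``b``'s rows are reported under their own identifiers) and a
    :class:`MatchReport` of counts removed at each step.
    """
    report = MatchReport(n_input_a=a.n_genes, n_input_b=b.n_genes)
    a_genes, b_genes = set(a.gene_ids), set(b.gene_ids)
    edges = [
        (s, t)
        for s, t in map_ab.pairs.itertuples(index=False)
        if s in a_genes and t in b_genes
    ]
    mapped_a = {s for s, _ in edges}
    mapped_b = {t for _, t in edges}
    report.n_unmapped_a = a.n_genes - len(mapped_a)
    report.n_unmapped_b = b.n_genes - len(mapped_b)

    sym_a = dict(zip(a.gene_ids, a.symbols)) if a.symbols is not None else None
    sym_b = dict(zip(b.gene_ids, b.symbols)) if b.symbols is not None else None

    kept: list[tuple[str, str]] = []
    for comp_a, comp_b, comp_edges in _components(edges):
        if len(comp_a) == 1 and len(comp_b) == 1:
            kept.append(comp_edges[0])
            report.n_one_to_one += 1
            continue
        if sym_a is None or sym_b is None:
            missing = sorted(comp_a | comp_b)
            raise ValueError(
                f"gene symbols required to resolve duplicate mappings for genes {missing}"
            )
        agree = [
            (x, y)
            for x, y in comp_edges
            if sym_a[x].strip() == sym_b[y].strip() and sym_a[x].strip() != ""
        ]
        a_deg = {x: sum(1 for x2, _ in agree if x2 == x) for x in comp_a}
        b_deg = {y: sum(1 for _, y2 in agree if y2 == y) for y in comp_b}
        conclusive = (
            len(agree) > 0
            and all(d <= 1 for d in a_deg.values())
            and all(d <= 1 for d in b_deg.values())
        )
        if conclusive:
            kept.extend(agree)
            report.n_symbol_resolved += len(agree)
        else:
            report.n_dropped_ambiguous_a += len(comp_a)
            report.n_dropped_ambiguous_b += len(comp_b)

    if not kept:
        raise ValueError("no genes could be matched between the two datasets")

    # preserve a's input gene order for the matched pairs
    order = {g: i for i, g in enumerate(a.gene_ids)}
    kept.sort(key=lambda e: order[e[0]])
    report.n_matched = len(kept)
    a_out = a.subset_genes([x for x, _ in kept])
    b_out = b.subset_genes([y for _, y in kept])
    return a_out, b_out, report


def align_samples(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Restrict both matrices to their shared samples, in identical column order.

    The shared order follows ``a``'s column order.  Raises on an empty sample
    intersection.
    """
    common = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not common:
        raise ValueError("no samples shared between the two datasets")
    report = {
        "n_shared": len(common),
        "dropped_a": [s for s in a.sample_ids if s not in set(common)],
        "dropped_b": [s for s in b.sample_ids if s not in set(common)],
    }
    return a.subset_samples(common), b.subset_samples(common), report
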