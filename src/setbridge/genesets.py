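"""Gene set collections: GMT I/O, composition summaries and structure-preserving permutation.

A gene set collection (e.g. the MSigDB hallmark or oncogenic collections) is a
named family of gene sets used as an a-priori basis for the enrichment-score
transform.  Permuted collections keep the structure of the original (set names,
set sizes, total pool) while destroying the biological coherence of membership;
they provide the null distribution against which real-collection concordance is
judged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "CollectionSummary",
    "read_gmt",
    "write_gmt",
    "summarize_collection",
    "permute_collection",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene identifiers.

    Gene identifiers are opaque, case-sensitive strings; identifier semantics
    (Entrez vs Ensembl vs symbol) are owned by the harmonize module.
    """

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} contains duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """A named list of gene sets with unique set names."""

    name: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate set names in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def set_names(self) -> list[str]:
        return [s.name for s in self.sets]

    @property
    def pool(self) -> list[str]:
        """Union of all member genes, sorted for determinism."""
        genes: set[str] = set()
        for s in self.sets:
            genes.update(s.members)
        return sorted(genes)


@dataclass(frozen=True)
class CollectionSummary:
    """Composition statistics of a collection (one row of a collection table)."""

    name: str
    n_sets: int
    min_size: int
    max_size: int
    mean_size: float
    total_genes: int
    unique_genes: int
    max_occurrence: int

    def to_frame(self, mean_digits: int | None = 0) -> pd.DataFrame:
        """One-row frame with conventional column names; mean rounded as configured."""
        mean = self.mean_size if mean_digits is None else round(self.mean_size, mean_digits)
        if mean_digits == 0:
            mean = int(mean)
        return pd.DataFrame(
            [
                {
                    "Name": self.name,
                    "# gene Sets": self.n_sets,
                    "Min set size": self.min_size,
                    "Max Set size": self.max_size,
                    "Mean Set size": mean,
                    "Total # genes": self.total_genes,
                    "Unique # genes": self.unique_genes,
                    "Max occurrence": self.max_occurrence,
                }
            ]
        )


class GMTParseError(ValueError):
    """Raised when a GMT line cannot be parsed."""


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a tab-separated GMT file (set name, description, members...).

    Duplicate gene entries within a line are dropped (first occurrence wins)
    with a logged warning; the description field is retained but unused
    downstream.

    Raises :class:`GMTParseError` naming the offending line for lines with
    fewer than three fields, and ``ValueError`` for duplicated set names.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_name, description, *genes = fields
            genes = [g for g in genes if g != ""]
            if len(genes) == 0:
                raise GMTParseError(f"{path}: line {lineno}: gene set {set_name!r} has no members")
            seen: dict[str, None] = {}
            n_dupes = 0
            for g in genes:
                if g in seen:
                    n_dupes += 1
                else:
                    seen[g] = None
            if n_dupes:
                logger.warning(
                    "GMT %s line %d: set %r had %d duplicate gene entries (deduplicated)",
                    path,
                    lineno,
                    set_name,
                    n_dupes,
                )
            sets.append(GeneSet(set_name, tuple(seen), description))
    return GeneSetCollection(name or path.stem, sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; round-trips losslessly through :func:`read_gmt`."""
    if len(collection) == 0:
        raise ValueError("refusing to write an empty collection")
    path = Path(path)
    with path.open("w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.members]) + "\n")


def summarize_collection(collection: GeneSetCollection) -> CollectionSummary:
    """Composition summary: set count, size range, total/unique genes, max gene reuse."""
    if len(collection) == 0:
        raise ValueError("cannot summarize an empty collection")
    sizes = np.array([len(s) for s in collection])
    counts: dict[str, int] = {}
    for s in collection:
        for g in s.members:
            counts[g] = counts.get(g, 0) + 1
    return CollectionSummary(
        name=collection.name,
        n_sets=len(collection),
        min_size=int(sizes.min()),
        max_size=int(sizes.max()),
        mean_size=float(sizes.mean()),
        total_genes=int(sizes.sum()),
        unique_genes=len(counts),
        max_occurrence=max(counts.values()),
    )


def permute_collection(
    collection: GeneSetCollection,
    seed: int | np.random.Generator,
) -> GeneSetCollection:
    """Draw a permuted collection: same set names and sizes, members resampled.

    Every permuted set is an independent uniform without-replacement draw from
    the pool of all genes occurring anywhere in the collection, so a permuted
    set contains a gene at most once but the same gene may land in several
    permuted sets (mirroring gene reuse in real collections).  Reproducible
    given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.array(collection.pool, dtype=object)
    permuted: list[GeneSet] = []
    for s in collection:
        if len(s) > pool.size:
            raise ValueError(
                f"set {s.name!r} (size {len(s)}) exceeds collection pool size {pool.size}"
            )
        members = rng.choice(pool, size=len(s), replace=False)
        permuted.append(GeneSet(s.name, tuple(members), s.description))
    return GeneSetCollection(f"{collection.name}_permuted", permuted)
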