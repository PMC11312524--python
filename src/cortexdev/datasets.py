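"""Containers and plain-text IO for expression data and gene sets.

Expression matrices travel as TSV (rows = genes, first column the gene
id), sample metadata as TSV (sample, age, region, sex, RIN, donor), and
cell-type gene sets as GMT (set name, description, then member genes,
tab-separated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "read_expression_tsv",
    "read_gmt",
    "write_gmt",
]

DIALECTS = ("microarray-normalized", "rnaseq-log2rpkm")


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with sample metadata.

    ``expression``: DataFrame indexed by gene id, one column per sample.
    ``samples``: DataFrame indexed by sample id with at least ``age``
    (years); ``region``, ``sex``, ``rin`` and ``donor`` are used by the
    RNA-seq dialect. ``dialect`` flags the value scale: normalized
    microarray intensities or log2 RPKM.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    dialect: str = "microarray-normalized"

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.expression.shape[1] != len(self.samples):
            raise ValueError(
                f"{self.expression.shape[1]} expression columns vs "
                f"{len(self.samples)} metadata rows"
            )
        if not (self.expression.columns == self.samples.index).all():
            raise ValueError("sample order mismatch between matrix and metadata")
        if "age" not in self.samples:
            raise ValueError("sample metadata needs an 'age' column")
        if self.samples["age"].isna().any():
            raise ValueError("missing ages in sample metadata")
        if not np.isfinite(self.expression.to_numpy()).all():
            raise ValueError("non-finite expression values")

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def ages(self) -> np.ndarray:
        return self.samples["age"].to_numpy(float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_tsv(self, expression_path, samples_path) -> None:
        self.expression.to_csv(expression_path, sep="\t", index_label="gene")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_expression_tsv(
    expression_path, samples_path, dialect="microarray-normalized"
) -> ExpressionDataset:
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return ExpressionDataset(expr, meta.loc[expr.columns], dialect)


@dataclass
class GeneSetCollection:
    """Named cell-type gene sets over a background universe."""

    sets: dict[str, frozenset]
    universe: frozenset
    disjoint: bool = field(default=False)

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        self.universe = frozenset(self.universe)
        for name, s in self.sets.items():
            extra = s - self.universe
            if extra:
                raise ValueError(
                    f"set {name!r} has {len(extra)} genes outside the universe"
                )
        if self.disjoint:
            for a, b in combinations(self.sets, 2):
                common = self.sets[a] & self.sets[b]
                if common:
                    raise ValueError(
                        f"sets {a!r} and {b!r} overlap ({len(common)} genes) "
                        "but disjointness was requested"
                    )

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read gene sets from a GMT file.

    If ``universe`` is None it is taken as the union of all sets.
    """
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, frozenset(universe))


def write_gmt(collection: GeneSetCollection, path, description="") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")
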