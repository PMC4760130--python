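"""Core in-memory containers: expression matrix, module definitions, annotation.

The expression matrix is a thin, validated wrapper around a pandas DataFrame
(genes x samples) plus a boolean missing-entry mask.  Modules are ordered gene
lists carrying a per-gene weight magnitude and an optional sign: a signed
weight encodes prior knowledge that a gene is an activator (positive) or an
inhibitor (negative) of the hidden factor the module reports on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError


class ExpressionMatrix:
    """Genes x samples numeric expression table with an optional missing mask.

    Parameters
    ----------
    values
        2-D real array, shape (n_genes, n_samples).  Expression units are
        taken as provided (log scale assumed, not enforced).
    gene_ids, sample_ids
        Unique, ordered identifiers for rows and columns.
    missing_mask
        Boolean array of the same shape; True marks a missing entry.  Missing
        entries may hold any placeholder value (NaN is used internally).
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        missing_mask: np.ndarray | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"shape {values.shape} inconsistent with "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        dup = _first_duplicate(gene_ids)
        if dup is not None:
            raise FormatError(f"duplicate gene name {dup!r}")
        dup = _first_duplicate(sample_ids)
        if dup is not None:
            raise FormatError(f"duplicate sample name {dup!r}")
        if missing_mask is None:
            missing_mask = np.isnan(values)
        else:
            missing_mask = np.asarray(missing_mask, dtype=bool)
            if missing_mask.shape != values.shape:
                raise ValueError("missing_mask shape differs from values")
        observed = values[~missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise FormatError("non-finite value in a non-missing cell")
        self.values = values
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.missing_mask = missing_mask

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        return df.mask(pd.DataFrame(self.missing_mask, index=df.index, columns=df.columns))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        values = df.to_numpy(dtype=float)
        return cls(values, list(df.index), list(df.columns), np.isnan(values))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.sample_ids), self.missing_mask.copy()
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        miss = int(self.missing_mask.sum())
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples"
            + (f", {miss} missing" if miss else "")
            + ")"
        )


@dataclass(frozen=True)
class ModuleGene:
    """One gene of a module: weight magnitude plus optional known sign.

    ``sign_defined`` is True iff the module file specified a signed weight for
    the gene; only such genes take part in PC1 orientation.
    """

    name: str
    weight: float = 1.0
    sign_defined: bool = False

    def __post_init__(self) -> None:
        if self.weight == 0:
            raise FormatError(f"gene {self.name!r} has zero weight")
        if not self.sign_defined and self.weight != 1.0:
            raise ValueError("unsigned genes must carry the default weight +1.0")


@dataclass
class ModuleDefinition:
    """A named gene set, optionally with per-gene signed weights."""

    name: str
    description: str = ""
    genes: list[ModuleGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"module {self.name!r} has no genes")
        dup = _first_duplicate([g.name for g in self.genes])
        if dup is not None:
            raise FormatError(f"module {self.name!r} lists gene {dup!r} twice")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def weights(self) -> np.ndarray:
        return np.array([g.weight for g in self.genes], dtype=float)

    def subset(self, names: Iterable[str]) -> "ModuleDefinition":
        keep = set(names)
        return ModuleDefinition(
            self.name, self.description, [g for g in self.genes if g.name in keep]
        )


class SampleAnnotation:
    """Per-sample annotation table (string/numeric feature columns)."""

    def __init__(self, table: pd.DataFrame) -> None:
        sample_ids = [str(s) for s in table.index]
        dup = _first_duplicate(sample_ids)
        if dup is not None:
            raise FormatError(f"duplicate sample name {dup!r} in annotation")
        self.table = table.set_axis(sample_ids, axis=0)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def features(self) -> list[str]:
        return list(self.table.columns)

    def column(self, feature: str) -> pd.Series:
        if feature not in self.table.columns:
            raise KeyError(f"unknown annotation feature {feature!r}")
        return self.table[feature]


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
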