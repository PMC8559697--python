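"""Mutation catalogs: samples x SBS-96 category count matrices.

A catalog holds the observed data of the model — for each tumor sample the
number of somatic single-base substitutions falling into each of the 96
pyrimidine-centered substitution categories (6 substitution classes x 16
flanking-base contexts). Only category counts matter to the likelihood; the
order in which mutations were observed is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"


def sbs96_labels() -> list[str]:
    """The canonical 96 SBS category labels in COSMIC order.

    Grouped by substitution class (C>A, C>G, C>T, T>A, T>C, T>G), each with
    its 16 flanking contexts in lexicographic order: ``A[C>A]A`` ... ``T[T>G]T``.
    """
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTION_CLASSES
        for five in _BASES
        for three in _BASES
    ]


def _default_sample_ids(n: int) -> list[str]:
    return [f"sample_{i}" for i in range(n)]


@dataclass
class MutationCatalog:
    """An N x M matrix of non-negative integer mutation counts.

    Parameters
    ----------
    counts
        Array of shape (n_samples, n_categories); entry (n, j) is the number
        of mutations of category j observed in sample n. Per-sample totals may
        be zero (such samples carry no likelihood information but are kept).
    sample_ids
        Unique sample identifiers, one per row.
    category_labels
        Category names, one per column; defaults to the canonical SBS-96 set
        when the matrix has 96 columns, else generic ``cat0..cat{M-1}``.
    """

    counts: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    category_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x categories matrix")
        if counts.shape[1] < 2:
            raise ValueError("a catalog needs at least 2 mutation categories")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts
        n, m = counts.shape
        if self.sample_ids is None:
            self.sample_ids = _default_sample_ids(n)
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if self.category_labels is None:
            self.category_labels = sbs96_labels() if m == 96 else [f"cat{j}" for j in range(m)]
        else:
            self.category_labels = [str(c) for c in self.category_labels]
        if len(self.category_labels) != m:
            raise ValueError("category_labels length does not match number of columns")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Per-sample mutation totals T_n."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.category_labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MutationCatalog":
        return cls(
            counts=frame.to_numpy(),
            sample_ids=list(frame.index.astype(str)),
            category_labels=list(frame.columns.astype(str)),
        )


def as_counts(catalog) -> np.ndarray:
    """Coerce a MutationCatalog or array-like into a validated count matrix."""
    if isinstance(catalog, MutationCatalog):
        return catalog.counts
    return MutationCatalog(np.asarray(catalog)).counts
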