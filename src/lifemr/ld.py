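"""Linkage-disequilibrium matrices aligned to an ordered variant list.

LD is always consumed precomputed (e.g. from a 1000G EUR reference panel);
this module never estimates correlations from genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LDMatrix", "read_ld"]

_PSD_TOL = 1e-8


@dataclass
class LDMatrix:
    """Signed pairwise correlation matrix aligned to an ordered variant list.

    Parameters
    ----------
    variant_ids
        Ordered variant identifiers labelling rows/columns of ``r``.
    r
        Square matrix of signed correlations, symmetric, unit diagonal,
        entries in [-1, 1], positive semi-definite within 1e-8.
    check
        Validate the invariants on construction. Constructively valid
        matrices (AR(1) simulation, submatrices of validated matrices)
        may skip the eigenvalue check.
    """

    variant_ids: list[str]
    r: np.ndarray
    check: bool = True
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} variants")
        if len(set(self.variant_ids)) != m:
            raise ValueError("duplicate variant ids in LD matrix")
        if self.check:
            if not np.allclose(self.r, self.r.T, atol=1e-8):
                raise ValueError("LD matrix is not symmetric")
            if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
                raise ValueError("LD matrix diagonal is not 1")
            if np.any(np.abs(self.r) > 1 + 1e-8):
                raise ValueError("LD entries outside [-1, 1]")
            if m <= 2000 and np.linalg.eigvalsh(self.r).min() < -_PSD_TOL:
                raise ValueError("LD matrix is not positive semi-definite")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    # -- lookups ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} absent from LD matrix") from None

    def corr(self, a: str, b: str) -> float:
        """Signed correlation r between two variants."""
        return float(self.r[self.index_of(a), self.index_of(b)])

    def r2(self, a: str, b: str) -> float:
        """Squared correlation r^2 between two variants."""
        return self.corr(a, b) ** 2

    def submatrix(self, variant_ids: list[str]) -> "LDMatrix":
        idx = [self.index_of(v) for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)], check=False)

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_long(cls, triplets: pd.DataFrame, check: bool = True) -> "LDMatrix":
        """Build from (id1, id2, r) triplets; missing pairs default to 0."""
        ids = pd.unique(pd.concat([triplets.iloc[:, 0], triplets.iloc[:, 1]]))
        index = {v: i for i, v in enumerate(ids)}
        m = len(ids)
        r = np.zeros((m, m))
        np.fill_diagonal(r, 1.0)
        for a, b, val in triplets.itertuples(index=False):
            r[index[a], index[b]] = val
            r[index[b], index[a]] = val
        return cls(list(ids), r, check=check)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", index_label="variant_id"
        )


def read_ld(path, check: bool = True) -> LDMatrix:
    """Read LD from a square tab-delimited matrix or long (id1, id2, r) triplets.

    A square file has a header of variant ids and one labelled row per
    variant; a long file has exactly three columns.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 3 and not np.issubdtype(df.dtypes.iloc[1], np.number):
        return LDMatrix.from_long(df, check=check)
    ids = list(df.columns[1:])
    return LDMatrix(ids, df.iloc[:, 1:].to_numpy(dtype=float), check=check)
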