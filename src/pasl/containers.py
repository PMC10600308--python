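"""In-memory containers shared across the package.

The central objects are an expression matrix ``X`` (samples x features), a
geneset collection parsed from a GMT file, and the binary membership matrix
``G`` (genesets x features) that aligns the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class ExpressionMatrix:
    """A samples-by-features numeric matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Expression values; must be finite (loaders reject missing data).
    sample_ids : list of str
    feature_ids : list of str
        Must be unique; alignment with a membership matrix is by these ids.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class GenesetCollection:
    """Ordered named genesets as parsed from a GMT file.

    Each entry is ``(name, description, members)`` with ``members`` a set of
    feature-identifier strings. Names are unique and file order is preserved.
    """

    entries: list[tuple[str, str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate geneset names: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def members(self, name: str) -> frozenset[str]:
        for n, _, m in self.entries:
            if n == name:
                return m
        raise KeyError(name)


@dataclass
class MembershipMatrix:
    """Binary geneset-membership matrix G (m genesets x p features).

    ``matrix[i, j] == 1`` when feature ``j`` measures at least one gene of
    geneset ``i``. Rows with empty support are dropped at construction time
    (their names are kept in ``dropped_names`` for the record).
    """

    matrix: sp.csr_matrix
    geneset_names: list[str]
    feature_ids: list[str]
    dropped_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.int8)
        m, p = self.matrix.shape
        if len(self.geneset_names) != m:
            raise ValueError("geneset_names length mismatch")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length mismatch")
        if self.matrix.nnz and not np.isin(self.matrix.data, (0, 1)).all():
            raise ValueError("membership entries must be binary")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def support(self, i: int) -> np.ndarray:
        """Column indices of the features in geneset ``i`` (sorted)."""
        return np.sort(self.matrix.indices[self.matrix.indptr[i] : self.matrix.indptr[i + 1]])

    def sizes(self) -> np.ndarray:
        """Number of member features per geneset."""
        return np.diff(self.matrix.indptr)

    def covered_features(self) -> np.ndarray:
        """Boolean mask over features: covered by at least one geneset."""
        return np.asarray(self.matrix.sum(axis=0)).ravel() > 0
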