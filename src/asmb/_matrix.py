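"""Symmetric pairwise matrices over samples, tagged with the quantity they carry."""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

#: roles whose diagonal is undefined (scores, not metrics) and stored as NaN
_UNDEFINED_DIAGONAL = frozenset({"bnti", "rc"})

ROLES = frozenset(
    {"dissimilarity", "similarity", "spatial_km", "env_distance", "distance",
     "bnti", "rc"}
)


class PairwiseMatrix:
    """A square symmetric matrix over a set of sample labels.

    The ``role`` tag records what the values mean (a dissimilarity, a
    spatial distance in km, a null-model score, ...) and drives validation:
    dissimilarities/similarities must lie in [0, 1], Raup-Crick scores in
    [-1, 1], and score matrices (``bnti``, ``rc``) carry a NaN diagonal
    instead of zeros.
    """

    def __init__(self, values, labels, role: str):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {sorted(ROLES)}")
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"matrix must be square, got shape {values.shape}")
        if values.shape[0] != len(labels):
            raise ValueError("label count does not match matrix dimension")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        off = ~np.eye(len(labels), dtype=bool)
        vals_off = values[off]
        if not np.all(np.isfinite(vals_off)):
            raise ValueError("non-finite off-diagonal values")
        if not np.allclose(values, values.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if role in _UNDEFINED_DIAGONAL:
            values = values.copy()
            np.fill_diagonal(values, np.nan)
        elif role == "similarity":
            # self-similarity is 1 by definition
            if not np.allclose(np.diag(values), 1.0, atol=1e-12):
                raise ValueError("similarity diagonal must be one")
            values = values.copy()
            np.fill_diagonal(values, 1.0)
        else:
            if not np.allclose(np.diag(values), 0.0, atol=1e-12):
                raise ValueError("diagonal must be zero")
            values = values.copy()
            np.fill_diagonal(values, 0.0)
        if role in ("dissimilarity", "similarity"):
            if vals_off.min() < -1e-9 or vals_off.max() > 1 + 1e-9:
                raise ValueError(f"{role} values must lie in [0, 1]")
            values = np.clip(values, 0.0, 1.0)
        elif role == "rc":
            if np.nanmin(values) < -1 - 1e-9 or np.nanmax(values) > 1 + 1e-9:
                raise ValueError("rc values must lie in [-1, 1]")
        elif role in ("spatial_km", "env_distance", "distance"):
            if vals_off.min() < -1e-9:
                raise ValueError(f"{role} values must be non-negative")
            values = np.where(np.abs(values) < 1e-15, 0.0, values)
        self.values = values
        self.labels = labels
        self.role = role

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PairwiseMatrix)
            and self.role == other.role
            and self.labels == other.labels
            and np.allclose(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"<PairwiseMatrix role={self.role} n={len(self)}>"

    # -- views -------------------------------------------------------------
    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy ``squareform`` (row-major) order."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def pair_labels(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(len(self), k=1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]

    def to_similarity(self) -> "PairwiseMatrix":
        if self.role != "dissimilarity":
            raise ValueError("to_similarity is defined for dissimilarity matrices")
        return PairwiseMatrix(1.0 - self.values, self.labels, "similarity")

    def to_dissimilarity(self) -> "PairwiseMatrix":
        if self.role != "similarity":
            raise ValueError("to_dissimilarity is defined for similarity matrices")
        return PairwiseMatrix(1.0 - self.values, self.labels, "dissimilarity")

    def subset(self, labels) -> "PairwiseMatrix":
        labels = [str(x) for x in labels]
        missing = set(labels) - set(self.labels)
        if missing:
            raise KeyError(f"labels not in matrix: {sorted(missing)}")
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(self.values[np.ix_(idx, idx)], labels, self.role)

    def to_skbio(self) -> DistanceMatrix:
        if self.role in _UNDEFINED_DIAGONAL:
            raise ValueError(f"role {self.role!r} is not a distance")
        return DistanceMatrix(self.values, ids=self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    # -- IO ----------------------------------------------------------------
    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = self.role
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, role: str | None = None) -> "PairwiseMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        inferred = df.index.name if df.index.name in ROLES else None
        role = role or inferred
        if role is None:
            raise ValueError("role not given and not recorded in the file header")
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(df.to_numpy(dtype=float), list(df.columns), role)

    @classmethod
    def from_condensed(cls, vec, labels, role: str) -> "PairwiseMatrix":
        from scipy.spatial.distance import squareform

        return cls(squareform(np.asarray(vec, dtype=float)), labels, role)


def check_same_labels(*matrices: PairwiseMatrix) -> None:
    """Fail loudly when matrices do not cover the same samples in the same order."""
    first = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != first:
            raise ValueError(
                "pairwise matrices cover different samples: "
                f"{first[:3]}... vs {m.labels[:3]}..."
            )
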