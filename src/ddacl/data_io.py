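"""Reading, validating and writing association / similarity matrices.

File dialect: delimited text (tab by default, comma auto-detected), UTF-8,
one header row of column identifiers and one leading column of row
identifiers; the first header cell is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DatasetBundle",
    "MatrixParseError",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "sparse_ratio",
    "write_predictions",
]


class MatrixParseError(ValueError):
    """Raised when a matrix file cannot be parsed."""


class MatrixValidationError(ValueError):
    """Raised when a parsed matrix violates its invariants."""


@dataclass
class AssociationMatrix:
    """Binary drug-disease incidence matrix A (N drugs x M diseases)."""

    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray  # N x M, entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise MatrixValidationError("association matrix must be at least 1x1")
        if len(self.drug_ids) != n or len(self.disease_ids) != m:
            raise MatrixValidationError("identifier count does not match matrix shape")
        if len(set(self.drug_ids)) != n:
            raise MatrixValidationError("duplicate drug identifiers")
        if len(set(self.disease_ids)) != m:
            raise MatrixValidationError("duplicate disease identifiers")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise MatrixValidationError(
                f"association entries must be 0 or 1; found "
                f"{self.values[bad[0], bad[1]]!r} at "
                f"({self.drug_ids[bad[0]]}, {self.disease_ids[bad[1]]})"
            )
        self.values = self.values.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MatrixValidationError(
                f"similarity matrix must be square over its {n} identifiers, "
                f"got shape {self.values.shape}"
            )
        if len(set(self.ids)) != n:
            raise MatrixValidationError("duplicate identifiers in similarity matrix")
        asym = np.abs(self.values - self.values.T)
        if asym.size and asym.max() > 1e-8:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise MatrixValidationError(
                f"similarity matrix not symmetric: ({self.ids[i]}, {self.ids[j]}) "
                f"differs from its transpose by {asym[i, j]:.3g}"
            )
        if self.values.min() < 0 or self.values.max() > 1:
            raise MatrixValidationError("similarity entries must lie in [0, 1]")
        diag = np.diag(self.values)
        if not np.allclose(diag, 1.0):
            # some published similarity kernels do not have unit diagonals
            warnings.warn(
                "similarity matrix diagonal is not identically 1",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DatasetBundle:
    """An association matrix plus the two matching similarity matrices."""

    associations: AssociationMatrix
    drug_similarity: SimilarityMatrix
    disease_similarity: SimilarityMatrix

    def __post_init__(self) -> None:
        if self.drug_similarity.ids != self.associations.drug_ids:
            raise MatrixValidationError("drug similarity ids do not match association drug ids")
        if self.disease_similarity.ids != self.associations.disease_ids:
            raise MatrixValidationError(
                "disease similarity ids do not match association disease ids"
            )


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "," if ("," in header and "\t" not in header) else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.loc[r, c])
        )
        raise MatrixParseError(f"{path}: missing or ragged cell at row {row!r}, column {col!r}")
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna().to_numpy().argmax()]
        raise MatrixParseError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    return df


def read_matrix(path: str | Path, kind: str) -> AssociationMatrix | SimilarityMatrix:
    """Read a delimited matrix file as an association or similarity matrix.

    Association bodies must already be binary (float 0.0/1.0 is cast, anything
    else rejected); similarity bodies must be symmetric with entries in [0, 1].
    """
    df = _read_frame(path)
    ids_rows = [str(i) for i in df.index]
    ids_cols = [str(c) for c in df.columns]
    if kind == "association":
        return AssociationMatrix(ids_rows, ids_cols, df.to_numpy())
    if kind == "similarity":
        if ids_rows != ids_cols:
            raise MatrixValidationError(f"{path}: row and column identifiers differ")
        return SimilarityMatrix(ids_rows, df.to_numpy())
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix: AssociationMatrix | SimilarityMatrix, path: str | Path,
                 sep: str = "\t") -> None:
    """Write a matrix back to delimited text (lossless round trip)."""
    if isinstance(matrix, AssociationMatrix):
        df = pd.DataFrame(matrix.values, index=matrix.drug_ids, columns=matrix.disease_ids)
    else:
        df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep=sep, index_label="id", float_format="%.17g")


def sparse_ratio(assoc: AssociationMatrix) -> float:
    """Fraction of known associations among all drug-disease pairs."""
    return assoc.n_associations / (assoc.n_drugs * assoc.n_diseases)


def write_predictions(pairs: list[tuple[str, str, float]], path: str | Path) -> None:
    """Write scored pairs as TSV sorted by (score desc, drug_id, disease_id)."""
    for drug, disease, score in pairs:
        if not 0.0 <= score <= 1.0:
            raise MatrixValidationError(
                f"score for ({drug}, {disease}) is {score}, outside [0, 1]"
            )
    ordered = sorted(pairs, key=lambda p: (-p[2], p[0], p[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdisease_id\tscore\n")
        for drug, disease, score in ordered:
            fh.write(f"{drug}\t{disease}\t{score:.17g}\n")
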