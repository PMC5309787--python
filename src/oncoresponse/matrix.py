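"""Expression-matrix container and tab-separated I/O.

The matrix is genes x samples in RPKM (reads per kilobase of exon per
million mapped reads), the unit every downstream stage assumes.  Values
are validated on construction: finite, non-negative, unique gene and
sample identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression_tsv", "write_expression_tsv"]


class MatrixError(ValueError):
    """Raised when an expression matrix violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples RPKM table with optional per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  All
        entries must be finite and >= 0.
    annotations
        Optional per-sample metadata (model system, cohort, purity),
        indexed by sample id.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise MatrixError(f"duplicate gene ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise MatrixError(f"duplicate sample ids: {dupes}")
        arr = df.to_numpy(dtype=float)
        bad = ~np.isfinite(arr)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MatrixError(
                f"non-finite value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        neg = arr < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise MatrixError(
                f"negative RPKM at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if self.annotations is not None:
            missing = [s for s in df.columns if s not in self.annotations.index]
            if missing:
                raise MatrixError(f"annotations missing samples: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(RPKM + pseudocount), the scale used for testing and scaling."""
        return np.log2(self.values + pseudocount)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise MatrixError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.annotations)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise MatrixError(f"samples absent from matrix: {missing}")
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[list(samples)]
        return ExpressionMatrix(self.values[list(samples)], ann)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples RPKM matrix from TSV.

    First column holds gene ids, header row holds sample ids.  Errors
    name the offending cell so malformed exports are easy to locate.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise MatrixError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
            )
        df[col] = coerced
    df = df.astype(float)
    if df.isna().any().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise MatrixError(
            f"missing value at gene {df.index[loc[0]]!r}, sample {df.columns[loc[1]]!r}"
        )
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix so that :func:`read_expression_tsv` round-trips it."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
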