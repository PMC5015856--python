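"""Readers, writers and alignment for the package's tabular inputs.

Three plain-text formats are consumed:

* **Expression matrix** — TSV/CSV, genes in rows (CCLE-style orientation),
  first column header ``gene``, remaining columns one per cell line.
* **Drug response** — CSV with header ``cell_line,drug,ec50_um``; EC50 in µM.
* **Gene lists** — one symbol per line, ``#`` comments allowed.

Expression values are used as provided (no normalization); the matrix is
treated as opaque real values, whatever upstream transform produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import logger
from .errors import AlignmentError, FormatError, ParseError, ValidationError

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x cell lines real-valued expression matrix.

    ``data`` is a DataFrame with gene symbols as the index and cell-line
    identifiers as the columns; both must be unique and no value missing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene symbols: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate cell-line identifiers: {dup[:5]}")
        if self.data.isna().any().any():
            raise ValidationError("expression matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cell_lines(self) -> int:
        return self.data.shape[1]

    def samples(self) -> pd.DataFrame:
        """Samples x genes view (the orientation models consume)."""
        return self.data.T


@dataclass(frozen=True)
class DrugResponseTable:
    """Per-(cell line, drug) EC50 records, EC50 strictly positive, in µM."""

    records: pd.DataFrame  # columns: cell_line, drug, ec50_um

    def __post_init__(self) -> None:
        dup = self.records.duplicated(subset=["cell_line", "drug"])
        if dup.any():
            pairs = self.records.loc[dup, ["cell_line", "drug"]].values.tolist()
            raise ValidationError(f"duplicate (cell_line, drug) records: {pairs[:5]}")
        if (self.records["ec50_um"] <= 0).any():
            raise ValidationError("non-positive EC50 in drug-response table")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.records["drug"].unique())

    def for_drug(self, drug: str) -> pd.Series:
        """EC50 values (µM) indexed by cell line for one drug."""
        sub = self.records[self.records["drug"] == drug]
        return pd.Series(
            sub["ec50_um"].to_numpy(), index=list(sub["cell_line"]), name="ec50_um"
        )


@dataclass(frozen=True)
class GeneList:
    name: str
    symbols: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValidationError(f"gene list {self.name!r} is empty")


def read_expression_matrix(
    path, dialect: str = "tsv", allow_missing: bool = False
) -> ExpressionMatrix:
    """Read a genes-x-cell-lines expression matrix.

    Duplicate gene rows collapse to the first occurrence with a warning.
    Missing cells ("NA"/empty) raise :class:`ParseError` unless
    ``allow_missing`` is set, in which case affected rows are dropped with a
    warning. Non-numeric cells always raise, naming the offending location.
    """
    if dialect not in _DIALECT_SEP:
        raise FormatError(f"unknown dialect {dialect!r}; expected tsv or csv")
    df = pd.read_csv(path, sep=_DIALECT_SEP[dialect], index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no cell-line columns found in header")
    df.index = df.index.astype(str)
    df.index.name = "gene"

    missing_on_read = df.isna()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing_on_read
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        cell = bad.loc[gene].idxmax()
        raise ParseError(
            f"{path}: non-numeric expression value at gene {gene!r}, "
            f"cell line {cell!r}: {df.loc[gene, cell]!r}"
        )
    if missing_on_read.any().any():
        if not allow_missing:
            gene = missing_on_read.any(axis=1).idxmax()
            cell = missing_on_read.loc[gene].idxmax()
            raise ParseError(
                f"{path}: missing value at gene {gene!r}, cell line {cell!r} "
                "(pass allow_missing=True to drop such rows)"
            )
        n_before = numeric.shape[0]
        numeric = numeric.dropna(axis=0)
        logger.warning(
            "%s: dropped %d gene rows with missing values", path, n_before - numeric.shape[0]
        )

    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning("%s: %d duplicated gene rows collapsed to first occurrence", path, n_dup)
        numeric = numeric[~numeric.index.duplicated(keep="first")]

    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    if dialect not in _DIALECT_SEP:
        raise FormatError(f"unknown dialect {dialect!r}; expected tsv or csv")
    expr.data.to_csv(path, sep=_DIALECT_SEP[dialect], index_label="gene")


def read_drug_response(path) -> DrugResponseTable:
    """Read a ``cell_line,drug,ec50_um`` CSV.

    Rows with non-numeric or non-positive EC50 are dropped with a warning;
    duplicated (cell line, drug) pairs are a validation error.
    """
    df = pd.read_csv(path)
    required = {"cell_line", "drug", "ec50_um"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    df = df[["cell_line", "drug", "ec50_um"]].copy()
    df["ec50_um"] = pd.to_numeric(df["ec50_um"], errors="coerce")
    keep = df["ec50_um"].notna() & (df["ec50_um"] > 0)
    if (~keep).any():
        logger.warning(
            "%s: dropped %d rows with non-positive or non-numeric EC50", path, int((~keep).sum())
        )
        df = df[keep]
    return DrugResponseTable(df.reset_index(drop=True))


def write_drug_response(resp: DrugResponseTable, path) -> None:
    resp.records.to_csv(path, index=False)


def read_gene_list(path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; ``#`` starts a comment."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                symbols.append(sym)
    return GeneList(name=name or str(path), symbols=frozenset(symbols))


def read_drug_metadata(path) -> pd.DataFrame:
    """Read drug metadata: either ``drug,cmax_um`` or precomputed
    ``drug,resistant_cutoff,sensitive_cutoff`` pairs."""
    df = pd.read_csv(path)
    if "drug" not in df.columns:
        raise FormatError(f"{path}: missing required column 'drug'")
    has_cmax = "cmax_um" in df.columns
    has_pair = {"resistant_cutoff", "sensitive_cutoff"}.issubset(df.columns)
    if not (has_cmax or has_pair):
        raise FormatError(
            f"{path}: need either a cmax_um column or "
            "resistant_cutoff/sensitive_cutoff columns"
        )
    return df


def align_dataset(
    expr: ExpressionMatrix, resp: DrugResponseTable, drug: str
) -> tuple[ExpressionMatrix, pd.Series]:
    """Restrict the matrix and the drug's EC50 vector to shared cell lines.

    Column order after alignment is lexicographic by cell-line id so that all
    downstream CV partitions are reproducible from a seed alone.
    """
    ec50 = resp.for_drug(drug)
    shared = sorted(set(expr.cell_lines) & set(ec50.index))
    if len(shared) < 2:
        raise AlignmentError(
            f"only {len(shared)} cell lines shared between expression matrix "
            f"and responses for drug {drug!r} (need at least 2)"
        )
    return ExpressionMatrix(expr.data[shared]), ec50.loc[shared]
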