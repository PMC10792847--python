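"""Reading and writing the gene x variable matrix and derived tables.

On-disk convention: the matrix is a delimited text table whose header row
names the variables and whose first column holds gene IDs; a required
metadata sidecar (TSV) describes each variable with columns
``name, omic_type, feature, context, population``. Missing cells are
encoded by a configurable token ("NA" by default) or an empty field.
All derived tables are written as TSV at full float precision so that a
write/load round trip is bit-exact.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import OmicsMatrix, VariableDescriptor

DEFAULT_MISSING_TOKENS = ("NA", "")

#: repr-based float format – round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def _delimiter_for(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


def load_metadata(metadata_path: str | Path) -> list[VariableDescriptor]:
    """Read the variable-metadata sidecar (TSV)."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "omic_type", "feature", "context", "population"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing column(s): {sorted(missing)}")
    return [
        VariableDescriptor(
            name=row["name"],
            omic_type=row["omic_type"],
            feature=row["feature"] or "none",
            context=row["context"] or "none",
            population=row["population"],
        )
        for row in meta.to_dict("records")
    ]


def load_matrix(
    path: str | Path,
    metadata_path: str | Path,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> OmicsMatrix:
    """Load a gene x variable matrix plus its variable metadata.

    The delimiter is taken from the matrix extension (.csv -> comma,
    anything else -> tab). Cells equal to a missing token become NaN; any
    other non-numeric cell raises with its row/column location.
    """
    sep = _delimiter_for(path)
    table = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, index_col=0
    )
    gene_ids = [str(g) for g in table.index]
    if len(set(gene_ids)) != len(gene_ids):
        idx = pd.Index(gene_ids)
        raise ValueError(
            f"duplicate gene IDs in {path}: "
            f"{sorted(idx[idx.duplicated()].unique())[:5]}"
        )

    descriptors = {d.name: d for d in load_metadata(metadata_path)}
    variables = []
    for col in table.columns:
        if str(col) not in descriptors:
            raise ValueError(f"variable {col!r} in header has no metadata entry")
        variables.append(descriptors[str(col)])

    raw = table.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    tokens = set(missing_tokens)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip() if isinstance(raw[i, j], str) else raw[i, j]
            if cell in tokens:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at gene {gene_ids[i]!r}, "
                    f"variable {table.columns[j]!r}"
                ) from None
    return OmicsMatrix(values, gene_ids, variables)


def write_matrix(
    m: OmicsMatrix, path: str | Path, missing_token: str = "NA"
) -> None:
    """Write the matrix; missing cells become ``missing_token``."""
    sep = _delimiter_for(path)
    df = m.to_frame()
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT, na_rep=missing_token)


def write_metadata(variables: Iterable[VariableDescriptor], path: str | Path) -> None:
    rows = [
        {
            "name": v.name,
            "omic_type": v.omic_type,
            "feature": v.feature,
            "context": v.context,
            "population": v.population,
        }
        for v in variables
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_table(obj, path: str | Path) -> None:
    """Write a tabular artifact (DataFrame/Series) as full-precision TSV."""
    if isinstance(obj, pd.Series):
        obj = obj.to_frame()
    if not isinstance(obj, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(obj).__name__} as a table")
    obj.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def load_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, **kwargs)


def write_gene_set(gene_ids: Iterable[str], path: str | Path) -> None:
    """One gene ID per line, with a header line."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id"])
        for g in gene_ids:
            writer.writerow([g])


def load_gene_set(path: str | Path) -> list[str]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or lines[0] != "gene_id":
        raise ValueError(f"{path} is not a gene-set file (missing 'gene_id' header)")
    return lines[1:]
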