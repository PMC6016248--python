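"""Tab-delimited I/O: OTU tables, sample sheets, distance matrices.

The OTU table dialect is rows = OTUs (first column ``otu_id``), one integer
column per sequenced pool.  The sample sheet pairs columns into sites:
``sample_id, ecosystem, intact_column, total_column, intact_copies,
total_copies``.  Everything is plain text with header rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bias_metrics import PairedSample
from .exceptions import FixtureParseError

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_paired_samples",
    "read_distance_matrix",
]

SHEET_COLUMNS = [
    "sample_id",
    "ecosystem",
    "intact_column",
    "total_column",
    "intact_copies",
    "total_copies",
]


def read_otu_table(path) -> pd.DataFrame:
    """Read an OTU-by-sample count table; rejects negative or fractional counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df[col][values.isna() | (values < 0) | (values % 1 != 0)]
        if len(bad):
            raise FixtureParseError(
                f"{path}: column '{col}', OTU '{bad.index[0]}': "
                f"count {bad.iloc[0]!r} is not a non-negative integer"
            )
    return df.astype(np.int64)


def write_otu_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="otu_id")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FixtureParseError(f"{path}: sample sheet is missing columns {missing}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_paired_samples(otu_table_path, sample_sheet_path) -> list[PairedSample]:
    """Assemble PairedSample records from an OTU table plus sample sheet."""
    table = read_otu_table(otu_table_path)
    sheet = read_sample_sheet(sample_sheet_path)
    samples = []
    for _, row in sheet.iterrows():
        for col_field in ("intact_column", "total_column"):
            if row[col_field] not in table.columns:
                raise FixtureParseError(
                    f"{sample_sheet_path}: sample '{row['sample_id']}' references "
                    f"missing OTU-table column '{row[col_field]}'"
                )
        samples.append(
            PairedSample(
                sample_id=str(row["sample_id"]),
                ecosystem=str(row["ecosystem"]),
                intact_counts=table[row["intact_column"]].to_numpy(),
                total_counts=table[row["total_column"]].to_numpy(),
                intact_copies=float(row["intact_copies"]),
                total_copies=float(row["total_copies"]),
            )
        )
    return samples


def read_distance_matrix(path) -> np.ndarray:
    """Square distance matrix with matching row/column labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FixtureParseError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float)
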