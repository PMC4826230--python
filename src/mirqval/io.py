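"""Tab-separated file conventions shared by all stages.

Every table is TSV with a header row; missing values are written as the
sentinel token ``NA``, never as an empty field.  Matrices are written with
assays as rows and samples as columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

NA_TOKEN = "NA"
SEP = "\t"

WELL_COLUMNS = ["sample_id", "assay_id", "replicate", "ct", "quality"]
ANNOTATION_COLUMNS = ["sample_id", "group", "kit", "plate"]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=SEP, na_rep=NA_TOKEN, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=SEP, na_values=[NA_TOKEN], keep_default_na=False, index_col=index_col
    )


def read_wells(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"well table {path} lacks columns {sorted(missing)}")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"annotation table {path} needs sample_id and group columns")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "assay_id"
    write_table(out, path, index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return read_table(path, index_col=0)
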