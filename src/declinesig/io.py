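"""Delimited-text readers and writers for every pipeline artifact.

Matrices are tab-separated with a header row of analyte ids (prefixed
``blood:`` / ``bal:`` once merged) and a first column of sample ids.  A
single comment line ``# scale=raw|log`` precedes the header so a matrix
round-trips with its scale flag.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import BAL, BLOOD, RAW, ConfigurationError, ProteomicMatrix
from .preprocess import LODSpec

SEP = "\t"


def write_matrix(matrix: ProteomicMatrix, path) -> None:
    path = Path(path)
    df = matrix.values.copy()
    tagged = []
    for col, comp in zip(df.columns, matrix.compartment):
        c = str(col)
        tagged.append(c if c.startswith(f"{comp}:") else f"{comp}:{c}")
    df.columns = tagged
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        df.to_csv(fh, sep=SEP, index_label="sample_id", float_format="%.17g")


def read_matrix(path) -> ProteomicMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        scale = RAW
        if first.startswith("#"):
            for token in first.lstrip("#").split():
                if token.startswith("scale="):
                    scale = token.split("=", 1)[1]
            df = pd.read_csv(fh, sep=SEP, index_col="sample_id", float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep=SEP, index_col="sample_id", float_precision="round_trip")
    comps = []
    cols = []
    for col in df.columns:
        c = str(col)
        if c.startswith(f"{BLOOD}:"):
            comps.append(BLOOD)
        elif c.startswith(f"{BAL}:"):
            comps.append(BAL)
        else:
            raise ConfigurationError(
                f"column {c!r} lacks a blood:/bal: compartment prefix"
            )
        cols.append(c)
    df.columns = cols
    return ProteomicMatrix(
        df, pd.Series(comps, index=df.columns, dtype=object), scale
    )


def write_participants(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep=SEP, index=False, float_format="%.17g")


def read_participants(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep=SEP, float_precision="round_trip")
    if "id" not in frame.columns:
        raise ConfigurationError("participant table needs an 'id' column")
    return frame.set_index("id", drop=False)


def write_lodspec(lod: LODSpec, path) -> None:
    lod.limits.to_csv(path, sep=SEP, index_label="analyte", float_format="%.17g")


def read_lodspec(path) -> LODSpec:
    return LODSpec(pd.read_csv(Path(path), sep=SEP, index_col="analyte", float_precision="round_trip"))


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep=SEP, index=index, float_format="%.17g")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep=SEP, index_col=index_col, float_precision="round_trip")


def write_series(series: pd.Series, path, index_label: str = "sample_id") -> None:
    series.to_csv(path, sep=SEP, index_label=index_label, header=True, float_format="%.17g")


def read_series(series_path, index_label: str = "sample_id") -> pd.Series:
    df = pd.read_csv(Path(series_path), sep=SEP, index_col=index_label, float_precision="round_trip")
    return df.iloc[:, 0]
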