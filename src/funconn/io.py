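"""TSV/JSON input and output for every pipeline artifact."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .graphs import BinaryGraph
from .stats import SubjectTable
from .timeseries import MotionParams, RoiTimeSeries

__all__ = [
    "read_timeseries",
    "read_motion",
    "read_subjects",
    "read_atlas",
    "read_confounds",
    "write_connectivity",
    "read_connectivity",
    "write_adjacency",
    "write_edge_list",
]


class ParseError(ValueError):
    """A malformed input file; the message names the file and the problem."""


def _read_tsv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{what} file is empty: {path}") from None
    except pd.errors.ParserError as e:
        raise ParseError(f"malformed {what} file {path}: {e}") from None
    if df.empty:
        raise ParseError(f"{what} file has a header but no rows: {path}")
    return df


def read_timeseries(
    path: str | Path, tr_seconds: float = 2.0, subject_id: str = ""
) -> RoiTimeSeries:
    """Read a T x N region time-series TSV (header = region names)."""
    df = _read_tsv(path, "time-series")
    bad = df.columns[~df.dtypes.apply(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ParseError(f"non-numeric column(s) {list(bad)} in {path}")
    return RoiTimeSeries(
        values=df.to_numpy(float),
        tr_seconds=tr_seconds,
        region_names=tuple(df.columns),
        subject_id=subject_id or Path(path).stem,
    )


def read_motion(path: str | Path, tr_seconds: float = 2.0) -> MotionParams:
    """Read a T x 6 rigid-body motion TSV (translations mm, rotations rad)."""
    df = _read_tsv(path, "motion")
    if df.shape[1] != 6:
        raise ParseError(f"motion file {path} must have 6 columns, found {df.shape[1]}")
    return MotionParams(values=df.to_numpy(float), tr_seconds=tr_seconds)


def read_confounds(path: str | Path) -> np.ndarray:
    """Read an arbitrary T x K confound TSV with header."""
    return _read_tsv(path, "confound").to_numpy(float)


def read_subjects(path: str | Path, patient_group: str = "IAD") -> SubjectTable:
    """Read the subject table (id, group, demographics, score columns)."""
    df = _read_tsv(path, "subject")
    if df["subject_id"].duplicated().any() if "subject_id" in df else False:
        raise ParseError(f"duplicate subject ids in {path}")
    return SubjectTable(df, patient_group=patient_group)


def read_atlas(path: str | Path) -> pd.DataFrame:
    """Read an atlas table (name, lobe, hemisphere, x, y, z)."""
    df = _read_tsv(path, "atlas")
    required = {"name", "lobe", "hemisphere", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"atlas {path} missing column(s): {sorted(missing)}")
    if df["name"].duplicated().any():
        dup = df["name"][df["name"].duplicated()].iloc[0]
        raise ParseError(f"duplicate region name {dup!r} in {path}")
    return df


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> None:
    """Write the square correlation matrix with region-name headers."""
    pd.DataFrame(
        conn.r_values, index=list(conn.region_names), columns=list(conn.region_names)
    ).to_csv(path, sep="\t", float_format="%.10g")


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    df = _read_tsv(path, "connectivity")
    df = df.set_index(df.columns[0])
    return ConnectivityMatrix(r_values=df.to_numpy(float), region_names=tuple(df.columns))


def write_adjacency(g: BinaryGraph, region_names, path: str | Path) -> None:
    pd.DataFrame(g.adjacency, index=list(region_names), columns=list(region_names)).to_csv(
        path, sep="\t"
    )


def write_edge_list(conn: ConnectivityMatrix, path: str | Path) -> None:
    """Write (region_a, region_b, r) rows for all unordered pairs."""
    iu = np.triu_indices(conn.n_regions, k=1)
    pd.DataFrame(
        {
            "region_a": [conn.region_names[i] for i in iu[0]],
            "region_b": [conn.region_names[j] for j in iu[1]],
            "r": conn.r_values[iu],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
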