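"""Reading and writing marker tables, curves and study results.

The input format is a delimited text table with a header, one numeric
marker column and one binary status column (0 = healthy, 1 = diseased).
Floats are serialized with 17 significant digits so that written files
round-trip exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .empirical import Sample

__all__ = [
    "read_marker_table",
    "write_marker_table",
    "sample_from_frame",
    "write_curve_csv",
    "format_float",
]

FLOAT_FMT = "%.17g"


def format_float(x: float) -> str:
    return FLOAT_FMT % x


def sample_from_frame(df: pd.DataFrame, value_col: str = "value", status_col: str = "status") -> Sample:
    """Split a tidy table into the two marker samples by disease status."""
    for col in (value_col, status_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}; available: {list(df.columns)}")
    values = pd.to_numeric(df[value_col], errors="coerce")
    bad = df.index[values.isna() | ~np.isfinite(values)].tolist()
    if bad:
        raise ValueError(f"non-numeric or missing marker values in rows {bad}")
    status = pd.to_numeric(df[status_col], errors="coerce")
    invalid = sorted(set(status.dropna().unique()) - {0, 1})
    if status.isna().any() or invalid:
        offending = invalid or df.loc[status.isna(), status_col].unique().tolist()
        raise ValueError(
            f"status column {status_col!r} must be binary 0/1; offending values: {offending}"
        )
    x = values[status == 0].to_numpy(dtype=float)
    y = values[status == 1].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("each status class (0 and 1) needs at least one row")
    return Sample(x, y)


def read_marker_table(
    path,
    value_col: str = "value",
    status_col: str = "status",
    delimiter: str = ",",
) -> Sample:
    """Read a delimited marker table and split it into the two groups.

    Row numbers in error messages refer to the file (header = row 1).
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    try:
        return sample_from_frame(df, value_col, status_col)
    except ValueError as err:
        # translate 0-based frame indices into 1-based file rows
        msg = str(err)
        raise ValueError(msg.replace("rows [", "file rows (header = row 1) [")) from None


def write_marker_table(
    sample: Sample,
    path,
    value_col: str = "value",
    status_col: str = "status",
    delimiter: str = ",",
) -> None:
    """Write a Sample back to a delimited table (healthy first, status 0/1)."""
    df = pd.DataFrame(
        {
            value_col: np.concatenate([sample.x, sample.y]),
            status_col: np.concatenate(
                [np.zeros(sample.n1, dtype=int), np.ones(sample.n2, dtype=int)]
            ),
        }
    )
    df.to_csv(path, sep=delimiter, index=False, float_format=FLOAT_FMT)


def write_curve_csv(path, grid, values, lower=None, upper=None) -> None:
    """Write a curve as CSV columns (t, roc_hat[, lower, upper])."""
    cols = {"t": np.asarray(grid, dtype=float), "roc_hat": np.asarray(values, dtype=float)}
    if lower is not None:
        cols["lower"] = np.asarray(lower, dtype=float)
    if upper is not None:
        cols["upper"] = np.asarray(upper, dtype=float)
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)
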