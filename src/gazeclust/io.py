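"""CSV interchange for gaze and selection datasets.

The two schemas are fixed: gaze files carry exactly the header
``subject,item,condition,t_ms,aoi`` and selection files
``subject,item,condition,chosen``, with conditions serialized as
OS1P/OS2P/TS2P and AOIs as negated/unmentioned/critical/elsewhere.  Readers
validate values and report the first offending data rows by line number
(header = line 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import AOI_LABELS, CHOICE_LABELS, CONDITIONS

GAZE_COLUMNS = ("subject", "item", "condition", "t_ms", "aoi")
SELECTION_COLUMNS = ("subject", "item", "condition", "chosen")


class SchemaError(ValueError):
    """A CSV file does not conform to the documented schema."""


def _check_columns(df: pd.DataFrame, expected: tuple[str, ...], path) -> None:
    if tuple(df.columns) != expected:
        raise SchemaError(
            f"{path}: expected columns {','.join(expected)}; got {','.join(map(str, df.columns))}"
        )


def _bad_rows(mask: np.ndarray, path, column: str, allowed) -> None:
    if mask.any():
        rows = (np.flatnonzero(mask)[:5] + 2).tolist()  # +2: header line + 1-based
        raise SchemaError(
            f"{path}: invalid {column} value(s) at row(s) {rows}; allowed: {list(allowed)}"
        )


def write_gaze_csv(gaze: pd.DataFrame, path) -> None:
    gaze.to_csv(path, index=False, columns=list(GAZE_COLUMNS))


def read_gaze_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, GAZE_COLUMNS, path)
    cond = pd.Categorical(df["condition"], categories=list(CONDITIONS))
    _bad_rows(cond.codes == -1, path, "condition", CONDITIONS)
    aoi = pd.Categorical(df["aoi"], categories=list(AOI_LABELS))
    _bad_rows(aoi.codes == -1, path, "aoi", AOI_LABELS)
    t = pd.to_numeric(df["t_ms"], errors="coerce")
    _bad_rows(t.isna().to_numpy(), path, "t_ms", "finite numbers")
    for col in ("subject", "item"):
        v = pd.to_numeric(df[col], errors="coerce")
        _bad_rows(v.isna().to_numpy(), path, col, "integers")
        df[col] = v.astype(np.int64)
    df["condition"] = cond
    df["aoi"] = aoi
    df["t_ms"] = t.astype(float)
    return df


def write_selections_csv(selections: pd.DataFrame, path) -> None:
    selections.to_csv(path, index=False, columns=list(SELECTION_COLUMNS))


def read_selections_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SELECTION_COLUMNS, path)
    cond = pd.Categorical(df["condition"], categories=list(CONDITIONS))
    _bad_rows(cond.codes == -1, path, "condition", CONDITIONS)
    chosen = pd.Categorical(df["chosen"], categories=list(CHOICE_LABELS))
    _bad_rows(chosen.codes == -1, path, "chosen", CHOICE_LABELS)
    for col in ("subject", "item"):
        v = pd.to_numeric(df[col], errors="coerce")
        _bad_rows(v.isna().to_numpy(), path, col, "integers")
        df[col] = v.astype(np.int64)
    df["condition"] = cond
    df["chosen"] = chosen
    return df
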