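"""Reading and writing the plain-text formats the package exchanges.

The canonical matrix layout is features-in-rows TSV: first column feature
ids, header row sample ids.  CSV is accepted by delimiter sniffing.  Lines
starting with ``#`` are comments; every file the package writes carries the
producing configuration hash in such a header line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "na")

__all__ = ["read_matrix", "write_matrix", "read_metadata",
           "read_annotations", "write_table", "config_hash"]


class ParseError(ValueError):
    pass


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved run configuration."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise ParseError(f"{path}: no data lines")


def read_matrix(path, missing_tokens=DEFAULT_MISSING_TOKENS,
                zeros_as_missing: bool = False,
                transpose: bool = False) -> OmicsMatrix:
    """Parse a features x samples matrix file into an :class:`OmicsMatrix`.

    Cells matching ``missing_tokens`` are masked; ``zeros_as_missing``
    additionally converts exact zeros (recorded in provenance);
    ``transpose`` reads a samples-in-rows file.  Ragged rows, duplicate ids
    and non-numeric cells raise :class:`ParseError` naming the offender.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str,
                     keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row ids {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate column ids {dupes}")
    vals = np.empty(df.shape, dtype=np.float64)
    tokens = set(missing_tokens)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col].to_numpy()):
            cell = cell.strip()
            if cell in tokens:
                vals[i, j] = np.nan
                continue
            try:
                vals[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{df.index[i]!r}, column {col!r}") from None
    if transpose:
        vals = vals.T
        feature_ids, sample_ids = list(df.columns), list(df.index)
    else:
        feature_ids, sample_ids = list(df.index), list(df.columns)
    data = OmicsMatrix(vals, feature_ids, sample_ids,
                       provenance=[f"read_matrix:{path.name}"])
    if zeros_as_missing:
        data = data.zeros_to_missing()
    return data


def write_table(df: pd.DataFrame, path, config: dict | None = None,
                index: bool = True, float_format: str | None = None) -> None:
    """Write a TSV with an optional ``# icitau-config: <hash>`` header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# icitau-config: {config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


def write_matrix(data: OmicsMatrix | pd.DataFrame, path,
                 config: dict | None = None) -> None:
    df = data.to_dataframe() if isinstance(data, OmicsMatrix) else data
    write_table(df, path, config=config)


def read_metadata(path) -> pd.Series:
    """Sample metadata TSV (sample_id, group) -> Series sample -> group."""
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns sample_id, group")
    ser = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="group")
    if ser.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids in metadata")
    return ser


def read_annotations(path) -> dict[str, set[str]]:
    """Annotation TSV (feature_id, label; one row per pair, one-to-many)."""
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns feature_id, label")
    out: dict[str, set[str]] = {}
    for fid, label in df.iloc[:, :2].itertuples(index=False):
        out.setdefault(str(fid), set()).add(str(label))
    return out
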