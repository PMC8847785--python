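"""Read, validate and write the tabular formats used throughout the pipeline.

The in-memory containers are deliberately plain:

* **ASV table** — :class:`pandas.DataFrame` of non-negative integer counts,
  rows = samples, columns = ASVs, both axes uniquely labelled.
* **Sample metadata** — :class:`pandas.DataFrame` indexed by ``sample_id``
  with columns ``population``, ``source`` (``field`` / ``common_garden``),
  ``timepoint`` (days in the common garden; ``NaN`` for field samples, which
  have no garden residence time) and ``tank`` (``NaN`` when not applicable).
* **Taxonomy** — :class:`pandas.DataFrame` indexed by ``asv_id`` with one
  column per rank (``domain`` … ``genus``); missing ranks are ``NaN``.

All on-disk formats are UTF-8 tab-separated text with a single header row.
Distance matrices use the labelled square-matrix dialect handled by
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import FormatError

SOURCES = ("field", "common_garden")
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

METADATA_REQUIRED = ("sample_id", "population", "source")
METADATA_OPTIONAL = ("timepoint", "tank")


# ---------------------------------------------------------------------------
# ASV table
# ---------------------------------------------------------------------------

def validate_asv_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an ASV count table (samples x ASVs) and return it.

    Raises
    ------
    FormatError
        On duplicate identifiers, negative / non-integer counts, or an
        empty table.
    """
    if not isinstance(table, pd.DataFrame):
        raise FormatError("ASV table must be a pandas DataFrame")
    if table.shape[0] < 1 or table.shape[1] < 1:
        raise FormatError("ASV table must have at least 1 sample and 1 ASV")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers: {dup}")
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate ASV identifiers: {dup}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("ASV table contains non-numeric values")
    if np.isnan(values.astype(float)).any():
        raise FormatError("ASV table contains missing values")
    if (values < 0).any():
        raise FormatError("ASV table contains negative counts")
    if not np.issubdtype(values.dtype, np.integer):
        if not np.array_equal(values, np.floor(values)):
            raise FormatError(
                "ASV table contains non-integer counts; relative abundances "
                "are rejected because presence is defined as count > 0"
            )
        table = table.astype(np.int64)
    return table


def read_asv_table(path, orientation: str = "samples_as_rows") -> pd.DataFrame:
    """Read a tab-separated count table into samples x ASVs orientation.

    Parameters
    ----------
    path : str or path-like
        TSV file with one header row and one leading ID column.
    orientation : {"samples_as_rows", "asvs_as_rows"}
        Layout of the file; the returned frame is always samples x ASVs.
    """
    if orientation not in ("samples_as_rows", "asvs_as_rows"):
        raise FormatError(f"unknown orientation: {orientation!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    body_ids = header[1:]
    if len(set(body_ids)) != len(body_ids):
        dup = sorted({c for c in body_ids if body_ids.count(c) > 1})
        raise FormatError(f"{path}: duplicate column identifiers: {dup}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.empty:
        raise FormatError(f"{path}: empty table")
    try:
        frame = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric count cell ({exc})") from exc
    if orientation == "asvs_as_rows":
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    frame.index.name = "sample_id"
    frame.columns.name = "asv_id"
    return validate_asv_table(frame)


def write_asv_table(table: pd.DataFrame, path, orientation: str = "samples_as_rows") -> None:
    """Write an ASV table as TSV (inverse of :func:`read_asv_table`)."""
    table = validate_asv_table(table)
    out = table if orientation == "samples_as_rows" else table.T
    label = "sample_id" if orientation == "samples_as_rows" else "asv_id"
    out = out.copy()
    out.index.name = label
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame indexed by sample_id.

    Enforces unique sample IDs, non-empty populations, known ``source``
    values, and the source/timepoint contract: field samples carry no
    timepoint (NaN sentinel), common-garden samples carry a timepoint >= 0.
    """
    meta = meta.copy()
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample_id in metadata: {dup}")
    for col in ("population", "source"):
        if col not in meta.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    if meta["population"].isna().any() or (meta["population"].astype(str) == "").any():
        raise FormatError("metadata contains empty population labels")
    bad = set(meta["source"]) - set(SOURCES)
    if bad:
        raise FormatError(f"unknown source value(s): {sorted(bad)}; expected {SOURCES}")
    if "timepoint" not in meta.columns:
        meta["timepoint"] = np.nan
    if "tank" not in meta.columns:
        meta["tank"] = np.nan
    meta["timepoint"] = pd.to_numeric(meta["timepoint"], errors="raise")
    field = meta["source"] == "field"
    # Field samples never have a garden residence time.
    meta.loc[field, "timepoint"] = np.nan
    garden = ~field
    if meta.loc[garden, "timepoint"].isna().any():
        missing = meta.index[garden & meta["timepoint"].isna()].tolist()
        raise FormatError(f"common_garden samples without timepoint: {missing}")
    if (meta.loc[garden, "timepoint"] < 0).any():
        raise FormatError("negative common_garden timepoint")
    meta["population"] = meta["population"].astype(str)
    return meta


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (QIIME2-style layout; extra columns ignored)."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in METADATA_REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    frame = frame.set_index("sample_id")
    frame.index = frame.index.astype(str)
    keep = [c for c in ("population", "source", "timepoint", "tank") if c in frame.columns]
    return validate_metadata(frame[keep])


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta = validate_metadata(meta)
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy(path) -> pd.DataFrame:
    """Read an ASV taxonomy TSV (asv_id + rank columns, any suffix missing)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "asv_id" not in frame.columns:
        raise FormatError(f"{path}: missing required column 'asv_id'")
    frame = frame.set_index("asv_id")
    if frame.index.duplicated().any():
        raise FormatError(f"{path}: duplicate asv_id in taxonomy")
    keep = [c for c in RANKS if c in frame.columns]
    if not keep:
        raise FormatError(f"{path}: no recognised rank columns {RANKS}")
    return frame[keep]


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.copy()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Distance matrices (labelled square TSV, lsmat dialect)
# ---------------------------------------------------------------------------

def read_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path), format="lsmat")


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    dist.write(str(path), format="lsmat")
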