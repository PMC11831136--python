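"""Tabular interfaces of the pipeline.

The quantification input is a wide table (one row per protein group, one
column per tissue section) as produced by DIA-NN post-processing.  Column
names carry a quantity-block prefix (``PG.Quant`` by default) plus tokens
encoding the biological replicate and the slice index, e.g.
``PG.Quant_S1_slice7``.  Both tokens are extracted with configurable regular
expressions so other naming schemes can be accommodated.

Annotations are kept in a plain :class:`pandas.DataFrame` indexed by sample
id with columns

``replicate``
    label of the biological replicate (one sectioned tissue).
``slice``
    integer index of the section along the cutting axis.
``total_intensity``
    sum of raw intensities in the sample (missing treated as 0).
``is_control``
    True for QC wells (cell-lysate controls, blanks) that must not enter
    normalization.

The network edge list is written in the exact shape Cytoscape's table import
expects: a leading unnamed row-identifier column (``source-target``),
unquoted values, columns ``source,target,delay,corr,delay_inv``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

#: second "_"-separated token is the replicate label
DEFAULT_REPLICATE_REGEX = r"^[^_]+_([^_]+)"
#: trailing "slice<k>" token is the slice index
DEFAULT_SLICE_REGEX = r"slice(\d+)\s*$"

EDGE_COLUMNS = ["source", "target", "delay", "corr", "delay_inv"]

ANNOTATION_COLUMNS = ["replicate", "slice", "total_intensity", "is_control"]


def parse_sample_name(
    name: str,
    replicate_regex: str = DEFAULT_REPLICATE_REGEX,
    slice_regex: str = DEFAULT_SLICE_REGEX,
) -> tuple[str, int]:
    """Extract (replicate, slice) from a sample column name.

    Raises :class:`ParseError` naming the column when either token is
    missing or the slice token is non-numeric.
    """
    m = re.search(replicate_regex, name)
    if m is None or not m.groups() or m.group(1) == "":
        raise ParseError(f"cannot parse replicate from column {name!r}")
    replicate = m.group(1)
    s = re.search(slice_regex, name)
    if s is None:
        raise ParseError(f"cannot parse a numeric slice index from column {name!r}")
    try:
        slice_idx = int(s.group(1))
    except (TypeError, ValueError) as exc:  # non-numeric capture group
        raise ParseError(f"slice token of column {name!r} is non-numeric") from exc
    return replicate, slice_idx


def _read_wide(path: Path, sheet=0, sep: Optional[str] = None) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        return pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    if sep is None:
        sep = "\t" if suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_quant_table(
    path,
    block: str = "PG.Quant",
    protein_col: str = "Protein.Group",
    replicate_regex: str = DEFAULT_REPLICATE_REGEX,
    slice_regex: str = DEFAULT_SLICE_REGEX,
    control_regex: Optional[str] = None,
    sheet=0,
    sep: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a wide quantification table and its per-sample annotations.

    Parameters
    ----------
    path
        Delimited text (csv/tsv) or xlsx file.
    block
        Quantity block to extract: columns whose first ``_``-separated token
        equals this value.  The table may also carry ``GENES``, ``MaxLFQ``,
        ``PG.Norm`` ... blocks; only the selected block is returned.
    control_regex
        Samples whose name matches are flagged ``is_control`` (QC lysate
        wells, blanks) and later excluded from normalization.

    Returns
    -------
    values, annotations
        ``values`` is proteins x samples with NaN for missing cells, columns
        sorted by (replicate, slice); ``annotations`` is indexed by sample id
        in the same order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_wide(path, sheet=sheet, sep=sep)
    if protein_col not in raw.columns:
        raise FormatError(f"missing protein identifier column {protein_col!r}")
    prefix = raw.columns.to_series().astype(str).str.split("_").str[0]
    sample_cols = [c for c, p in zip(raw.columns, prefix) if p == block]
    if not sample_cols:
        raise FormatError(f"no columns of quantity block {block!r} found")

    protein_ids = raw[protein_col].astype(str)
    if protein_ids.duplicated().any():
        dup = protein_ids[protein_ids.duplicated()].iloc[0]
        raise ValidationError(f"duplicate protein id {dup!r}")

    values = raw[sample_cols].apply(pd.to_numeric, errors="coerce")
    values.index = protein_ids.to_numpy()
    values.index.name = "protein"

    records = []
    for col in sample_cols:
        replicate, slice_idx = parse_sample_name(col, replicate_regex, slice_regex)
        is_control = bool(control_regex and re.search(control_regex, col))
        records.append((col, replicate, slice_idx, is_control))
    ann = pd.DataFrame(
        records, columns=["sample_id", "replicate", "slice", "is_control"]
    ).set_index("sample_id")
    dup = ann[~ann.is_control].duplicated(subset=["replicate", "slice"])
    if dup.any():
        r, s = ann.loc[dup[dup].index[0], ["replicate", "slice"]]
        raise ValidationError(f"duplicate (replicate, slice) = ({r!r}, {s})")

    order = ann.sort_values(["replicate", "slice"], kind="stable").index
    ann = ann.loc[order]
    values = values[order]

    neg = values.to_numpy()
    if np.nanmin(neg, initial=0.0) < 0:
        raise ValidationError("negative raw intensities encountered")
    ann["total_intensity"] = values.fillna(0.0).sum(axis=0)
    ann = ann[ANNOTATION_COLUMNS]
    return values, ann


def write_quant_table(values: pd.DataFrame, path, protein_col: str = "Protein.Group") -> None:
    """Write a wide matrix back to csv/tsv (inverse of :func:`read_quant_table`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out = values.copy()
    out.insert(0, protein_col, out.index)
    out.to_csv(path, sep=sep, index=False)


def validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Check the edge-record invariants and return a normalized frame."""
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValidationError(f"edge table lacks columns {missing}")
    edges = edges[EDGE_COLUMNS].copy()
    if len(edges):
        delay = edges["delay"].to_numpy()
        if (delay < 0).any():
            raise ValidationError("edge delays must be >= 0")
        expected = 1.0 / (delay + 1.0)
        if not np.allclose(edges["delay_inv"], expected, rtol=0, atol=0):
            raise ValidationError("delay_inv must equal 1/(delay+1) exactly")
        corr = edges["corr"].to_numpy(dtype=float)
        if np.nanmax(np.abs(corr)) > 1 + 1e-12:
            raise ValidationError("correlations must lie in [-1, 1]")
    return edges


def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Write the directed edge list as an unquoted CSV for Cytoscape.

    The first column is the row identifier ``source-target`` under an empty
    header field, matching R's ``write.csv(..., quote=FALSE)`` layout.
    """
    edges = validate_edges(edges)
    out = edges.copy()
    out.index = out["source"].astype(str) + "-" + out["target"].astype(str)
    out.to_csv(path, index=True, index_label="", quoting=3)  # csv.QUOTE_NONE


def read_edge_list(path) -> pd.DataFrame:
    """Read an edge-list CSV written by :func:`write_edge_list`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.empty and not all(c in df.columns for c in EDGE_COLUMNS):
        return pd.DataFrame(columns=EDGE_COLUMNS)
    return validate_edges(df.reset_index(drop=True))
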