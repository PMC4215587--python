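"""Tabular I/O for the three tables every stage exchanges.

Conventions (fixed across the package):

* Expression matrices are probes x samples, log2 intensity scale, stored as a
  :class:`pandas.DataFrame` whose index holds probe ids and whose columns hold
  sample ids.  The first header field of the TSV is ``probe_id``.
* Probe annotation is a DataFrame with columns ``probe_id``, ``symbol``,
  ``description`` (``probe_id`` unique).
* Clinical tables carry one row per sample with distant-metastasis-free
  survival (``time`` in months, ``event`` 0/1) plus receptor status and the
  usual prognostic covariates.  ``NA`` / empty tokens map to missing values.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, FormatError, ValidationError

CLINICAL_COLUMNS = [
    "sample_id",
    "time",
    "event",
    "er_status",
    "erbb2_status",
    "pgr_status",
    "age",
    "size",
    "grade",
]

_STATUS_TOKENS = {"pos", "neg"}
_NA_TOKENS = {"", "NA", "na", "NaN", "nan", None}


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path, values_scale: str = "log2", offset: float = 1.0) -> pd.DataFrame:
    """Read a probes x samples expression TSV.

    ``values_scale='linear'`` applies ``log2(x + offset)`` so zero intensities
    stay finite; ``'log2'`` inputs are taken as-is and round-trip bit-exactly
    with :func:`write_expression_tsv`.
    """
    if values_scale not in ("log2", "linear"):
        raise FormatError(f"values_scale must be 'log2' or 'linear', got {values_scale!r}")
    if values_scale == "linear" and offset <= 0:
        raise FormatError("offset must be positive for linear-scale input")
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"{path}: duplicated sample ids in header: {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no sample columns")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in column {col!r}") from exc
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns)
    out.index.name = "probe_id"
    if np.isnan(out.values).any():
        bad = out.index[np.isnan(out.values).any(axis=1)][:5].tolist()
        raise FormatError(f"{path}: missing expression values (e.g. probes {bad})")
    if values_scale == "linear":
        if (out.values + offset <= 0).any():
            raise FormatError(f"{path}: linear values <= -offset cannot be log2 transformed")
        out = np.log2(out + offset)
    return out


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix = matrix.copy()
    matrix.index.name = "probe_id"
    matrix.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def read_annotation_tsv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "symbol", "description"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required annotation column {col!r}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise FormatError(f"{path}: duplicated probe_id rows: {dups}")
    return df[["probe_id", "symbol", "description"]].reset_index(drop=True)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def select_phosphatase_probes(annotation: pd.DataFrame, keyword: str = "phosphatase") -> list[str]:
    """Probe ids whose description contains *keyword* (case-insensitive substring).

    This is how the phosphatome universe is defined: every probe whose
    description field mentions the keyword, in annotation order.
    """
    if not keyword:
        raise ValidationError("keyword must be non-empty")
    mask = annotation["description"].str.contains(re.escape(keyword), case=False, na=False)
    return annotation.loc[mask, "probe_id"].tolist()


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def _parse_status(token, path, col):
    if token in _NA_TOKENS or (isinstance(token, float) and math.isnan(token)):
        return None
    t = str(token).strip().lower()
    aliases = {"positive": "pos", "+": "pos", "1": "pos", "negative": "neg", "-": "neg", "0": "neg"}
    t = aliases.get(t, t)
    if t not in _STATUS_TOKENS:
        raise ValidationError(f"{path}: bad {col} token {token!r}")
    return t


def _parse_grade(token, path):
    if token in _NA_TOKENS or (isinstance(token, float) and math.isnan(token)):
        return None
    t = str(token).strip().upper()
    t = t[1:] if t.startswith("G") else t  # pathology reports write G1/G2/G3
    try:
        g = int(float(t))
    except ValueError as exc:
        raise ValidationError(f"{path}: bad grade token {token!r}") from exc
    if g not in (1, 2, 3):
        raise ValidationError(f"{path}: grade must be 1, 2 or 3, got {token!r}")
    return g


def read_clinical_tsv(path) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "time", "event"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing required clinical columns {sorted(missing)}")
    if raw["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample ids")
    out = pd.DataFrame({"sample_id": raw["sample_id"].astype(str)})
    out["time"] = pd.to_numeric(raw["time"], errors="coerce")
    out["event"] = pd.to_numeric(raw["event"], errors="coerce")
    if out["time"].isna().any():
        raise ValidationError(f"{path}: non-numeric or missing time values")
    if (out["time"] < 0).any():
        raise ValidationError(f"{path}: negative survival times")
    if not out["event"].isin([0, 1]).all():
        raise ValidationError(f"{path}: event must be 0 or 1")
    out["event"] = out["event"].astype(int)
    for col in ("er_status", "erbb2_status", "pgr_status"):
        if col in raw.columns:
            out[col] = [_parse_status(t, path, col) for t in raw[col]]
        else:
            out[col] = None
    for col in ("age", "size"):
        if col in raw.columns:
            out[col] = pd.to_numeric(raw[col].replace(list(_NA_TOKENS), np.nan), errors="coerce")
        else:
            out[col] = np.nan
    out["grade"] = [_parse_grade(t, path) for t in raw["grade"]] if "grade" in raw.columns else None
    # preserve any extra columns (e.g. the simulator's group labels)
    for col in raw.columns:
        if col not in out.columns:
            out[col] = raw[col]
    return out


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

def zscore_by_probe(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize every probe row to mean 0, sd 1 (sample sd, ddof=1).

    Each dataset is z-scored independently before signature training or
    projection; training statistics are never carried over to a test set.
    """
    values = matrix.values.astype(float)
    sd = values.std(axis=1, ddof=ddof)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        names = matrix.index[bad].tolist()[:10]
        raise DegenerateDataError(f"constant probe rows cannot be z-scored: {names}")
    centered = values - values.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered / sd[:, None], index=matrix.index, columns=matrix.columns)
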