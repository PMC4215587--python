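"""Array preprocessing: quantile normalization, background filtering, replicate summarization.

The stages mirror standard microarray practice: bring every array onto a
common intensity distribution, drop probes that are not detected above
background in enough arrays, and collapse probes spotted multiple times on
the chip to a single row.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean-of-sorted-columns distribution.

    After normalization each column's sorted values equal the across-column
    mean of sorted values.  Ties within a column receive the mean of the
    reference values at their tied ranks, so tied inputs stay tied and the
    transform is idempotent.
    """
    values = matrix.values.astype(float)
    if np.isnan(values).any():
        raise ValidationError("quantile normalization requires a complete matrix")
    if values.shape[1] < 2:
        raise ValidationError("need at least 2 samples to quantile normalize")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average reference values across tied input values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").values
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_above_background(
    matrix: pd.DataFrame, flags: pd.DataFrame, min_fraction: float = 0.75
) -> pd.DataFrame:
    """Keep probes flagged "well above background" in >= min_fraction of samples.

    ``flags`` is a boolean probe x sample matrix aligned with ``matrix``; the
    default 0.75 fraction is configurable because detection-call defaults vary
    between feature-extraction pipelines.
    """
    if not 0 < min_fraction <= 1:
        raise ValidationError("min_fraction must be in (0, 1]")
    if flags.shape != matrix.shape or not flags.index.equals(matrix.index) or not flags.columns.equals(matrix.columns):
        raise ValidationError("detection flags must share the matrix's probes and samples")
    frac = flags.values.astype(bool).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        log.warning("background filter removed every probe (min_fraction=%s)", min_fraction)
    return matrix.loc[keep]


def summarize_replicate_probes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a probe_id to their per-sample median.

    Unique probes pass through unchanged; output keeps first-occurrence order.
    """
    if not matrix.index.duplicated().any():
        return matrix
    first_order = matrix.index[~matrix.index.duplicated()]
    collapsed = matrix.groupby(level=0, sort=False).median()
    return collapsed.loc[first_order]
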