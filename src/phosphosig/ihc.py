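"""Immunohistochemistry scoring arithmetic and categorical statistics.

Staining is scored semiquantitatively: intensity on a 0-3 scale and the
percentage of tumor cells stained.  The categorical score uses a 4-tiered
percentage scale (<5% -> 0, 5-33% -> 1, 34-66% -> 2, >66% -> 3); the
continuous score is intensity x percentage (range 0-300).  Marker-specific
dichotomization feeds 2x2 contingency tables tested by Fisher's exact test;
continuous scores are compared by Spearman rank correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError

# marker -> lowest categorical score that counts as "high"
DICHOTOMIZATION_RULES = {"DUSP6": 1, "pERK": 1, "DUSP4": 2}


@dataclass(frozen=True)
class IHCScore:
    marker: str
    intensity: int
    pct_cells: float
    categorical: int
    continuous: float


def score_ihc(intensity: int, pct_cells: float, marker: str = "") -> IHCScore:
    """Categorical tier from the stained-cell percentage + continuous product."""
    if intensity not in (0, 1, 2, 3):
        raise ValidationError(f"intensity must be 0..3, got {intensity!r}")
    if not 0 <= pct_cells <= 100:
        raise ValidationError(f"pct_cells must be in [0, 100], got {pct_cells!r}")
    if pct_cells < 5:
        categorical = 0
    elif pct_cells <= 33:
        categorical = 1
    elif pct_cells <= 66:
        categorical = 2
    else:
        categorical = 3
    return IHCScore(
        marker=marker,
        intensity=int(intensity),
        pct_cells=float(pct_cells),
        categorical=categorical,
        continuous=float(intensity) * float(pct_cells),
    )


def dichotomize_marker(categorical_scores, marker: str, high_from: int | None = None):
    """Map categorical scores to low/high using the marker's published cutoff.

    DUSP6 and phospho-ERK split at 0 vs 1-3; DUSP4 splits at 0-1 vs >=2.
    Unknown markers need an explicit ``high_from`` cutoff.
    """
    if high_from is None:
        if marker not in DICHOTOMIZATION_RULES:
            raise ValidationError(
                f"no dichotomization rule for marker {marker!r}; pass high_from"
            )
        high_from = DICHOTOMIZATION_RULES[marker]
    out = []
    for c in categorical_scores:
        if c not in (0, 1, 2, 3):
            raise ValidationError(f"categorical score must be 0..3, got {c!r}")
        out.append("high" if c >= high_from else "low")
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of all fixed-margin tables no more likely
    than the observed one."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("contingency table must be 2x2 with non-negative counts")
    if t.sum() == 0:
        raise ValidationError("empty contingency table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0  # an empty margin carries no information
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def spearman_correlation(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rho on mid-ranks with a two-tailed p-value.

    ``method='t'`` uses the t-distribution approximation (the default of
    common statistical software); ``method='exact'`` enumerates all rank
    permutations (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need two equal-length vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateDataError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    if method == "t":
        return float(rho), float(p)
    if method != "exact":
        raise ValidationError("method must be 't' or 'exact'")
    n = len(x)
    if n > 10:
        raise ValidationError("exact permutation p limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return float(rho), count / total
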