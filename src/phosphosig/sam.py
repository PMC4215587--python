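"""Two-class SAM: moderated d-statistic, fudge factor s0, permutation FDR.

Significance Analysis of Microarrays screens probes with

    d_i = (mean_A,i - mean_B,i) / (s_i + s0)

where s_i is the classical pooled standard error and s0 is a small constant
("fudge factor") chosen so the spread of d does not depend on s, stabilizing
low-variance probes.  False-discovery rates come from label permutations:
for each cutoff on |d| the expected number of permuted statistics beyond the
cutoff, scaled by an estimate of the null proportion pi0, is compared with
the observed count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

_PI0_FLOOR = 0.1  # avoid q collapse on tiny fixtures


@dataclass(frozen=True)
class SamConfig:
    """Knobs of a SAM run (permutation count, seed, FDR cutoff, s0 handling)."""

    n_permutations: int = 200
    seed: int = 0
    q_threshold: float = 0.05
    s0_method: str = "tusher"  # or "fixed"
    s0_value: float | None = None

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not 0 < self.q_threshold < 1:
            raise ConfigurationError("q_threshold must be in (0, 1)")
        if self.s0_method not in ("tusher", "fixed"):
            raise ConfigurationError("s0_method must be 'tusher' or 'fixed'")
        if self.s0_method == "fixed" and (self.s0_value is None or self.s0_value < 0):
            raise ConfigurationError("fixed s0 requires a non-negative s0_value")


@dataclass
class SamResult:
    """Per-probe SAM statistics plus the global s0 and pi0 estimates."""

    table: pd.DataFrame  # columns: d, numerator, s, fold_change, q
    s0: float
    pi0: float
    config: SamConfig = field(default=None, repr=False)


def _split_groups(matrix: pd.DataFrame, labels, numerator: str | None = None):
    labels = pd.Series(labels)
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValidationError("labels must cover every sample column")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups required, got {groups}")
    if numerator is None:
        numerator = groups[0]
    elif numerator not in groups:
        raise ValidationError(f"numerator group {numerator!r} not among {groups}")
    denominator = groups[0] if groups[1] == numerator else groups[1]
    idx_a = np.flatnonzero((labels == numerator).values)
    idx_b = np.flatnonzero((labels == denominator).values)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError("both groups need at least 2 samples")
    return idx_a, idx_b


def _d_components(values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    """Numerator and Tusher pooled standard error for one group split."""
    na, nb = len(idx_a), len(idx_b)
    a = values[:, idx_a]
    b = values[:, idx_b]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ss_a + ss_b) / (na + nb - 2))
    return mean_a - mean_b, s


def sam_statistic(matrix: pd.DataFrame, labels, s0: float, numerator: str | None = None) -> pd.DataFrame:
    """Per-probe (d, numerator, s) with the given fudge factor."""
    if s0 < 0:
        raise ValidationError("s0 must be >= 0")
    idx_a, idx_b = _split_groups(matrix, labels, numerator)
    num, s = _d_components(matrix.values.astype(float), idx_a, idx_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / (s + s0)
    d = np.where(num == 0, 0.0, d)  # 0/0 -> 0
    return pd.DataFrame({"d": d, "numerator": num, "s": s}, index=matrix.index)


def estimate_s0(numerators: np.ndarray, s_values: np.ndarray, n_windows: int = 100) -> float:
    """Tusher fudge-factor search.

    Candidates are the 0,5,...,100th percentiles of s.  For each candidate
    the probes are split into s-quantile windows; the dispersion (median
    absolute deviation) of d within each window is computed, and the
    candidate minimizing the coefficient of variation of those window MADs
    wins.  Deterministic; ties go to the smallest candidate.
    """
    numerators = np.asarray(numerators, dtype=float)
    s_values = np.asarray(s_values, dtype=float)
    if numerators.shape != s_values.shape or numerators.ndim != 1:
        raise ValidationError("numerators and s_values must be equal-length vectors")
    p = len(s_values)
    if p < 10:
        raise ValidationError("s0 estimation needs at least 10 probes")
    if np.allclose(s_values, s_values[0]):
        return 0.0
    candidates = np.unique(np.percentile(s_values, np.arange(0, 101, 5)))
    n_win = min(n_windows, max(2, p // 10))
    edges = np.quantile(s_values, np.linspace(0, 1, n_win + 1))
    window = np.clip(np.searchsorted(edges, s_values, side="right") - 1, 0, n_win - 1)
    best_s0, best_cv = None, None
    for s0 in candidates:
        d = numerators / (s_values + s0)
        mads = np.array([
            np.median(np.abs(d[window == w] - np.median(d[window == w])))
            for w in range(n_win)
            if np.any(window == w)
        ])
        mean = mads.mean()
        if mean == 0:
            cv = 0.0
        else:
            cv = mads.std(ddof=1) / mean
        if best_cv is None or cv < best_cv - 1e-12:
            best_s0, best_cv = float(s0), cv
    return best_s0


def fold_change(matrix_log2: pd.DataFrame, labels, numerator: str | None = None) -> pd.Series:
    """Linear fold change 2^(mean_A - mean_B); values < 1 mean higher in B."""
    idx_a, idx_b = _split_groups(matrix_log2, labels, numerator)
    num, _ = _d_components(matrix_log2.values.astype(float), idx_a, idx_b)
    return pd.Series(2.0 ** num, index=matrix_log2.index, name="fold_change")


def _permutation_indices(n: int, na: int, n_permutations: int, rng: np.random.Generator):
    """Group-A index sets for each permutation; exhaustive when feasible."""
    total = math.comb(n, na)
    if total <= n_permutations:
        return [np.array(c) for c in itertools.combinations(range(n), na)]
    perms = []
    for _ in range(n_permutations):
        perms.append(rng.permutation(n)[:na])
    return perms


def sam_permutation_fdr(matrix: pd.DataFrame, labels, config: SamConfig, numerator: str | None = None) -> SamResult:
    """Full SAM run: d, s0, fold change and permutation q-values.

    q_i is the smallest estimated FDR over all |d| cutoffs at which probe i
    would be called, with FDR(c) = pi0 * mean_perm #{|d*| >= c} / #{|d| >= c};
    this makes q monotone non-increasing in the |d| ranking by construction.
    """
    idx_a, idx_b = _split_groups(matrix, labels, numerator)
    values = matrix.values.astype(float)
    num, s = _d_components(values, idx_a, idx_b)

    if config.s0_method == "fixed":
        s0 = float(config.s0_value)
    else:
        s0 = estimate_s0(num, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / (s + s0)
    d = np.where(num == 0, 0.0, d)

    n = values.shape[1]
    na = len(idx_a)
    rng = np.random.default_rng(config.seed)
    perms = _permutation_indices(n, na, config.n_permutations, rng)
    n_perm = len(perms)

    all_idx = np.arange(n)
    d_perm = np.empty((values.shape[0], n_perm))
    for k, pa in enumerate(perms):
        pb = np.setdiff1d(all_idx, pa, assume_unique=False)
        pn, ps = _d_components(values, pa, pb)
        with np.errstate(divide="ignore", invalid="ignore"):
            dk = pn / (ps + s0)
        d_perm[:, k] = np.where(pn == 0, 0.0, dk)

    # pi0 from the share of observed d inside the permutation interquartile range
    q25, q75 = np.percentile(d_perm, [25, 75])
    pi0 = float(np.clip(np.mean((d >= q25) & (d <= q75)) / 0.5, _PI0_FLOOR, 1.0))

    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")  # descending |d|
    cutoffs = abs_d[order]
    perm_abs_sorted = np.sort(np.abs(d_perm).ravel())
    # mean over permutations of #{|d*| >= cutoff}
    exceed = (len(perm_abs_sorted) - np.searchsorted(perm_abs_sorted, cutoffs, side="left")) / n_perm
    observed = np.arange(1, len(cutoffs) + 1)  # #{|d| >= cutoff} in rank order
    fdr = np.clip(pi0 * exceed / observed, 0.0, 1.0)
    # a probe is called at every cutoff below its |d|: take the suffix minimum
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    fc = 2.0 ** num
    table = pd.DataFrame(
        {"d": d, "numerator": num, "s": s, "fold_change": fc, "q": q},
        index=matrix.index,
    )
    return SamResult(table=table, s0=s0, pi0=pi0, config=config)


def significant_table(result: SamResult, annotation: pd.DataFrame, q_threshold: float | None = None) -> pd.DataFrame:
    """Significant probes annotated with gene symbols, sorted by descending fold change.

    The returned frame carries ``probe_count`` and ``gene_count`` attrs
    (probes can share a symbol, so the two differ in general).
    """
    if q_threshold is None:
        q_threshold = result.config.q_threshold if result.config else 0.05
    table = result.table[result.table["q"] < q_threshold].copy()
    symbols = annotation.set_index("probe_id")["symbol"] if len(annotation) else pd.Series(dtype=str)
    table.insert(0, "symbol", table.index.map(symbols))
    table = table.sort_values("fold_change", ascending=False)
    table.attrs["probe_count"] = len(table)
    table.attrs["gene_count"] = int(table["symbol"].dropna().nunique())
    return table


def intersect_series(tables: list[pd.DataFrame], key: str = "symbol") -> pd.DataFrame:
    """Identifiers significant in every series with a consistent direction.

    Direction is taken from the fold change (>1 vs <1); an identifier up in
    one series and down in another is excluded.  Rows come from the first
    table, with a ``direction`` column attached.
    """
    if len(tables) < 2:
        raise ValidationError("need at least two significance tables to intersect")

    def directions(tbl):
        ids = tbl[key] if key in tbl.columns else tbl.index.to_series()
        out = {}
        for ident, fc in zip(ids, tbl["fold_change"]):
            if fc == 1 or pd.isna(ident):
                continue
            direction = "up in A" if fc > 1 else "up in B"
            if out.setdefault(ident, direction) != direction:
                out[ident] = None  # internally discordant within one series
        return {k: v for k, v in out.items() if v is not None}

    maps = [directions(t) for t in tables]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    consistent = {i for i in common if len({m[i] for m in maps}) == 1}
    first = tables[0]
    ids = first[key] if key in first.columns else first.index.to_series()
    mask = ids.isin(consistent).values
    out = first.loc[mask].copy()
    out_ids = ids[mask]
    out["direction"] = [maps[0][i] for i in out_ids]
    return out
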