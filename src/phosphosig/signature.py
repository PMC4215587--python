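"""Supervised-principal-component survival signature.

The method: screen each probe by a univariate Cox proportional-hazards fit
of distant-metastasis-free survival on its z-scored expression; keep probes
whose selection score clears a threshold (chosen by cross-validation); take
the thin SVD of the selected probes-x-patients matrix

    X = U . diag(D) . V^T        so that     V = X^T . U . diag(D)^-1 ,

fit a Cox model on the first three columns of V (the leading component
scores), and combine them with the fitted coefficients into a per-patient
risk index

    I_j = beta_1 V_j1 + beta_2 V_j2 + beta_3 V_j3 .

Higher index means higher hazard of distant metastasis.  A validation
cohort is projected through the *training* U and D and scored with the
training betas; its own quintiles then define the risk groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .errors import ConvergenceError, DegenerateDataError, ValidationError

LOWER_3_QUINTILES = "lower_3_quintiles"
UPPER_2_QUINTILES = "upper_2_quintiles"
BELOW_MEDIAN = "below_median"
ABOVE_MEDIAN = "above_median"


# ---------------------------------------------------------------------------
# univariate Cox screen (vectorized Newton with Efron tie handling)
# ---------------------------------------------------------------------------

def _check_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape or time.ndim != 1:
        raise ValidationError("time and event must be equal-length vectors")
    if (time < 0).any():
        raise ValidationError("survival times must be >= 0")
    if not np.isin(event, [0, 1]).all():
        raise ValidationError("event flags must be 0/1")
    return time, event.astype(int)


def _efron_grad_hess(X, w, order, groups):
    """Per-probe gradient and (negative) Hessian of the Efron partial log-lik.

    X, w: probes x samples arrays (w = exp(beta*x)); ``order`` sorts samples
    by time descending so suffix sums become prefix sums; ``groups`` lists,
    per unique event time, (risk_start, event_indices) in the sorted frame.
    """
    Xo = X[:, order]
    wo = w[:, order]
    wx = wo * Xo
    wxx = wx * Xo
    cw = np.cumsum(wo, axis=1)
    cwx = np.cumsum(wx, axis=1)
    cwxx = np.cumsum(wxx, axis=1)
    grad = np.zeros(X.shape[0])
    hess = np.zeros(X.shape[0])
    for risk_end, ev_idx in groups:
        d = len(ev_idx)
        W = cw[:, risk_end]
        S1 = cwx[:, risk_end]
        S2 = cwxx[:, risk_end]
        Wd = wo[:, ev_idx].sum(axis=1)
        S1d = wx[:, ev_idx].sum(axis=1)
        S2d = wxx[:, ev_idx].sum(axis=1)
        grad += Xo[:, ev_idx].sum(axis=1)
        for l in range(d):
            f = l / d
            denom = W - f * Wd
            num1 = S1 - f * S1d
            num2 = S2 - f * S2d
            grad -= num1 / denom
            hess += num2 / denom - (num1 / denom) ** 2
    return grad, hess


def _efron_groups(time, event):
    order = np.argsort(-time, kind="stable")  # descending time
    t_sorted = time[order]
    groups = []
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        ev_idx = [k for k in range(i, j + 1) if event[order[k]] == 1]
        if ev_idx:
            groups.append((j, np.asarray(ev_idx)))
        i = j + 1
    return order, groups


def univariate_cox_screen(
    X: pd.DataFrame,
    time,
    event,
    score_type: str = "coef",
    max_iter: int = 40,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """One single-covariate Cox fit per probe (Efron ties), all probes at once.

    Returns a frame with ``coef`` (log hazard per unit of z-scored
    expression), ``se``, ``score`` and a ``converged`` flag.  ``score`` is
    the selection statistic: the raw coefficient by default, or the
    standardized Wald statistic coef/se with ``score_type='standardized'``.
    """
    if score_type not in ("coef", "standardized"):
        raise ValidationError("score_type must be 'coef' or 'standardized'")
    time, event = _check_survival(time, event)
    if event.sum() == 0:
        raise ValidationError("no events: univariate Cox screen undefined")
    values = X.values.astype(float)
    if values.shape[1] != len(time):
        raise ValidationError("expression columns must match survival length")
    order, groups = _efron_groups(time, event)

    p = values.shape[0]
    beta = np.zeros(p)
    converged = np.zeros(p, dtype=bool)
    hess = np.full(p, np.nan)
    for _ in range(max_iter):
        w = np.exp(np.clip(beta[:, None] * values, -700, 700))
        grad, hess = _efron_grad_hess(values, w, order, groups)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = grad / hess
        step = np.where(np.isfinite(step), step, 0.0)
        step = np.clip(step, -2.0, 2.0)  # damp early overshoot
        active = ~converged
        beta[active] += step[active]
        converged |= np.abs(grad) < tol
        if converged.all():
            break
    ok = converged & np.isfinite(beta) & (hess > 0) & (np.abs(beta) < 50)
    se = np.full(p, np.nan)
    se[ok] = 1.0 / np.sqrt(hess[ok])
    coef = np.where(ok, beta, np.nan)
    if score_type == "coef":
        score = coef
    else:
        score = coef / se
    return pd.DataFrame(
        {"coef": coef, "se": se, "score": score, "converged": ok}, index=X.index
    )


def select_features(screen: pd.DataFrame, threshold: float) -> list[str]:
    """Probes with |score| >= threshold, descending |score| order (inclusive cut)."""
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    ok = screen[screen["converged"].astype(bool)].copy()
    ok = ok[ok["score"].abs() >= threshold]
    if ok.empty:
        raise ValidationError(
            f"no probe reaches |score| >= {threshold}; lower the threshold"
        )
    return ok.reindex(ok["score"].abs().sort_values(ascending=False).index).index.tolist()


# ---------------------------------------------------------------------------
# the signature model
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """Trained supervised-PC signature: probes, SVD factors, Cox betas, cutoffs."""

    selected_probes: list[str]
    U: np.ndarray  # p_sel x r, orthonormal columns
    D: np.ndarray  # r singular values, non-increasing
    beta: np.ndarray  # Cox coefficients on the first n_components scores
    n_components: int = 3
    threshold: float | None = None
    training_index: pd.Series | None = field(default=None, repr=False)
    quintile_cutoffs: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "selected_probes": list(self.selected_probes),
            "U": self.U.tolist(),
            "D": self.D.tolist(),
            "beta": self.beta.tolist(),
            "n_components": self.n_components,
            "threshold": self.threshold,
            "quintile_cutoffs": None
            if self.quintile_cutoffs is None
            else list(map(float, self.quintile_cutoffs)),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            selected_probes=payload["selected_probes"],
            U=np.asarray(payload["U"], dtype=float),
            D=np.asarray(payload["D"], dtype=float),
            beta=np.asarray(payload["beta"], dtype=float),
            n_components=payload["n_components"],
            threshold=payload["threshold"],
            quintile_cutoffs=None
            if payload["quintile_cutoffs"] is None
            else np.asarray(payload["quintile_cutoffs"], dtype=float),
        )


def _cox_on_scores(V: np.ndarray, time, event, n_components: int):
    df = pd.DataFrame(V[:, :n_components], columns=[f"v{i + 1}" for i in range(n_components)])
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises several convergence types
        raise ConvergenceError(f"Cox fit on component scores failed: {exc}") from exc
    beta = cph.params_[[f"v{i + 1}" for i in range(n_components)]].values
    return beta, cph


def fit_signature(X_selected: pd.DataFrame, time, event, n_components: int = 3) -> SignatureModel:
    """Thin SVD of the selected z-scored matrix + Cox fit on the leading scores."""
    time, event = _check_survival(time, event)
    values = X_selected.values.astype(float)
    if values.shape[0] < n_components:
        raise ValidationError("need at least n_components selected probes")
    U, D, Vt = np.linalg.svd(values, full_matrices=False)
    rank = int((D > D[0] * 1e-12).sum())
    if rank < n_components:
        raise DegenerateDataError(
            f"selected matrix has rank {rank} < {n_components} components"
        )
    U, D, Vt = U[:, :rank], D[:rank], Vt[:rank]
    V = Vt.T  # n x r; equals X^T U D^-1 by construction
    beta, _ = _cox_on_scores(V, time, event, n_components)
    index = V[:, :n_components] @ beta
    training_index = pd.Series(index, index=X_selected.columns, name="index")
    cutoffs = np.quantile(index, [0.2, 0.4, 0.6, 0.8])  # linear-interpolation quantiles
    return SignatureModel(
        selected_probes=list(X_selected.index),
        U=U,
        D=D,
        beta=beta,
        n_components=n_components,
        training_index=training_index,
        quintile_cutoffs=cutoffs,
    )


def apply_signature(model: SignatureModel, X_test_selected: pd.DataFrame) -> pd.Series:
    """Project a test matrix through training U, D and score with training betas.

    The test matrix must contain every selected probe (rows are re-ordered to
    the training order) and should be z-scored within the test dataset.
    """
    missing = [p for p in model.selected_probes if p not in X_test_selected.index]
    if missing:
        raise ValidationError(f"test matrix lacks selected probes: {missing[:10]}")
    X = X_test_selected.loc[model.selected_probes].values.astype(float)
    V_test = X.T @ model.U @ np.diag(1.0 / model.D)
    index = V_test[:, : model.n_components] @ model.beta
    return pd.Series(index, index=X_test_selected.columns, name="index")


def assign_risk_groups(indices: pd.Series, rule: str = "quintile_3v2") -> pd.DataFrame:
    """Dichotomize index scores: three lower quintiles vs two upper, or median.

    Ties at the cutoff go to the lower-risk group (the comparison is <=).
    """
    indices = pd.Series(indices, dtype=float)
    if indices.nunique() == 1:
        raise DegenerateDataError("all index scores identical; grouping undefined")
    if rule == "quintile_3v2":
        if len(indices) < 5:
            raise ValidationError("quintile rule needs at least 5 patients")
        cutoff = float(np.quantile(indices.values, 0.6))
        low, high = LOWER_3_QUINTILES, UPPER_2_QUINTILES
    elif rule == "median":
        cutoff = float(np.quantile(indices.values, 0.5))
        low, high = BELOW_MEDIAN, ABOVE_MEDIAN
    else:
        raise ValidationError("rule must be 'quintile_3v2' or 'median'")
    group = np.where(indices.values <= cutoff, low, high)
    return pd.DataFrame({"index": indices.values, "group": group}, index=indices.index)


# ---------------------------------------------------------------------------
# threshold selection by cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(event: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment with events and censorings spread evenly."""
    fold = np.empty(len(event), dtype=int)
    for flag in (0, 1):
        idx = np.flatnonzero(event == flag)
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % k
    return fold


def select_threshold_cv(
    X: pd.DataFrame,
    time,
    event,
    grid=None,
    k_folds: int = 10,
    seed: int = 0,
    n_components: int = 3,
    score_type: str = "coef",
) -> float:
    """Pick the screening threshold maximizing mean held-out Cox fit quality.

    For each candidate threshold, each fold is held out in turn: probes are
    screened and selected on the remaining folds, the signature is fitted
    there, the held-out patients are projected, and the partial-likelihood-
    ratio statistic of a fresh Cox fit on their projected component scores
    measures how much survival signal transferred.  The grid defaults to the
    deciles of the full-data |score| distribution.
    """
    time, event = _check_survival(time, event)
    if k_folds < 2:
        raise ValidationError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    full_screen = univariate_cox_screen(X, time, event, score_type=score_type)
    if grid is None:
        scores = full_screen.loc[full_screen["converged"], "score"].abs()
        grid = np.unique(np.quantile(scores.values, np.linspace(0.1, 0.9, 9)))
    grid = [g for g in np.asarray(grid, dtype=float) if g > 0]
    if not grid:
        raise ValidationError("threshold grid is empty")
    folds = _stratified_folds(event, k_folds, rng)
    mean_stats = []
    for threshold in grid:
        stats = []
        for k in range(k_folds):
            train = folds != k
            test = ~train
            if event[test].sum() < 1 or event[train].sum() < 5:
                continue
            Xtr = X.iloc[:, train]
            screen = univariate_cox_screen(Xtr, time[train], event[train], score_type=score_type)
            try:
                probes = select_features(screen, threshold)
                if len(probes) < n_components:
                    continue
                model = fit_signature(Xtr.loc[probes], time[train], event[train], n_components)
                Xte = X.iloc[:, test].loc[probes]
                V_test = Xte.values.T @ model.U @ np.diag(1.0 / model.D)
                _, cph = _cox_on_scores(V_test, time[test], event[test], n_components)
                stats.append(cph.log_likelihood_ratio_test().test_statistic)
            except (ValidationError, DegenerateDataError, ConvergenceError):
                continue
        mean_stats.append(np.mean(stats) if stats else -np.inf)
    best = int(np.argmax(mean_stats))
    return float(grid[best])
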