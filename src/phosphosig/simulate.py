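"""Seeded synthetic cohorts with the structure every downstream stage assumes.

The generator emulates what the pipeline sees after platform-specific
preprocessing: a log2-scale probe x sample expression matrix with Gaussian
noise, a minority of probes annotated as phosphatases, a planted two-group
fold-change structure in the 1.2-4x range typical of phosphatase screens,
and exponential distant-metastasis-free survival whose log hazard is a
linear combination of a planted probe subset, with independent censoring.
Paired "platforms" with partially overlapping probe sets support
train/validation projection and cross-series intersection tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, ValidationError
from .io import zscore_by_probe

_EXPR_STREAM, _SURV_STREAM, _TRUTH_STREAM, _PAIR_STREAM = 0, 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated two-group cohort.

    Defaults describe a mid-sized phosphatome screen: 2000 probes of which
    5% are "phosphatase" probes, 20 samples per group, 100 differentially
    expressed probes with linear fold changes between 1.2x and 4x, within-
    group noise of 0.5 log2 units, 10 prognostic probes with per-unit
    log-hazards of 0.5-1.0 on z-scored expression, a baseline hazard of
    0.01 events/month and ~40% independent censoring.
    """

    n_probes: int = 2000
    frac_phosphatase: float = 0.05
    n_samples_per_group: int = 20
    n_de_probes: int = 100
    fc_range: tuple[float, float] = (1.2, 4.0)
    probe_sd: float = 0.5
    n_prognostic: int = 10
    beta_range: tuple[float, float] = (0.5, 1.0)
    baseline_hazard: float = 0.01
    censor_rate: float = 0.4
    n_replicate_probes: int = 0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_probes, self.n_de_probes, self.n_prognostic, self.n_replicate_probes) < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.n_probes < 1 or self.n_samples_per_group < 2:
            raise ConfigurationError("need >= 1 probe and >= 2 samples per group")
        if self.n_de_probes + self.n_prognostic > self.n_probes:
            raise ConfigurationError("n_de_probes + n_prognostic exceeds n_probes")
        if not 0 < self.frac_phosphatase <= 1:
            raise ConfigurationError("frac_phosphatase must be in (0, 1]")
        if not (1 <= self.fc_range[0] <= self.fc_range[1]):
            raise ConfigurationError("fc_range must satisfy 1 <= lo <= hi")
        if self.probe_sd <= 0:
            raise ConfigurationError("probe_sd must be > 0")
        if self.beta_range[0] > self.beta_range[1]:
            raise ConfigurationError("beta_range must be ordered")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ConfigurationError("censor_rate must be in [0, 1)")
        if self.n_replicate_probes > self.n_probes:
            raise ConfigurationError("n_replicate_probes exceeds n_probes")


@dataclass
class SimulatedCohort:
    """Expression + annotation + clinical tables with the planted ground truth."""

    expression: pd.DataFrame
    annotation: pd.DataFrame
    clinical: pd.DataFrame
    truth_de: dict[str, tuple[bool, float]]
    truth_prognostic: dict[str, float]
    config: SimConfig = field(repr=False, default=None)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # one deterministic sub-stream per purpose, all derived from config.seed
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


_PHOSPHATASE_DESCRIPTIONS = [
    "protein tyrosine phosphatase, receptor type",
    "dual specificity Phosphatase",
    "serine/threonine-protein phosphatase subunit",
    "inositol polyphosphate phosphatase family member",
]
_OTHER_DESCRIPTIONS = [
    "mitogen-activated protein kinase",
    "zinc finger protein, uncharacterized",
    "solute carrier family member",
    "ribosomal protein, cytosolic",
]


def _plan_truth(config: SimConfig, rng: np.random.Generator, probe_ids: list[str], eligible: np.ndarray):
    """Choose planted DE and prognostic probes (disjoint) and their effects."""
    n_plant = config.n_de_probes + config.n_prognostic
    if n_plant > len(eligible):
        raise ConfigurationError("not enough eligible probes to hold the planted effects")
    chosen = rng.choice(eligible, size=n_plant, replace=False)
    de_idx = chosen[: config.n_de_probes]
    prog_idx = chosen[config.n_de_probes:]
    fcs = rng.uniform(config.fc_range[0], config.fc_range[1], size=config.n_de_probes)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_probes)  # both directions occur
    shifts = np.zeros(config.n_probes)
    shifts[de_idx] = signs * np.log2(fcs)
    truth_de = {
        probe_ids[i]: (True, float(fc if sg > 0 else 1.0 / fc))
        for i, fc, sg in zip(de_idx, fcs, signs)
    }
    beta_mag = rng.uniform(config.beta_range[0], config.beta_range[1], size=config.n_prognostic)
    beta_sign = rng.choice([-1.0, 1.0], size=config.n_prognostic)
    truth_prognostic = {probe_ids[i]: float(b * s) for i, b, s in zip(prog_idx, beta_mag, beta_sign)}
    return shifts, truth_de, truth_prognostic


def _make_annotation(config: SimConfig, rng: np.random.Generator, probe_ids: list[str]) -> pd.DataFrame:
    n_phos = max(1, round(config.frac_phosphatase * config.n_probes))
    phos_idx = set(rng.choice(config.n_probes, size=n_phos, replace=False).tolist())
    descriptions, symbols = [], []
    for i in range(config.n_probes):
        if i in phos_idx:
            descriptions.append(_PHOSPHATASE_DESCRIPTIONS[i % len(_PHOSPHATASE_DESCRIPTIONS)])
            symbols.append(f"PHOS{i:05d}")
        else:
            descriptions.append(_OTHER_DESCRIPTIONS[i % len(_OTHER_DESCRIPTIONS)])
            symbols.append(f"GENE{i:05d}")
    return pd.DataFrame({"probe_id": probe_ids, "symbol": symbols, "description": descriptions})


def _expression_from_truth(
    config: SimConfig,
    rng: np.random.Generator,
    probe_ids: list[str],
    base_means: np.ndarray,
    shifts: np.ndarray,
    sample_prefix: str = "",
):
    n = config.n_samples_per_group
    sample_ids = [f"{sample_prefix}A{i + 1:03d}" for i in range(n)] + [
        f"{sample_prefix}B{i + 1:03d}" for i in range(n)
    ]
    means = np.tile(base_means[:, None], (1, 2 * n))
    means[:, :n] += shifts[:, None]  # group A carries the planted shift
    values = means + rng.normal(0.0, config.probe_sd, size=means.shape)
    expr = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    if config.n_replicate_probes:
        rep_rows = rng.choice(config.n_probes, size=config.n_replicate_probes, replace=False)
        rep_values = (
            means[rep_rows] + rng.normal(0.0, config.probe_sd, size=(config.n_replicate_probes, 2 * n))
        )
        rep = pd.DataFrame(
            rep_values, index=pd.Index([probe_ids[i] for i in rep_rows], name="probe_id"), columns=sample_ids
        )
        expr = pd.concat([expr, rep])
    groups = ["A"] * n + ["B"] * n
    return expr, sample_ids, groups


def _clinical_frame(config, rng, sample_ids, groups, time, event):
    n_total = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": time,
            "event": event,
            "er_status": ["neg"] * n_total,
            "erbb2_status": ["pos" if g == "A" else "neg" for g in groups],
            "pgr_status": ["neg"] * n_total,
            "age": np.round(rng.uniform(34, 80, size=n_total), 1),
            "size": np.round(rng.uniform(1.0, 7.5, size=n_total), 1),
            "grade": rng.choice([1, 2, 3], size=n_total, p=[0.05, 0.35, 0.6]),
            "group": groups,
        }
    )


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """One two-group cohort ("A"/"B") with planted fold changes and survival."""
    truth_rng = _rng(config, _TRUTH_STREAM)
    probe_ids = [f"P{i + 1:06d}" for i in range(config.n_probes)]
    base_means = truth_rng.uniform(6.0, 12.0, size=config.n_probes)
    shifts, truth_de, truth_prognostic = _plan_truth(
        config, truth_rng, probe_ids, np.arange(config.n_probes)
    )
    annotation = _make_annotation(config, truth_rng, probe_ids)

    expr_rng = _rng(config, _EXPR_STREAM)
    expression, sample_ids, groups = _expression_from_truth(
        config, expr_rng, probe_ids, base_means, shifts
    )
    surv = simulate_survival_times(expression, truth_prognostic, config)
    full = _clinical_frame(config, _rng(config, _SURV_STREAM + 10), sample_ids, groups,
                           surv["time"].values, surv["event"].values)
    return SimulatedCohort(
        expression=expression,
        annotation=annotation,
        clinical=full,
        truth_de=truth_de,
        truth_prognostic=truth_prognostic,
        config=config,
    )


def _solve_censor_rate(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate c with mean_j c/(c+h_j) = censor_rate."""

    def gap(log_c):
        c = np.exp(log_c)
        return np.mean(c / (c + hazards)) - censor_rate

    lo, hi = np.log(hazards.min()) - 20, np.log(hazards.max()) + 20
    return float(np.exp(brentq(gap, lo, hi, xtol=1e-12)))


def simulate_survival_times(expression: pd.DataFrame, betas: dict[str, float], config: SimConfig) -> pd.DataFrame:
    """Exponential DMFS times with log hazard = sum_k beta_k * z_k per sample.

    Expression is z-scored per probe before entering the hazard; censoring is
    exponential with a rate solved numerically so the expected censored
    fraction matches ``config.censor_rate``.
    """
    missing = [p for p in betas if p not in expression.index]
    if missing:
        raise KeyError(f"betas reference probes absent from expression: {missing[:5]}")
    rng = _rng(config, _SURV_STREAM)
    n = expression.shape[1]
    lp = np.zeros(n)
    if betas:
        sub = expression.loc[list(betas)]
        sub = sub[~sub.index.duplicated()]  # replicate rows: use the first copy
        z = zscore_by_probe(sub)
        lp = np.asarray(list(betas.values())) @ z.values
    hazards = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        c = _solve_censor_rate(hazards, config.censor_rate)
        censor_time = rng.exponential(1.0 / c, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"sample_id": list(expression.columns), "time": time, "event": event})


def simulate_multiplatform_pair(
    config: SimConfig, overlap_fraction: float
) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Two independent cohorts sharing planted truth on an overlapping probe set.

    The second cohort keeps ``overlap_fraction`` of the first cohort's probes
    (identical ids and planted effects) and fills the remainder with private
    probes carrying no planted signal.  Planted DE and prognostic probes are
    placed inside the shared subset so cross-platform validation has a
    defined truth.
    """
    if not 0 < overlap_fraction <= 1:
        raise ConfigurationError("overlap_fraction must be in (0, 1]")
    truth_rng = _rng(config, _PAIR_STREAM)
    probe_ids = [f"P{i + 1:06d}" for i in range(config.n_probes)]
    n_shared = round(overlap_fraction * config.n_probes)
    shared_idx = np.sort(truth_rng.choice(config.n_probes, size=n_shared, replace=False))
    if config.n_de_probes + config.n_prognostic > n_shared:
        raise ConfigurationError("overlap too small to hold the planted DE + prognostic probes")
    base_means = truth_rng.uniform(6.0, 12.0, size=config.n_probes)
    shifts, truth_de, truth_prognostic = _plan_truth(config, truth_rng, probe_ids, shared_idx)
    annotation = _make_annotation(config, truth_rng, probe_ids)

    cohorts = []
    for which in (0, 1):
        sub_cfg = SimConfig(**{**config.__dict__, "seed": config.seed * 2 + which + 1})
        rng = _rng(sub_cfg, _EXPR_STREAM)
        if which == 0:
            ids, means, shf = probe_ids, base_means, shifts
            anno = annotation
        else:
            shared_ids = [probe_ids[i] for i in shared_idx]
            n_private = config.n_probes - n_shared
            private_ids = [f"Q{i + 1:06d}" for i in range(n_private)]
            ids = shared_ids + private_ids
            means = np.concatenate([base_means[shared_idx], rng.uniform(6.0, 12.0, n_private)])
            shf = np.concatenate([shifts[shared_idx], np.zeros(n_private)])
            anno = pd.concat(
                [
                    annotation[annotation["probe_id"].isin(shared_ids)],
                    pd.DataFrame(
                        {
                            "probe_id": private_ids,
                            "symbol": [f"PRIV{i:05d}" for i in range(n_private)],
                            "description": [
                                _OTHER_DESCRIPTIONS[i % len(_OTHER_DESCRIPTIONS)] for i in range(n_private)
                            ],
                        }
                    ),
                ],
                ignore_index=True,
            )
        expr_cfg = SimConfig(**{**config.__dict__, "seed": sub_cfg.seed, "n_replicate_probes": 0})
        n = config.n_samples_per_group
        sample_ids = [f"S{which}_{g}{i + 1:03d}" for g in ("A", "B") for i in range(n)]
        groups = ["A"] * n + ["B"] * n
        mean_mat = np.tile(np.asarray(means)[:, None], (1, 2 * n))
        mean_mat[:, :n] += np.asarray(shf)[:, None]
        values = mean_mat + rng.normal(0.0, config.probe_sd, size=mean_mat.shape)
        expression = pd.DataFrame(values, index=pd.Index(ids, name="probe_id"), columns=sample_ids)
        surv = simulate_survival_times(expression, truth_prognostic, expr_cfg)
        clinical = _clinical_frame(
            expr_cfg, _rng(expr_cfg, _SURV_STREAM + 10), sample_ids, groups,
            surv["time"].values, surv["event"].values,
        )
        cohorts.append(
            SimulatedCohort(
                expression=expression,
                annotation=anno.reset_index(drop=True),
                clinical=clinical,
                truth_de=truth_de,
                truth_prognostic=truth_prognostic,
                config=config,
            )
        )
    return cohorts[0], cohorts[1]
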