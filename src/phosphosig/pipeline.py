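"""End-to-end orchestrated run: simulate -> preprocess -> screen -> subtype ->
signature train/validate -> survival statistics.

Every artifact is written under one run directory; ``report.json`` carries
the headline numbers together with the seed and a hash of the configuration
so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io, preprocess, sam, signature, subtype, survstats
from .errors import PhosphosigError, ValidationError
from .simulate import SimConfig, simulate_multiplatform_pair

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "phosphosig_run"
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    overlap_fraction: float = 0.8
    q_threshold: float = 0.05
    n_permutations: int = 200
    min_fraction: float = 0.75
    threshold: float | str = 0.4  # screening threshold, or "cv"
    n_components: int = 3
    grouping_rule: str = "quintile_3v2"
    score_type: str = "coef"
    run_diffexp: bool = True
    run_subtype: bool = True
    run_signature: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown pipeline config keys: {sorted(bad)}")
        return cls(**raw)

    def hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("outdir")  # a location, not a parameter
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = _time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PhosphosigError:
                raise
            except Exception as exc:
                raise PhosphosigError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, _time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "config_hash": config.hash()}

    sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
    train, valid = _stage("simulate")(simulate_multiplatform_pair)(sim_cfg, config.overlap_fraction)

    cohorts = {}
    for name, cohort in (("train", train), ("validation", valid)):
        expr = _stage("preprocess")(preprocess.quantile_normalize)(cohort.expression)
        expr = preprocess.summarize_replicate_probes(expr)
        io.write_expression_tsv(expr, outdir / f"{name}_expression.tsv")
        io.write_clinical_tsv(cohort.clinical, outdir / f"{name}_clinical.tsv")
        io.write_annotation_tsv(cohort.annotation, outdir / f"{name}_annotation.tsv")
        cohorts[name] = (expr, cohort)

    expr_train, train_cohort = cohorts["train"]
    phos = io.select_phosphatase_probes(train_cohort.annotation)
    phos = [p for p in phos if p in expr_train.index]

    if config.run_diffexp:
        labels = train_cohort.clinical.set_index("sample_id")["group"]
        sam_cfg = sam.SamConfig(
            n_permutations=config.n_permutations, seed=config.seed, q_threshold=config.q_threshold
        )
        result = _stage("diffexp")(sam.sam_permutation_fdr)(expr_train.loc[phos], labels, sam_cfg)
        table = sam.significant_table(result, train_cohort.annotation, config.q_threshold)
        table.to_csv(outdir / "sam_significant.tsv", sep="\t")
        report["diffexp"] = {
            "s0": result.s0,
            "pi0": result.pi0,
            "significant_probes": table.attrs["probe_count"],
            "significant_genes": table.attrs["gene_count"],
        }

    if config.run_subtype:
        assignment = _stage("subtype")(subtype.hierarchical_cluster_two_groups)(expr_train, phos)
        labeled = subtype.label_clusters_by_erbb2(assignment, train_cohort.clinical)
        labeled.labels.rename_axis("sample_id").to_frame().to_csv(
            outdir / "subtype_assignment.tsv", sep="\t"
        )
        scores = subtype.pca_scores(expr_train)
        scores.rename_axis("sample_id").to_csv(outdir / "pca_scores.tsv", sep="\t")
        report["subtype"] = {"erbb2_fractions": labeled.erbb2_fractions}

    if config.run_signature:
        report["signature"] = _stage("signature")(_signature_stage)(config, cohorts, outdir)

    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return outdir


def _signature_stage(config: PipelineConfig, cohorts, outdir: Path) -> dict:
    expr_train, train_cohort = cohorts["train"]
    expr_valid, valid_cohort = cohorts["validation"]
    z_train = io.zscore_by_probe(expr_train)
    z_valid = io.zscore_by_probe(expr_valid)
    t_tr = train_cohort.clinical["time"].values
    e_tr = train_cohort.clinical["event"].values
    t_va = valid_cohort.clinical["time"].values
    e_va = valid_cohort.clinical["event"].values

    shared = z_train.index.intersection(z_valid.index)
    screen = signature.univariate_cox_screen(
        z_train.loc[shared], t_tr, e_tr, score_type=config.score_type
    )
    if config.threshold == "cv":
        threshold = signature.select_threshold_cv(
            z_train.loc[shared], t_tr, e_tr, seed=config.seed, score_type=config.score_type
        )
    else:
        threshold = float(config.threshold)
    probes = signature.select_features(screen, threshold)
    model = signature.fit_signature(z_train.loc[probes], t_tr, e_tr, config.n_components)
    model.threshold = threshold
    model.to_json(outdir / "signature_model.json")

    out = {"threshold": threshold, "n_selected": len(probes)}
    valid_index = signature.apply_signature(model, z_valid.loc[probes])
    for name, idx, t, e in (
        ("train", model.training_index, t_tr, e_tr),
        ("validation", valid_index, t_va, e_va),
    ):
        groups = signature.assign_risk_groups(idx, config.grouping_rule)
        groups.rename_axis("sample_id").to_csv(outdir / f"{name}_risk_groups.tsv", sep="\t")
        chi2, p = survstats.logrank_test(t, e, groups["group"].values)
        curves = survstats.kaplan_meier(t, e, groups["group"].values)
        for gname, curve in curves.items():
            curve.to_csv(outdir / f"km_{name}_{gname}.tsv", sep="\t", index=False)
        refit = survstats.refit_continuous_cox(idx.values, t, e)
        out[name] = {"logrank_chi2": chi2, "logrank_p": p, "continuous_hr": refit["hr"]}
    return out
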