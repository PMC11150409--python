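"""End-to-end orchestration: simulate -> chemistry -> eco-clusters ->
feature selection -> train/validate -> warming projection.

Every stage reads and writes plain-text artifacts in the run directory, so
intermediate results are individually re-loadable, and the whole run is
deterministic for a fixed :class:`RunConfig` (the summary JSON is
byte-identical across reruns of the same config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, ecocluster, io, model, projection, rules, synthetic
from .sae import SaeConfig

logger = logging.getLogger("necromap")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All stage parameters for a pipeline run.

    Every stochastic stage derives its seed from ``seed`` so a serialized
    config reproduces the run exactly.
    """

    seed: int = 1
    out_dir: str = "necromap_run"
    # synthetic landscape
    n_sites: int = 80
    n_phylotypes: int = 100
    class_split: float = 0.48
    noise_sd: float = 1.0           # mg/g on planted MNC
    fb_ratio: float = 3.0
    # eco-cluster stage
    top_frac: float = 0.10
    occupancy_frac: float = 0.5
    screen_threshold: float = 30.0
    screen_trees: int = 500
    k: int | str = "auto"
    k_max: int = 12
    # feature selection / model
    select_fraction: float = 0.70
    kfold: int = 10
    holdout_frac: float = 0.25
    pretrain_epochs: int = 400
    finetune_epochs: int = 800
    learning_rate: float = 0.01
    # scenario (climate deltas for the 2050s high-emission pathway)
    delta_mat: float = 2.2          # degC
    delta_map_frac: float = 0.06    # fractional MAP change
    recompute_ai: bool = True
    alpha: float = 0.05

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig, out: Path):
    env = synthetic.generate_environment(cfg.n_sites, seed=cfg.seed,
                                         class_split=cfg.class_split)
    table, truth = synthetic.generate_phylotypes(
        env, cfg.n_phylotypes, seed=cfg.seed + 1)
    truth.noise_sd = cfg.noise_sd
    truth.fb_ratio = cfg.fb_ratio
    truth.mnc_coefficients = synthetic.default_mnc_coefficients(truth.cluster_names())
    true_abund = pd.DataFrame(
        {c: table[truth.members(c)].sum(axis=1) for c in truth.cluster_names()})
    sugars = synthetic.generate_amino_sugars(
        env, true_abund.reset_index(drop=True), truth, seed=cfg.seed + 2)
    io.write_table(env, out / "env.tsv")
    io.write_phylotype_table(table, out / "phylotypes.tsv")
    io.write_table(sugars, out / "amino_sugars.tsv")
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")
    return env, table, truth, sugars


@_stage("mnc")
def _mnc(cfg: RunConfig, out: Path, sugars: pd.DataFrame):
    est = chem.mnc_table(sugars)
    io.write_table(est, out / "mnc.tsv")
    return est


@_stage("ecocluster")
def _ecocluster(cfg: RunConfig, out: Path, table, env):
    dominant = ecocluster.select_dominant_phylotypes(
        table, top_frac=cfg.top_frac, occupancy_frac=cfg.occupancy_frac)
    pref = ecocluster.screen_habitat_preference(
        table, dominant, env, threshold=cfg.screen_threshold,
        n_trees=cfg.screen_trees, seed=cfg.seed + 3)
    clusters = ecocluster.cluster_phylotypes(
        pref, table, env, k=cfg.k, k_max=cfg.k_max)
    abund = ecocluster.cluster_relative_abundance(table, clusters)
    io.write_table(pref, out / "preference.tsv")
    io.write_json(clusters.to_dict(), out / "ecoclusters.json")
    io.write_table(abund.reset_index(), out / "cluster_abundance.tsv")
    return clusters, abund


@_stage("select-features")
def _select(cfg: RunConfig, out: Path, env, abund, mnc):
    candidates = pd.concat(
        [env[list(synthetic.ENV_VARIABLES)].reset_index(drop=True),
         abund.reset_index(drop=True)], axis=1)
    ranked = model.rank_variable_importance(candidates, mnc, seed=cfg.seed + 4)
    spec = model.select_top_fraction(
        ranked, fraction=cfg.select_fraction, cluster_vars=set(abund.columns))
    io.write_table(ranked, out / "importance.tsv")
    io.write_json(
        {"selected": spec.selected, "ce_set": spec.ce_set, "we_set": spec.we_set},
        out / "feature_spec.json")
    return candidates, spec


def _sae_cfg(cfg: RunConfig, seed: int) -> SaeConfig:
    return SaeConfig(
        learning_rate=cfg.learning_rate,
        pretrain_epochs=cfg.pretrain_epochs,
        finetune_epochs=cfg.finetune_epochs,
        seed=seed,
    )


@_stage("train-validate")
def _train_validate(cfg: RunConfig, out: Path, candidates, spec, mnc, env):
    factory = model.sae_factory(_sae_cfg(cfg, cfg.seed + 5))
    reports = {}
    for name, feats in (("CE", spec.ce_set), ("WE", spec.we_set)):
        rep = model.kfold_validate(
            candidates[feats], mnc, k=cfg.kfold, seed=cfg.seed + 6,
            model_factory=factory)
        reports[name] = rep
        io.write_table(rep.per_fold, out / f"cv_{name.lower()}_folds.tsv")
    hold = model.holdout_validate(
        candidates[spec.ce_set], mnc,
        classes=env["grassland_class"].to_numpy(),
        holdout_frac=cfg.holdout_frac, seed=cfg.seed + 7, model_factory=factory)
    # final CE model on all sites, for projection
    from .sae import SaeRegressor

    final = SaeRegressor(len(spec.ce_set), _sae_cfg(cfg, cfg.seed + 8))
    final.fit(candidates[spec.ce_set].to_numpy(dtype=float), mnc)
    metrics = {
        "cv": {k: v.pooled for k, v in reports.items()},
        "holdout_ce": hold.pooled,
    }
    io.write_json(metrics, out / "validation.json")
    return reports, hold, final


@_stage("project")
def _project(cfg: RunConfig, out: Path, env, abund, final, spec):
    rule_models = {
        cl: rules.fit_abundance_mapper(env, abund, cl, seed=cfg.seed + 9)
        for cl in abund.columns
    }
    env_future = synthetic.scenario_perturb(
        env, delta_mat=cfg.delta_mat, delta_map_frac=cfg.delta_map_frac,
        recompute_ai=cfg.recompute_ai)
    delta = projection.project_scenario(
        rule_models, final, spec.ce_set, env, env_future, alpha=cfg.alpha)
    io.write_table(delta.per_site, out / "projection_sites.tsv")
    io.write_table(delta.class_summary, out / "projection_summary.tsv")
    io.write_table(delta.shift_tests, out / "cluster_shift_tests.tsv")
    rule_err = {cl: rm.relative_error for cl, rm in rule_models.items()}
    return delta, rule_err


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Writes all intermediate tables plus ``summary.json`` with the metrics a
    downstream consumer needs (CE/WE cross-validation, hold-out, rule-model
    relative errors, scenario summary). Any stage failure aborts with the
    stage name and cause; partial outputs are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(dataclasses.asdict(cfg), out / "config.json")

    env, table, truth, sugars = _simulate(cfg, out)
    est = _mnc(cfg, out, sugars)
    mnc = est["total_C"].to_numpy(dtype=float)
    clusters, abund = _ecocluster(cfg, out, table, env)
    candidates, spec = _select(cfg, out, env, abund, mnc)
    reports, hold, final = _train_validate(cfg, out, candidates, spec, mnc, env)
    delta, rule_err = _project(cfg, out, env, abund, final, spec)

    grass = delta.class_summary.set_index("class").loc["grassland"]
    summary = {
        "config_hash": cfg.config_hash(),
        "n_sites": cfg.n_sites,
        "clusters": clusters.names,
        "ce_set_size": len(spec.ce_set),
        "we_set_size": len(spec.we_set),
        "cv": {k: v.pooled for k, v in reports.items()},
        "holdout_ce": hold.pooled,
        "rule_relative_error": rule_err,
        "scenario": {
            "mean_current_mnc": float(grass["mean_current"]),
            "mean_future_mnc": float(grass["mean_future"]),
            "mean_d_value": float(grass["mean_d"]),
            "percent_increase": float(
                100.0 * grass["mean_d"] / grass["mean_current"]),
            "n_significant_cluster_shifts": int(delta.shift_tests["significant"].sum()),
        },
    }
    io.write_json(summary, out / "summary.json")
    logger.info("pipeline complete: %s", out)
    return out
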