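"""End-to-end pipeline: simulate -> preprocess -> ANOVA -> fit x4 ->
compare -> PPC -> features -> forests -> report.

A :class:`PipelineConfig` fixes every seed and size; re-running the same
config reproduces all outputs bit-identically.  Two presets are bundled:
``desk`` (10 participants, shortened chains — minutes on one CPU) and
``full`` (34 participants, 3 chains x 3000 iterations — the study's
protocol sizes).  Every artifact file name carries the config hash that
produced it.
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
import yaml

from . import behavior, compare as mc, design, features, forest, ppc, sampler, simulate

__all__ = ["PipelineConfig", "run_all", "load_config"]

log = logging.getLogger("ruleddm.pipeline")

PRESETS = {
    "desk": dict(n_participants=10, n_iter=1500, burn_in=750, n_chains=3,
                 n_trees=100),
    "full": dict(n_participants=34, n_iter=3000, burn_in=1500, n_chains=3,
                 n_trees=300),
}


@dataclass
class PipelineConfig:
    scale: str = "desk"
    seed: int = 1
    n_participants: int | None = None
    trials_per_cell: int = 6
    population: str = "additive"      # truth used by the simulator
    v_interaction: float = 0.1
    dt: float = simulate.DEFAULT_DT
    n_chains: int | None = None
    n_iter: int | None = None
    burn_in: int | None = None
    adapt_window: int = 200
    target_accept: float = 0.30
    models: tuple = (1, 2, 3, 4)
    n_trees: int | None = None
    topk: int = 8
    importance_repeats: int = 50
    out_dir: str = "results/run"

    def __post_init__(self):
        if self.scale not in PRESETS:
            raise ValueError(f"scale must be one of {sorted(PRESETS)}")
        if self.seed is None:
            raise ValueError("config must set a seed")
        for k, v in PRESETS[self.scale].items():
            if getattr(self, k) is None:
                setattr(self, k, v)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:10]

    def mcmc(self, seed_offset: int = 0) -> sampler.McmcConfig:
        return sampler.McmcConfig(n_chains=self.n_chains, n_iter=self.n_iter,
                                  burn_in=self.burn_in,
                                  adapt_window=self.adapt_window,
                                  target_accept=self.target_accept,
                                  seed=self.seed + 1000 + seed_offset)


def load_config(path) -> PipelineConfig:
    """Read a YAML or JSON pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "models" in raw:
        raw["models"] = tuple(raw["models"])
    return PipelineConfig(**raw)


def _population(cfg: PipelineConfig) -> design.PopulationParams:
    if cfg.population == "hierarchy":
        return design.hierarchy_population()
    if cfg.population == "block":
        return design.block_population()
    if cfg.population == "additive":
        return design.additive_population(v_interaction=cfg.v_interaction)
    raise ValueError(f"unknown population style {cfg.population!r}")


def simulate_cohort(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full collected cohort plus its screening fixture."""
    fixture = design.make_exclusion_fixture(seed=cfg.seed)
    des = design.generate_design(cfg.n_participants, cfg.trials_per_cell,
                                 seed=cfg.seed + 1)
    pop = _population(cfg)
    params = design.draw_subject_params(pop, cfg.n_participants, seed=cfg.seed + 2)
    trials = simulate.simulate_dataset(des, params, dt=cfg.dt, seed=cfg.seed + 3)
    fixture = fixture.iloc[:max(cfg.n_participants, 0)] if cfg.n_participants < 40 \
        else fixture
    return trials, fixture


def run_all(cfg: PipelineConfig, stages: tuple | None = None) -> dict:
    """Execute the pipeline; returns a report bundle of key artifacts.

    Any stage failure aborts with a stage-tagged error; partial outputs
    written so far are preserved in the run directory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash
    bundle: dict = {"config_hash": h}
    (out / f"config-{h}.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2, default=str))
    stage = "simulate"
    try:
        log.info("[simulate] cohort of %d participants", cfg.n_participants)
        trials, fixture = simulate_cohort(cfg)
        design.write_trials_csv(trials, out / f"trials-{h}.csv")
        fixture.to_csv(out / f"screening-{h}.csv", index=False)
        bundle["trials"] = trials

        stage = "preprocess"
        clean = behavior.preprocess(trials, fixture)
        bundle["clean"] = clean
        log.info("[preprocess] %d participants retained, %d outlier trials",
                 clean.n_participants, len(clean.outlier_log))

        stage = "anova"
        for dv in ("accuracy", "rt"):
            res = behavior.rm_anova(clean, dv=dv)
            res.table.to_csv(out / f"anova-{dv}-{h}.csv", index=False)
            bundle[f"anova_{dv}"] = res

        stage = "fit"
        fits = {}
        for mid in cfg.models:
            log.info("[fit] model %d", mid)
            fits[mid] = sampler.fit(clean.trials, mid, cfg.mcmc(seed_offset=mid))
            fits[mid].summary().to_csv(out / f"posterior-m{mid}-{h}.csv", index=False)
        bundle["fits"] = fits

        stage = "compare"
        table = mc.compare(fits, clean.trials)
        table.per_model.to_csv(out / f"comparison-{h}.csv", index=False)
        (out / f"comparison-{h}.txt").write_text(str(table))
        bundle["comparison"] = table
        log.info("[compare] selected model %d", table.selected)

        stage = "ppc"
        best = fits[table.selected]
        report = ppc.posterior_predictive_check(best, clean.trials,
                                                seed=cfg.seed + 7)
        report.table.to_csv(out / f"ppc-{h}.csv", index=False)
        bundle["ppc"] = report

        stage = "features"
        ft = features.build_features(clean.trials, best)
        ft.to_csv(out / f"features-{h}.csv", index=False)
        bundle["features"] = ft

        stage = "forest"
        groups = ft["participant_id"].to_numpy()
        results = {}
        for task, target in (("classification", "Accuracy"), ("regression", "log_rt")):
            sub = ft if task == "classification" else ft[ft["Accuracy"] == 1]
            y = sub[target].to_numpy()
            fcfg = forest.ForestConfig(task=task, n_trees=cfg.n_trees,
                                       seed=cfg.seed + 11)
            fr = forest.train_forest(sub, y, fcfg)
            imp = forest.permutation_importance(fr, repeats=cfg.importance_repeats,
                                                seed=cfg.seed + 13)
            imp.table.to_csv(out / f"importance-{task}-{h}.csv", index=False)
            K = min(5, int(sub["participant_id"].nunique()))
            comparison = forest.topk_refit(sub[forest.FEATURE_COLUMNS], y, fcfg,
                                           imp, k=cfg.topk,
                                           groups=sub["participant_id"].to_numpy(),
                                           K=K, seed=cfg.seed + 17)
            comparison.to_csv(out / f"topk-{task}-{h}.csv", index=False)
            results[task] = {"forest": fr, "importance": imp,
                             "topk": comparison}
        bundle["forest"] = results
        _ = groups
    except Exception as err:  # noqa: BLE001 - re-tag with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / f"report-{h}.json").write_text(json.dumps({
        "config_hash": h,
        "n_participants_retained": bundle["clean"].n_participants,
        "selected_model": bundle["comparison"].selected,
        "max_rhat_selected": bundle["fits"][bundle["comparison"].selected].max_rhat,
        "ppc_max_rt_discrepancy": bundle["ppc"].max_rt_discrepancy,
        "importance_ranking_classification":
            bundle["forest"]["classification"]["importance"].ranking(),
    }, indent=2))
    return bundle
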