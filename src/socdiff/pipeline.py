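"""End-to-end analysis pipeline: validate -> networks -> model selection ->
best-model inference -> multistate -> (optional) observation-network GLMM.

Configured from a YAML file with either an ``inputs`` block (paths to
events/ilv/kin CSVs) or a ``simulation`` block (ground-truth parameters for
the synthetic generator) — exactly one of the two. Every artifact is
stamped with the config hash and seed; stage warnings are surfaced in the
final report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import model_selection as ms
from .data_model import (
    EventLog,
    ILVTable,
    count_learners,
    format_rate,
    load_event_log,
    load_ilv_table,
    min_observations_among_learners,
    summarize_individuals,
    write_event_log,
    write_ilv_table,
)
from .multistate import build_multistate_data, fit_multistate
from .oada import OADAModelSpec, build_diffusion_data, percent_st, percent_st_ci, profile_ci_s
from .obsnet_glmm import build_obs_design, mcmc_sample, odds_ratios_hpd
from .synthetic import SimulationConfig, simulate_diffusion

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    inputs: dict | None = None  # {"events": ..., "ilv": ..., "kin": ...}
    simulation: dict | None = None  # SimulationConfig fields
    networks: tuple[str, ...] = ms.OBSERVATION_NETWORKS
    hypotheses: tuple[str, ...] = ms.SOCIAL_HYPOTHESES
    ilvs: tuple[str, ...] = ("sex", "age", "rank")
    ilv_scheme: str = "joint"
    include_group_network: bool = True
    include_asocial: bool = True
    ci_level: float = 0.95
    profile_ceiling: float = 1e6
    seed: int = 0
    run_multistate: bool = True
    run_obsnet: bool = False
    obsnet_iters: tuple[int, int, int] = (2, 3000, 1000)  # chains, iters, burn-in

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("config must contain exactly one of 'inputs' / 'simulation'")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for key in (
            "inputs", "simulation", "networks", "hypotheses", "ilvs", "ilv_scheme",
            "include_group_network", "include_asocial", "ci_level", "profile_ceiling",
            "seed", "run_multistate", "run_obsnet",
        ):
            if key in raw:
                v = raw[key]
                kwargs[key] = tuple(v) if isinstance(v, list) else v
        cfg = cls(**kwargs)
        if seed is not None:
            cfg.seed = seed
        return cfg

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _load_or_simulate(cfg: PipelineConfig, outdir: Path) -> tuple[EventLog, ILVTable, list[str]]:
    warnings: list[str] = []
    if cfg.inputs is not None:
        ilv = load_ilv_table(cfg.inputs["ilv"], cfg.inputs.get("kin"))
        log = load_event_log(cfg.inputs["events"], ilv)
        return log, ilv, warnings
    sim_kwargs = dict(cfg.simulation or {})
    sim_kwargs.setdefault("seed", cfg.seed)
    for k, v in sim_kwargs.items():
        if isinstance(v, list):
            sim_kwargs[k] = tuple(v)
    sim = SimulationConfig(**sim_kwargs)
    study = simulate_diffusion(sim)
    warnings.extend(study.flags)
    write_event_log(study.log, outdir / "events.csv")
    write_ilv_table(study.ilv, outdir / "ilv.csv", outdir / "kin.csv")
    (outdir / "truth.json").write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    return study.log, study.ilv, warnings


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages and write model_table.csv, summary.json, report.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    warnings: list[str] = []
    summary: dict = {"config_hash": cfg.hash(), "seed": cfg.seed}

    log, ilv, w = _load_or_simulate(cfg, outdir)
    warnings.extend(w)
    summaries = summarize_individuals(log, ilv)
    n_learners = count_learners(summaries)
    summary["data"] = {
        "n_individuals": len(ilv),
        "n_trained": len(ilv.trained_ids()),
        "n_solve_events": len(log.solves),
        "n_observation_events": len(log.observations),
        "n_learners": n_learners,
        "min_observations_among_learners": (
            min_observations_among_learners(summaries) if n_learners else None
        ),
    }

    # model selection across networks and hypotheses
    data_by_network = {
        net: build_diffusion_data(log, ilv, net)
        for net in {*cfg.networks, *( ("group",) if cfg.include_group_network else () )}
    }
    specs = ms.enumerate_model_set(
        networks=cfg.networks, hypotheses=cfg.hypotheses, ilvs=cfg.ilvs,
        scheme=cfg.ilv_scheme, include_group_network=cfg.include_group_network,
        include_asocial=cfg.include_asocial,
    )
    n_events = data_by_network[specs[0].network_variant].n_events
    fittable = [sp for sp in specs if n_events > sp.n_params + 1]
    if len(fittable) < len(specs):
        warnings.append(
            f"dropped {len(specs) - len(fittable)} over-parameterised models "
            f"(AICc undefined at {n_events} events)"
        )
    table = ms.fit_model_set(fittable, data_by_network)
    table.table.to_csv(outdir / "model_table.csv", index=False)
    social = table.table[table.table["hypothesis"] != "asocial"]
    summary["support"] = {
        "comparison_set": "social models (asocial excluded; assessed via s profile CI)",
        "by_network": ms.total_support(social, "network"),
        "by_hypothesis": ms.total_support(social, "hypothesis"),
    }
    for f in table.fits:
        warnings.extend(f.diagnostics)

    # best-model inference; social effects conditional on the best social model
    best = table.best()
    summary["best_model"] = best.to_dict()
    social_fits = [f for f in table.fits if f.spec.n_free_s > 0]
    if social_fits:
        best_social = min(social_fits, key=lambda f: f.aicc)
        best_data = data_by_network[best_social.spec.network_variant]
        ci = profile_ci_s(best_social, best_data, which=0, level=cfg.ci_level,
                          ceiling_factor=cfg.profile_ceiling)
        best_social.profile_ci["s[0]"] = ci
        best_social.percent_st = percent_st(best_social, data=best_data)
        best_social.percent_st_interval = percent_st_ci(best_social, best_data, ci)
        summary["best_social_model"] = best_social.to_dict()

    # multistate extension (only meaningful when manipulations were recorded)
    if cfg.run_multistate and log.first_manipulations:
        msd = build_multistate_data(log, ilv)
        fit = fit_multistate(msd, level=cfg.ci_level)
        summary["multistate"] = fit.to_dict()
        warnings.extend(fit.diagnostics)

    # observation-network structure (optional; MCMC)
    if cfg.run_obsnet:
        design = build_obs_design(log, ilv)
        chains, iters, burn = cfg.obsnet_iters
        sample = mcmc_sample(design, n_chains=chains, n_iter=iters, n_burn=burn, seed=cfg.seed)
        summary["obsnet"] = odds_ratios_hpd(sample, level=cfg.ci_level, force=True)

    summary["warnings"] = warnings
    (outdir / "summary.json").write_text(json.dumps(_jsonify(summary), indent=2, sort_keys=True))
    (outdir / "report.txt").write_text(
        _render_report(summary) + f"\nwall time: {time.time() - t0:.1f} s\n"
    )
    return summary


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def _render_report(summary: dict) -> str:
    lines = [
        "Diffusion analysis report",
        f"config {summary['config_hash']}  seed {summary['seed']}",
        "",
        f"individuals: {summary['data']['n_individuals']}  "
        f"(trained: {summary['data']['n_trained']})",
        f"learners: {summary['data']['n_learners']}  "
        f"min observations among learners: {summary['data']['min_observations_among_learners']}",
        "",
        "support by network (%):",
    ]
    for k, v in summary["support"]["by_network"].items():
        lines.append(f"  {k}: {v:.1f}")
    lines.append("support by hypothesis (%):")
    for k, v in summary["support"]["by_hypothesis"].items():
        lines.append(f"  {k}: {v:.1f}")
    best = summary.get("best_social_model", summary["best_model"])
    lines += [
        "",
        f"best model (AICc): {summary['best_model']['spec']}",
        f"social effects conditional on: {best['spec']}",
        f"  s by group: {[format_rate(s, 3) for s in best['s_by_group']]}",
        f"  95% profile CI for s: {best['profile_ci']}",
        f"  %ST: {best['percent_st']} (interval {best['percent_st_interval']})",
    ]
    if "multistate" in summary:
        st1, st2 = summary["multistate"]["stage1"], summary["multistate"]["stage2"]
        lines += [
            "",
            "multistate (naive -> interacting -> informed):",
            f"  stage 1 s by group: {st1['s_by_group']}  CI {st1['profile_ci']}  %ST {st1['percent_st']}",
            f"  stage 2 s by group: {st2['s_by_group']}  CI {st2['profile_ci']}  %ST {st2['percent_st']}",
            f"  stage-1 ratio s2/s1: {summary['multistate']['ratio_s2_s1']} "
            f"CI {summary['multistate']['ratio_ci']}",
        ]
    if summary.get("warnings"):
        lines += ["", "warnings:"] + [f"  - {w}" for w in summary["warnings"]]
    lines.append("")
    return "\n".join(str(x) for x in lines)
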