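"""Config-driven experiment orchestration.

Each experiment family of the study maps to one registry entry:

    bifurcation    -- equilibrium branches over an excitability grid
    switch_single  -- single-unit switching statistics over noise scales
    mfpt_curve     -- Monte Carlo MFPT over noise scales
    density        -- stationary histogram (and optional FPK solve) + modality
    switch_network -- network switching counts over clustering coefficients
    nmfpt_surface  -- pooled NMFPT over (clustering coefficient, noise scale)

``run_experiment`` reads a flat YAML/dict config (validated against a light
per-experiment schema), dispatches to the library modules, writes CSV tables
into the output directory, and records a JSON manifest (config echo, seeds,
package version, wall time, produced files).  Re-running an identical config
reproduces identical outputs: deterministic stages exactly, stochastic ones
through identical seed schedules.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .density import count_modes, forward_fpk_stationary, stationary_density_histogram, write_density_csv
from .model import FNParams, bifurcation_diagram, find_equilibria
from .passage import NMFPTConfig, PassageProblem, mfpt_monte_carlo, nmfpt_surface
from .simulate import (
    CouplingSpec,
    SimConfig,
    detect_switches,
    retention_statistics,
    simulate_ensemble,
    simulate_network,
    simulate_single,
    switch_counts_per_node,
)
from .synthetic import StableNoiseSpec, build_ring_lattice, draw_initial_conditions

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]

log = logging.getLogger("fhnswitch")


@dataclass
class ExperimentConfig:
    """A named experiment plus its (flat, serializable) option mapping."""

    experiment: str
    options: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "fhn_out"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        name = raw.pop("experiment")
        seed = int(raw.pop("seed", 0))
        out_dir = str(raw.pop("out_dir", "fhn_out"))
        return cls(experiment=name, options=raw, seed=seed, out_dir=out_dir)

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {sorted(EXPERIMENTS)}"
            )
        schema = _SCHEMAS[self.experiment]
        for key, val in self.options.items():
            if key not in schema:
                raise ValueError(f"unknown option {key!r} for {self.experiment!r}")
            expect = schema[key]
            if expect is float and isinstance(val, (int, float)):
                continue
            if expect is list and isinstance(val, (list, tuple)):
                continue
            if not isinstance(val, expect):
                raise ValueError(f"option {key!r} should be {expect}, got {type(val)}")


def _opt(cfg: ExperimentConfig, key: str, default):
    return cfg.options.get(key, default)


def _params(cfg: ExperimentConfig) -> FNParams:
    return FNParams(
        a=float(_opt(cfg, "a", 2.0)),
        b=float(_opt(cfg, "b", 1.5)),
        c=float(_opt(cfg, "c", 1.0)),
        e=float(_opt(cfg, "e", 2.0)),
    )


def _noise(cfg: ExperimentConfig, gamma: float) -> StableNoiseSpec:
    return StableNoiseSpec(
        alpha=float(_opt(cfg, "alpha", 2.0)),
        beta=float(_opt(cfg, "beta", 0.0)),
        gamma=float(gamma),
        delta=float(_opt(cfg, "delta", 0.0)),
    )


def _simcfg(cfg: ExperimentConfig, t_end_default=200.0, stride=1) -> SimConfig:
    return SimConfig(
        dt=float(_opt(cfg, "dt", 0.01)),
        t_end=float(_opt(cfg, "t_end", t_end_default)),
        record_stride=int(_opt(cfg, "record_stride", stride)),
        seed=cfg.seed,
    )


# --- experiment implementations -------------------------------------------


def _run_bifurcation(cfg: ExperimentConfig, out: Path) -> dict:
    p = _params(cfg)
    e_grid = np.linspace(
        float(_opt(cfg, "e_min", 0.5)), float(_opt(cfg, "e_max", 3.0)), int(_opt(cfg, "n_e", 101))
    )
    df = bifurcation_diagram(p, e_grid)
    path = out / "bifurcation.csv"
    df.to_csv(path, index=False)
    return {"tables": [path.name], "n_rows": len(df), "e_critical": p.e_critical}


def _run_switch_single(cfg: ExperimentConfig, out: Path) -> dict:
    p = _params(cfg)
    gammas = list(_opt(cfg, "gamma_list", [0.1, 0.2, 0.3, 0.4]))
    sim = _simcfg(cfg)
    eq = find_equilibria(p)
    init = eq.stable_points[0] if eq.regime == "bistable" else eq.points[0]
    rows = []
    for i, g in enumerate(gammas):
        sim_g = SimConfig(sim.dt, sim.t_end, sim.record_stride, seed=sim.seed + i)
        traj = simulate_single(p, _noise(cfg, g), sim_g, init)
        rec = detect_switches(traj)
        ret = retention_statistics(rec)
        rows.append(
            {
                "gamma": g,
                "d": _noise(cfg, g).d,
                "n_switches": int(rec.counts.sum()),
                "mean_dwell": ret.pooled_mean,
            }
        )
    df = pd.DataFrame(rows)
    path = out / "switch_single.csv"
    df.to_csv(path, index=False)
    return {"tables": [path.name], "n_rows": len(df)}


def _run_mfpt_curve(cfg: ExperimentConfig, out: Path) -> dict:
    p = _params(cfg)
    gammas = list(_opt(cfg, "gamma_list", [0.15, 0.2, 0.3, 0.4]))
    n_paths = int(_opt(cfg, "n_paths", 500))
    sim = _simcfg(cfg, t_end_default=1000.0)
    eq = find_equilibria(p)
    start = eq.stable_points[0]
    u_high = float(_opt(cfg, "u_high", 1.0))
    rows = []
    for g in gammas:
        prob = PassageProblem(p, _noise(cfg, g), tuple(start), u_high=u_high, mode="u_above")
        est = mfpt_monte_carlo(prob, sim, n_paths)
        rows.append(
            {
                "gamma": g,
                "d": prob.noise.d,
                "mfpt": est.mean,
                "sem": est.sem,
                "n_paths": est.n_paths,
                "censored": est.censored,
            }
        )
    df = pd.DataFrame(rows)
    path = out / "mfpt_curve.csv"
    df.to_csv(path, index=False)
    return {"tables": [path.name], "monotone_decreasing": bool(df["mfpt"].is_monotonic_decreasing)}


def _run_density(cfg: ExperimentConfig, out: Path) -> dict:
    p = _params(cfg)
    gamma = float(_opt(cfg, "gamma", 0.2))
    sim = _simcfg(cfg, t_end_default=400.0, stride=10)
    n_paths = int(_opt(cfg, "n_traj", 32))
    eq = find_equilibria(p)
    if eq.regime == "bistable":
        inits = np.array([eq.stable_points[i % 2] for i in range(n_paths)], dtype=float)
    else:
        inits = np.tile(np.asarray(eq.points[0], dtype=float), (n_paths, 1))
    traj = simulate_ensemble(p, _noise(cfg, gamma), sim, inits)
    grid = stationary_density_histogram(traj)
    n_modes, modes = count_modes(grid)
    path = out / "density.csv"
    write_density_csv(grid, path)
    report = {"n_modes": n_modes, "modes": modes, "gamma": gamma, "d": _noise(cfg, gamma).d}
    (out / "modes.json").write_text(json.dumps(report, indent=2) + "\n")
    tables = [path.name, "modes.json"]
    if bool(_opt(cfg, "fpk", False)):
        fpk = forward_fpk_stationary(p, D_u=_noise(cfg, gamma).diffusion_u)
        write_density_csv(fpk, out / "density_fpk.csv")
        tables.append("density_fpk.csv")
    return {"tables": tables, **report}


def _run_switch_network(cfg: ExperimentConfig, out: Path) -> dict:
    p = _params(cfg)
    n = int(_opt(cfg, "n_nodes", 100))
    k_list = list(_opt(cfg, "k_list", [2, 14, 20, 36]))
    gamma = float(_opt(cfg, "gamma", 0.4))
    sim = _simcfg(cfg, t_end_default=100.0, stride=10)
    coupling = CouplingSpec(float(_opt(cfg, "d1", 0.1)), float(_opt(cfg, "d2", 0.1)))
    rows = []
    for k in k_list:
        net = build_ring_lattice(n, k)
        init = draw_initial_conditions("random_basin", p, n, seed=sim.seed)
        noise = _noise(cfg, gamma) if gamma > 0 else None
        traj = simulate_network(p, net, coupling, noise, sim, init)
        counts, _ = switch_counts_per_node(traj)
        rows.append(
            {
                "k": k,
                "cc": net.clustering,
                "gamma": gamma,
                "total_switches": int(counts.sum()),
                "nodes_switched": int((counts > 0).sum()),
            }
        )
    df = pd.DataFrame(rows)
    path = out / "switch_network.csv"
    df.to_csv(path, index=False)
    return {"tables": [path.name], "n_rows": len(df)}


def _run_nmfpt_surface(cfg: ExperimentConfig, out: Path) -> dict:
    p = _params(cfg)
    df = nmfpt_surface(
        p,
        k_list=list(_opt(cfg, "k_list", [2, 14, 20, 36])),
        gamma_list=list(_opt(cfg, "gamma_list", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])),
        n_nodes=int(_opt(cfg, "n_nodes", 100)),
        coupling=CouplingSpec(float(_opt(cfg, "d1", 0.1)), float(_opt(cfg, "d2", 0.1))),
        cfg=_simcfg(cfg, t_end_default=100.0),
        nmcfg=NMFPTConfig(
            u_high=float(_opt(cfg, "u_high", 1.0)),
            u_low=float(_opt(cfg, "u_low", -1.0)),
            n_reps=int(_opt(cfg, "n_reps", 50)),
        ),
    )
    path = out / "nmfpt_surface.csv"
    df.to_csv(path, index=False)
    return {"tables": [path.name], "n_cells": len(df)}


EXPERIMENTS = {
    "bifurcation": _run_bifurcation,
    "switch_single": _run_switch_single,
    "mfpt_curve": _run_mfpt_curve,
    "density": _run_density,
    "switch_network": _run_switch_network,
    "nmfpt_surface": _run_nmfpt_surface,
}

_COMMON = {
    "a": float, "b": float, "c": float, "e": float,
    "alpha": float, "beta": float, "delta": float,
    "dt": float, "t_end": float, "record_stride": int,
}
_SCHEMAS = {
    "bifurcation": {**_COMMON, "e_min": float, "e_max": float, "n_e": int},
    "switch_single": {**_COMMON, "gamma_list": list},
    "mfpt_curve": {**_COMMON, "gamma_list": list, "n_paths": int, "u_high": float},
    "density": {**_COMMON, "gamma": float, "n_traj": int, "fpk": bool},
    "switch_network": {**_COMMON, "gamma": float, "n_nodes": int, "k_list": list, "d1": float, "d2": float},
    "nmfpt_surface": {
        **_COMMON,
        "gamma_list": list, "k_list": list, "n_nodes": int,
        "d1": float, "d2": float, "u_high": float, "u_low": float, "n_reps": int,
    },
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Dispatch an experiment, write its tables and manifest, return a summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log.info("running experiment %r (seed=%d) -> %s", config.experiment, config.seed, out)
    status = "ok"
    try:
        summary = EXPERIMENTS[config.experiment](config, out)
    except Exception as exc:  # pragma: no cover - error path
        status = f"error: {exc}"
        summary = {}
        raise
    finally:
        manifest = {
            "experiment": config.experiment,
            "options": config.options,
            "seed": config.seed,
            "version": __version__,
            "wall_clock_s": round(time.time() - t0, 3),
            "status": status,
            **{k: v for k, v in summary.items() if k != "modes"},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n"
        )
    return summary
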