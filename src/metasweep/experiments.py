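"""Ensemble replication, summary statistics, presets and analytic reports.

This is the plumbing layer behind the CLI: given a flat configuration it
runs seeded replicate ensembles of any model variant, tabulates per-replicate
and aggregate statistics, and bundles every closed-form prediction for a
parameter set into a single serialisable record.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import ModelParams, Trajectory, _as_rng, sample_equilibrium_state
from .full import classify_regime, omega0, run_full
from .neutral import (
    expected_diversity_approx,
    expected_diversity_exact,
    run_neutral,
    tau_eq,
    theta,
)
from .sweep import introduce_gene, run_until_fixation, sweep_parameter_Q0, tau_fix

__all__ = [
    "CONFIG_KEYS",
    "EnsembleSummary",
    "AnalyticPrediction",
    "run_ensemble",
    "analytic_report",
    "preset",
    "plateau_mean",
    "PRESET_NAMES",
]

MODELS = ("neutral", "sweep", "full")

CONFIG_KEYS = {
    "model", "M", "nu", "pm", "ph", "omega", "arrival_mode",
    "steps", "record_every", "replicates", "seed", "init_nu",
}

STAT_COLUMNS = ["S0", "S_i", "S_f", "S_min", "S_max", "S_mean", "fixation_steps"]


def plateau_mean(traj: Trajectory, fraction: float = 1 / 3) -> float:
    """Time-averaged diversity over the final ``fraction`` of a trajectory."""
    n = len(traj.S)
    lo = int(math.floor(n * (1 - fraction)))
    return float(np.mean(traj.S[lo:]))


def _params_from_config(cfg: dict) -> ModelParams:
    return ModelParams(
        M=int(cfg["M"]),
        nu=float(cfg.get("nu", 0.0)),
        p_m=float(cfg.get("pm", 0.0)),
        p_h=float(cfg.get("ph", 0.0)),
        omega=float(cfg.get("omega", 0.0)),
        arrival_mode=cfg.get("arrival_mode", "none"),
        n_steps=int(cfg.get("steps", 0)),
        record_every=int(cfg.get("record_every", max(1, int(cfg["M"])))),
        seed=int(cfg.get("seed", 0)),
    )


@dataclass
class EnsembleSummary:
    """Per-replicate statistics plus exactly recomputable aggregates."""

    config: dict
    per_replicate: pd.DataFrame
    aggregate: pd.DataFrame

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metasweep {__version__}\n")
            for key in sorted(self.config):
                fh.write(f"# {key} = {self.config[key]}\n")
            self.per_replicate.to_csv(fh, sep="\t", index=False, float_format="%.10g")
            fh.write("#aggregate\n")
            self.aggregate.to_csv(fh, sep="\t", index=True, float_format="%.10g")

    def to_tsv_bytes(self) -> bytes:
        buf = io.StringIO()
        buf.write(f"# metasweep {__version__}\n")
        for key in sorted(self.config):
            buf.write(f"# {key} = {self.config[key]}\n")
        self.per_replicate.to_csv(buf, sep="\t", index=False, float_format="%.10g")
        buf.write("#aggregate\n")
        self.aggregate.to_csv(buf, sep="\t", index=True, float_format="%.10g")
        return buf.getvalue().encode()


def aggregate_statistics(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean/std/median/IQR/min/max for every statistic column present."""
    cols = [c for c in STAT_COLUMNS if c in per_replicate.columns]
    data = per_replicate[cols]
    agg = pd.DataFrame(
        {
            "mean": data.mean(),
            "std": data.std(ddof=1),
            "median": data.median(),
            "iqr": data.quantile(0.75) - data.quantile(0.25),
            "min": data.min(),
            "max": data.max(),
        }
    ).T
    agg.index.name = "statistic"
    return agg


def _replicate_row(model: str, params: ModelParams, cfg: dict, seed: int) -> dict:
    rng = _as_rng(seed)
    row: dict = {}
    if model == "neutral":
        traj = run_neutral(params.with_(seed=seed), rng)
        row["S0"] = plateau_mean(traj)
        row["S_f"] = int(traj.S[-1])
        row["S_min"] = int(traj.S.min())
        row["S_max"] = int(traj.S.max())
        row["S_mean"] = float(traj.S.mean())
    elif model == "sweep":
        init_nu = float(cfg.get("init_nu") or params.nu)
        state = sample_equilibrium_state(params.M, init_nu, rng)
        introduce_gene(state, rng)
        max_steps = params.n_steps if params.n_steps > 0 else None
        traj, summary = run_until_fixation(
            state, params.p_m, params.p_h, rng,
            record_every=params.record_every, max_steps=max_steps,
        )
        row["S_i"] = summary.S_i
        row["S_f"] = summary.S_f
        row["S_min"] = summary.S_min
        row["S_max"] = summary.S_max
        row["S_mean"] = summary.S_mean
        row["fixation_steps"] = (
            float(summary.fixation_step) if summary.fixation_step is not None else np.nan
        )
    else:
        init_nu = cfg.get("init_nu")
        traj, episodes = run_full(
            params.with_(seed=seed), rng,
            init_nu=float(init_nu) if init_nu is not None else None,
        )
        first = episodes[0]
        row["S0"] = first.S_start
        row["S_min"] = int(min(e.S_min for e in episodes))
        row["S_max"] = int(max(e.S_max for e in episodes))
        row["S_mean"] = float(traj.S.mean())
        row["S_f"] = int(traj.S[-1])
        row["fixation_steps"] = (
            float(first.fixation_step) if first.fixation_step is not None else np.nan
        )
    return row


def run_ensemble(config: dict) -> EnsembleSummary:
    """Run ``replicates`` seeded copies of one experiment.

    Replicate ``r`` uses seed ``seed + r``, so the whole ensemble is
    reproducible from the configuration alone. Unknown configuration keys
    raise a named error rather than being ignored.
    """
    unknown = set(config) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    model = config.get("model", "neutral")
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    replicates = int(config.get("replicates", 1))
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    params = _params_from_config(config)
    base_seed = int(config.get("seed", 0))
    rows = []
    for r in range(replicates):
        seed = base_seed + r
        row = {"replicate": r, "seed": seed}
        row.update(_replicate_row(model, params, config, seed))
        rows.append(row)
    per_replicate = pd.DataFrame(rows)
    return EnsembleSummary(
        config=dict(config),
        per_replicate=per_replicate,
        aggregate=aggregate_statistics(per_replicate),
    )


@dataclass(frozen=True)
class AnalyticPrediction:
    """All closed-form quantities for one parameter set, in one record.

    Fields that are undefined for the given rates (e.g. tau_eq at nu = 0)
    are ``None``. Times are reported in steps and meta-generations.
    """

    M: int
    nu: float
    p_m: float
    p_h: float
    omega: float
    theta: Optional[float]
    S0_exact: Optional[float]
    S0_approx: Optional[float]
    tau_eq_steps: Optional[float]
    tau_eq_gen: Optional[float]
    tau_fix_steps: Optional[float]
    tau_fix_gen: Optional[float]
    Q0: Optional[float]
    omega0: Optional[float]
    x1: Optional[float]
    x2: Optional[float]
    regime: Optional[str]

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "AnalyticPrediction":
        return cls(**json.loads(text))


def analytic_report(params: ModelParams) -> AnalyticPrediction:
    """Evaluate every closed form that is defined for ``params``."""
    M, nu, p_m, p_h = params.M, params.nu, params.p_m, params.p_h
    has_nu = 0.0 < nu < 1.0
    has_sweep = p_m + p_h > 0
    t_eq = tau_eq(M, nu) if nu > 0 else None
    t_fix = tau_fix(M, p_m, p_h) if has_sweep else None
    regime = None
    x1 = x2 = w0 = None
    if t_eq is not None and t_fix is not None:
        w0 = omega0(M, nu, p_m, p_h)
        report = classify_regime(params.omega, t_fix, t_eq)
        x1, x2, regime = report.x1, report.x2, report.label
    return AnalyticPrediction(
        M=M,
        nu=nu,
        p_m=p_m,
        p_h=p_h,
        omega=params.omega,
        theta=theta(M, nu),
        S0_exact=expected_diversity_exact(M, nu) if has_nu else None,
        S0_approx=expected_diversity_approx(M, nu) if has_nu else None,
        tau_eq_steps=t_eq,
        tau_eq_gen=t_eq / M if t_eq is not None else None,
        tau_fix_steps=t_fix,
        tau_fix_gen=t_fix / M if t_fix is not None else None,
        Q0=sweep_parameter_Q0(nu, p_m, p_h) if (has_nu and has_sweep) else None,
        omega0=w0,
        x1=x1,
        x2=x2,
        regime=regime,
    )


# --------------------------------------------------------------------------
# presets: the headline experiments at publication scale (M = 10^4) and at a
# desk scale (M = 10^3, identical rates) that runs in seconds


def _fig_configs(M: int) -> dict[str, dict]:
    def steps_eq(nu, mult=3):
        return int(mult * M / nu)

    base = {"M": M, "record_every": M, "replicates": 100, "seed": 0}
    w0 = omega0(M, 0.01, 0.9, 0.1)
    return {
        "fig2": {
            **base, "model": "neutral", "nu": 0.01, "pm": 0.0, "ph": 0.0,
            "omega": 0.0, "arrival_mode": "none", "steps": steps_eq(0.01),
        },
        "fig3": {
            **base, "model": "sweep", "nu": 0.02, "pm": 0.8, "ph": 0.2,
            "omega": 0.0, "arrival_mode": "none", "steps": 0,
        },
        "fig4-single": {
            **base, "model": "full", "nu": 0.01, "pm": 0.9, "ph": 0.1,
            "omega": 0.0, "arrival_mode": "single", "steps": steps_eq(0.01, 5),
        },
        "fig4-periodic": {
            **base, "model": "full", "nu": 0.01, "pm": 0.9, "ph": 0.1,
            "omega": w0, "arrival_mode": "periodic", "steps": steps_eq(0.01, 5),
        },
        "fig4-poisson": {
            **base, "model": "full", "nu": 0.01, "pm": 0.9, "ph": 0.1,
            "omega": w0, "arrival_mode": "poisson", "steps": steps_eq(0.01, 5),
        },
    }


PRESET_NAMES = tuple(_fig_configs(10_000))


def preset(name: str, scale: str = "desk") -> dict:
    """Named experiment configuration at ``paper`` or ``desk`` scale.

    Paper scale uses M = 10000 as in the headline experiments; desk scale
    substitutes M = 1000 with all rates unchanged and 100 replicates.
    """
    if scale not in ("paper", "desk"):
        raise ValueError(f"scale must be 'paper' or 'desk', got {scale!r}")
    M = 10_000 if scale == "paper" else 1_000
    configs = _fig_configs(M)
    if name not in configs:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(configs))}"
        )
    return configs[name]
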