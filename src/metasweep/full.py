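"""Full model: innovation, neutral sweeps, selective sweeps, gene arrivals.

Three forces act per step: innovation (rate ``nu``; the new species carries
the gene with probability ``f0 = B/M``), neutral migration-sweeps between
same-carrier-status patches (joint rate ``1 - nu``), and selective
migration/HGT-sweeps from carrier to non-carrier patches (probabilities
``p_m`` and ``p_h``). Beneficial genes can arrive once, periodically, or as
a Poisson stream with frequency ``omega``; the newest gene always confers
the largest advantage, so each arrival clears all carrier flags and seeds
one uniformly chosen patch (older genes are dynamically inert).

The competition between the fixation time ``tau_fix`` and the neutral
equilibration time ``tau_eq`` sets four qualitative regimes, indexed by the
dimensionless numbers ``omega * (tau_fix + tau_eq)`` and ``tau_fix/tau_eq``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .core import (
    EpisodeSummary,
    MetacommunityState,
    ModelParams,
    Trajectory,
    _as_rng,
    _kernel_seed,
    new_monomorphic_state,
    sample_equilibrium_state,
)
from .neutral import tau_eq
from .sweep import tau_fix

__all__ = [
    "full_step",
    "schedule_arrivals",
    "apply_gene_arrival",
    "run_full",
    "omega0",
    "classify_regime",
    "RegimeReport",
]


def full_step(state: MetacommunityState, params: ModelParams, rng) -> dict:
    """Apply one elementary event of the full dynamics in place.

    Event menu: innovation (probability ``nu``; Bernoulli(B/M) carrier flag
    for the new species), neutral migration-sweep for same-status pairs,
    selective migration-sweep / HGT-sweep for carrier -> non-carrier pairs,
    no-op otherwise. Returns an event record dict.
    """
    rng = _as_rng(rng)
    M = state.M
    state.step += 1
    if rng.random() < params.nu:
        i = int(rng.integers(M))
        f0 = state.B / M
        new_carrier = bool(rng.random() < f0)
        was_carrier = bool(state.patch_carrier[i])
        label = state.innovate(i)
        state.patch_carrier[i] = new_carrier
        return {
            "event": "innovation",
            "patch": i,
            "label": label,
            "carrier": new_carrier,
            "displaced_carrier": was_carrier,
        }
    i = int(rng.integers(M))
    j = int(rng.integers(M - 1))
    if j >= i:
        j += 1
    ci = bool(state.patch_carrier[i])
    cj = bool(state.patch_carrier[j])
    if ci == cj:
        state.copy_species(i, j)
        return {"event": "neutral_migration", "source": i, "target": j}
    if ci:
        u = rng.random()
        if u < params.p_m:
            state.copy_species(i, j)
            state.patch_carrier[j] = True
            return {"event": "migration_sweep", "source": i, "target": j}
        if u < params.p_m + params.p_h:
            state.patch_carrier[j] = True
            return {"event": "hgt_sweep", "source": i, "target": j}
    return {"event": "noop", "source": i, "target": j}


def schedule_arrivals(omega: float, mode: str, horizon: int, rng=None) -> np.ndarray:
    """Ordered beneficial-gene arrival steps within ``[0, horizon]``.

    ``single`` -> [0]; ``periodic`` -> multiples of round(1/omega);
    ``poisson`` -> cumulative geometric gaps with mean 1/omega (the
    discrete-time analogue of exponential waiting times).
    """
    if mode == "none":
        return np.empty(0, dtype=np.int64)
    if mode == "single":
        return np.zeros(1, dtype=np.int64)
    if mode not in ("periodic", "poisson"):
        raise ValueError(f"unknown arrival mode {mode!r}")
    if omega <= 0:
        raise ValueError(f"{mode} arrivals require omega > 0")
    if mode == "periodic":
        period = max(1, int(round(1.0 / omega)))
        return np.arange(0, horizon + 1, period, dtype=np.int64)
    rng = _as_rng(rng)
    # expected count ~ omega * horizon; draw with margin, then trim
    n_draw = max(16, int(omega * horizon + 6 * math.sqrt(omega * horizon) + 16))
    steps = np.cumsum(rng.geometric(min(omega, 1.0), size=n_draw))
    while steps[-1] <= horizon:
        extra = np.cumsum(rng.geometric(min(omega, 1.0), size=n_draw)) + steps[-1]
        steps = np.concatenate([steps, extra])
    return steps[steps <= horizon].astype(np.int64)


def apply_gene_arrival(state: MetacommunityState, rng=None, patch: Optional[int] = None):
    """A new (fitter) beneficial gene arrives: reset carriers, seed one patch.

    All existing carrier flags are cleared (the newest gene dominates), one
    patch becomes the sole carrier, and ``arrivals_seen`` is incremented.
    Species labels are untouched, so S is unchanged.
    """
    state.patch_carrier[:] = False
    if patch is None:
        patch = int(_as_rng(rng).integers(state.M))
    state.patch_carrier[patch] = True
    state.arrivals_seen += 1
    return state


def run_full(
    params: ModelParams,
    rng=None,
    initial_state: Optional[MetacommunityState] = None,
    init_nu: Optional[float] = None,
) -> tuple[Trajectory, list[EpisodeSummary]]:
    """Simulate the full dynamics with scheduled gene arrivals.

    The initial state defaults to an exact neutral-equilibrium draw at
    ``init_nu`` (itself defaulting to ``params.nu``; a monomorphic state is
    used when that is 0). If ``initial_state`` is given it is advanced in
    place, which allows chunked runs. Returns the sampled trajectory and one
    :class:`EpisodeSummary` per inter-arrival window (a single window spans
    the whole run when there are no arrivals).
    """
    rng = _as_rng(params.seed if rng is None else rng)
    if initial_state is None:
        nu0 = params.nu if init_nu is None else init_nu
        if nu0 > 0:
            state = sample_equilibrium_state(params.M, nu0, rng)
        else:
            state = new_monomorphic_state(params.M)
    else:
        state = initial_state
        if state.M != params.M:
            raise ValueError("initial_state has a different M than params")
    arrivals = schedule_arrivals(params.omega, params.arrival_mode, params.n_steps, rng)
    step0 = state.step
    counts = state.counts_array(state.next_label + params.n_steps + 1)
    (
        rec_step, rec_S, rec_B, rec_A,
        ep_start, ep_end, ep_Sstart, ep_Smin, ep_Sminfix, ep_Smax,
        ep_Ssum, ep_n, ep_Send, ep_fix,
        S, B, next_label, arrivals_seen,
    ) = _kernels.full_run(
        state.patch_species, counts, state.patch_carrier,
        state.S, state.B, state.next_label,
        params.nu, params.p_m, params.p_h,
        arrivals, params.n_steps, params.record_every,
        _kernel_seed(rng), state.arrivals_seen,
    )
    state.sync_from_counts(counts, next_label)
    state.step = step0 + params.n_steps
    state.arrivals_seen = int(arrivals_seen)
    traj = Trajectory(
        M=params.M,
        step=rec_step + step0,
        S=rec_S,
        B=rec_B,
        arrivals_seen=rec_A,
    )
    episodes = [
        EpisodeSummary(
            window=(step0 + int(ep_start[e]), step0 + int(ep_end[e])),
            S_start=int(ep_Sstart[e]),
            S_min=int(ep_Smin[e]),
            S_max=int(ep_Smax[e]),
            S_mean=float(ep_Ssum[e] / ep_n[e]) if ep_n[e] else float(ep_Sstart[e]),
            S_end=int(ep_Send[e]),
            S_min_to_fixation=int(ep_Sminfix[e]),
            fixation_step=(step0 + int(ep_fix[e])) if ep_fix[e] >= 0 else None,
            truncated=ep_fix[e] < 0,
        )
        for e in range(len(ep_start))
    ]
    return traj, episodes


def omega0(M: int, nu: float, p_m: float, p_h: float) -> float:
    """Critical arrival frequency ``1 / (tau_fix + tau_eq)`` per step.

    Above it, diversity cannot fully recover between successive gene
    arrivals.
    """
    return 1.0 / (tau_fix(M, p_m, p_h) + tau_eq(M, nu))


@dataclass(frozen=True)
class RegimeReport:
    """Qualitative regime for the long-run diversity dynamics.

    ``x1 = omega * (tau_fix + tau_eq)`` compares the inter-arrival time with
    the time to fix a gene and re-equilibrate; ``x2 = tau_fix / tau_eq``
    says which of sweep and restoration is slower. The label and the
    predicted extremes (in terms of the neutral equilibrium S0 and the sweep
    parameter Q0) depend only on whether each number is below 1.
    """

    omega0: float
    x1: float
    x2: float
    label: str
    S_max_prediction: str
    S_min_prediction: str

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def classify_regime(omega: float, tau_fix_steps: float, tau_eq_steps: float) -> RegimeReport:
    """Classify (arrival frequency, time scales) into one of four regimes."""
    if tau_fix_steps <= 0 or tau_eq_steps <= 0:
        raise ValueError("time scales must be positive")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    x1 = omega * (tau_fix_steps + tau_eq_steps)
    x2 = tau_fix_steps / tau_eq_steps
    recovery = x1 < 1  # sparse arrivals: full recovery between sweeps
    deep = x2 < 1      # restoration slower than the sweep: full-depth minimum
    label = ("full-recovery" if recovery else "suppressed-recovery") + "/" + (
        "deep-sweep" if deep else "buffered-sweep"
    )
    return RegimeReport(
        omega0=1.0 / (tau_fix_steps + tau_eq_steps),
        x1=x1,
        x2=x2,
        label=label,
        S_max_prediction="S0" if recovery else "<S0",
        S_min_prediction="Q0*S0" if deep else ">Q0*S0",
    )
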