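"""Spread of a single beneficial gene with no diversity restoration.

After the gene lands on one patch, only carrier -> non-carrier pair events
act: migration-sweep (probability ``p_m``) replaces the resident species and
removes diversity; HGT-sweep (probability ``p_h``) transfers the gene into
the resident species and preserves diversity. The carrier count grows
logistically and absorbs at ``B = M`` after ``tau_fix ~ 2 M ln M / (p_m+p_h)``
steps; the expected residual fraction of diversity is the sweep parameter

    Q0 = 1 - ln(1 - (1-nu) exp(-p_h/p_m)) / ln(nu),

where ``nu`` is the innovation rate of the neutral model that generated the
initial species partition (it plays no dynamical role here). ``Q0 = 0`` is a
full genome-wide sweep; ``Q0 = 1`` preserves all diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import _kernels
from .core import (
    EpisodeSummary,
    MetacommunityState,
    Trajectory,
    _as_rng,
    _kernel_seed,
)

__all__ = [
    "introduce_gene",
    "sweep_step",
    "run_until_fixation",
    "carriers_logistic",
    "tau_fix",
    "noncarrier_species_decay",
    "expected_total_gains",
    "extinction_probability",
    "fisher_logseries_pmf",
    "sweep_parameter_Q0",
    "SweepAnalytics",
    "sweep_analytics",
]


# --------------------------------------------------------------------------
# stochastic dynamics


def introduce_gene(state: MetacommunityState, rng=None, patch: Optional[int] = None):
    """Seed the beneficial gene on one patch (B: 0 -> 1), in place."""
    if state.B > 0:
        raise ValueError("beneficial gene already present (B > 0)")
    if patch is None:
        patch = int(_as_rng(rng).integers(state.M))
    state.patch_carrier[patch] = True
    state.arrivals_seen += 1
    return state


def sweep_step(state: MetacommunityState, p_m: float, p_h: float, rng) -> dict:
    """Apply one elementary event of the single-gene sweep dynamics in place.

    Draws an ordered pair (i, j), i != j. Only carrier -> non-carrier pairs
    can act; everything else (including non-carrier -> carrier) is a no-op,
    so selection protects carriers from displacement.
    """
    if p_m + p_h > 1.0 + 1e-12:
        raise ValueError("p_m + p_h must not exceed 1")
    rng = _as_rng(rng)
    M = state.M
    i = int(rng.integers(M))
    j = int(rng.integers(M - 1))
    if j >= i:
        j += 1
    state.step += 1
    if state.patch_carrier[i] and not state.patch_carrier[j]:
        u = rng.random()
        if u < p_m:
            state.copy_species(i, j)
            state.patch_carrier[j] = True
            return {"event": "migration_sweep", "source": i, "target": j}
        if u < p_m + p_h:
            state.patch_carrier[j] = True
            return {"event": "hgt_sweep", "source": i, "target": j}
    return {"event": "noop", "source": i, "target": j}


def run_until_fixation(
    state: MetacommunityState,
    p_m: float,
    p_h: float,
    rng=None,
    record_every: int = 1,
    max_steps: Optional[int] = None,
) -> tuple[Trajectory, EpisodeSummary]:
    """Iterate the sweep dynamics until B = M (absorbing) or ``max_steps``.

    Requires exactly one carrier at entry. The summary reports the initial
    and final diversity (S_i, S_f) and the empirical fixation step; if the
    horizon is hit first, ``truncated`` is set instead of raising.
    """
    if state.B != 1:
        raise ValueError("run_until_fixation requires exactly one carrier (B = 1)")
    if p_m + p_h <= 0:
        raise ValueError("p_m + p_h must be positive to reach fixation")
    rng = _as_rng(rng)
    if max_steps is None:
        max_steps = int(50 * tau_fix(state.M, p_m, p_h)) + 1
    step0 = state.step
    counts = state.counts_array(state.next_label)
    (rec_step, rec_S, rec_B, S, B, fix, s_sum, n_sum, steps_done) = _kernels.sweep_run(
        state.patch_species, counts, state.patch_carrier,
        state.S, state.B, p_m, p_h, max_steps, record_every, _kernel_seed(rng),
    )
    S_i = int(rec_S[0])
    state.sync_from_counts(counts, state.next_label)
    state.step = step0 + int(steps_done)
    traj = Trajectory(
        M=state.M,
        step=rec_step + step0,
        S=rec_S,
        B=rec_B,
        arrivals_seen=np.full_like(rec_S, state.arrivals_seen),
    )
    summary = EpisodeSummary(
        window=(step0, step0 + int(steps_done)),
        S_start=S_i,
        S_min=int(rec_S.min()),
        S_max=int(rec_S.max()),
        S_mean=float(s_sum / n_sum) if n_sum else float(S_i),
        S_end=int(S),
        S_min_to_fixation=int(S),
        fixation_step=(step0 + int(fix)) if fix >= 0 else None,
        truncated=fix < 0,
    )
    return traj, summary


# --------------------------------------------------------------------------
# closed forms


def carriers_logistic(t, M: int, p_m: float, p_h: float):
    """Deterministic carrier count ``B(t) = M / (1 + (M-1) e^{-rt})``.

    ``r = (p_m + p_h)/M``; B(0) = 1, monotone increasing, -> M. This is the
    solution of the logistic growth dB/dt = (p_m+p_h) (B/M) (1 - B/M).
    """
    r = (p_m + p_h) / M
    t = np.asarray(t, dtype=float)
    out = M / (1.0 + (M - 1) * np.exp(-r * t))
    return float(out) if out.ndim == 0 else out


def tau_fix(M: int, p_m: float, p_h: float) -> float:
    """Expected fixation time ``2 M ln(M-1) / (p_m + p_h)`` steps.

    Obtained by imposing B(tau_fix) = M - 1 on the logistic carrier curve.
    """
    if p_m + p_h <= 0:
        raise ValueError("p_m + p_h = 0: fixation time is infinite")
    return 2.0 * M * math.log(M - 1) / (p_m + p_h)


def noncarrier_species_decay(t, M: int, m0: float, p_m: float, p_h: float):
    """Expected non-carrier patch count of a focal species during the sweep.

    Solves dD/dt = -p_m (B(t)/M) (D/M) with D(0) = m0 and B(t) the logistic
    carrier curve:

        D(t) = m0 * (M / (e^{rt} + M - 1))^{p_m/(p_m+p_h)},

    evaluated in log space for numerical stability at large ``rt``.
    """
    t = np.asarray(t, dtype=float)
    if p_m + p_h <= 0 or p_m == 0:
        out = np.full_like(t, float(m0))
        return float(out) if out.ndim == 0 else out
    r = (p_m + p_h) / M
    a = p_m / (p_m + p_h)
    log_d = math.log(m0) + a * (math.log(M) - np.logaddexp(r * t, math.log(M - 1)))
    out = np.exp(log_d)
    return float(out) if out.ndim == 0 else out


def expected_total_gains(m0: float, p_m: float, p_h: float) -> float:
    """Expected number of HGT gains for a species starting on m0 patches.

    ``G_tot = m0 * p_h / p_m``: integrating the gain rate
    p_h (B/M) (D/M) over the whole sweep.
    """
    if p_m <= 0:
        raise ValueError("p_m = 0: expected gains diverge (no displacement)")
    return m0 * p_h / p_m


def extinction_probability(m0: float, p_m: float, p_h: float) -> float:
    """Probability the focal species never gains the gene: ``exp(-m0 p_h/p_m)``.

    Poisson approximation for the number of gains with mean G_tot; p_h = 0
    gives certain extinction of non-carrier species.
    """
    if p_m <= 0:
        raise ValueError("p_m = 0: every non-carrier species survives")
    if m0 < 0:
        raise ValueError("m0 must be >= 0")
    return math.exp(-m0 * p_h / p_m)


def fisher_logseries_pmf(m0, nu: float):
    """Fisher log-series mass ``-(1/ln nu) (1-nu)^m0 / m0`` for m0 >= 1.

    Large-M, small-nu limit of the (normalised) Ewens abundance spectrum;
    sums to 1 exactly over m0 >= 1.
    """
    if not (0.0 < nu < 1.0):
        raise ValueError(f"nu must lie in (0, 1), got {nu}")
    m = np.asarray(m0)
    if np.any(m < 1):
        raise ValueError("m0 must be >= 1")
    out = -(np.power(1.0 - nu, m) / m) / math.log(nu)
    return float(out) if out.ndim == 0 else out


def sweep_parameter_Q0(nu: float, p_m: float, p_h: float) -> float:
    """Expected residual diversity fraction after fixation of the gene.

    ``Q0 = 1 - ln(1 - (1-nu) e^{-p_h/p_m}) / ln(nu)``; depends on the rates
    only through the ratio ``p_h/p_m``. The ``p_m = 0`` limit is a pure
    genome-wide sweep chain with ``Q0 -> 1`` only formally via ``p_h/p_m ->
    inf``; here ``p_m = 0`` with ``p_h > 0`` returns that limit (1.0).
    """
    if not (0.0 < nu < 1.0):
        raise ValueError(f"nu must lie in (0, 1), got {nu}")
    if p_h < 0 or p_m < 0:
        raise ValueError("rates must be >= 0")
    if p_m == 0:
        if p_h == 0:
            raise ValueError("p_m = p_h = 0: sweep parameter undefined")
        return 1.0
    if p_h == 0:
        return 0.0  # pure genome-wide sweep; exact limit of the closed form
    ratio = p_h / p_m
    q = 1.0 - math.log1p(-(1.0 - nu) * math.exp(-ratio)) / math.log(nu)
    # the closed form lies in [0, 1]; clip the ~1 ulp error of the ratio->0 limit
    return min(1.0, max(0.0, q))


@dataclass(frozen=True)
class SweepAnalytics:
    """Bundle of the closed-form sweep predictions for one parameter set."""

    M: int
    nu: float
    p_m: float
    p_h: float
    tau_fix_steps: float
    Q0: float
    B_of_t: Callable
    P_ext: Callable
    G_tot: Callable


def sweep_analytics(M: int, nu: float, p_m: float, p_h: float) -> SweepAnalytics:
    return SweepAnalytics(
        M=M,
        nu=nu,
        p_m=p_m,
        p_h=p_h,
        tau_fix_steps=tau_fix(M, p_m, p_h),
        Q0=sweep_parameter_Q0(nu, p_m, p_h),
        B_of_t=lambda t: carriers_logistic(t, M, p_m, p_h),
        P_ext=lambda m0: extinction_probability(m0, p_m, p_h),
        G_tot=lambda m0: expected_total_gains(m0, p_m, p_h),
    )
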