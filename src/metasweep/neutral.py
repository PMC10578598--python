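"""Hubbell-type infinite-allele diversity dynamics and its equilibrium theory.

The diversity-maintenance ("null") model: per step, a uniformly chosen focal
patch either undergoes innovation (fresh species label) with probability
``nu`` or sweeps a uniformly chosen other patch neutrally. The stationary
species partition is the Ewens distribution with concentration
``theta = (M-1) * nu / (1-nu)`` (the fundamental biodiversity number), which
gives closed forms for the expected equilibrium diversity and abundance
spectrum, and an equilibration time ``tau_eq ~ M/nu`` steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from . import _kernels
from .core import (
    MetacommunityState,
    ModelParams,
    Trajectory,
    _as_rng,
    _kernel_seed,
    new_monomorphic_state,
)

__all__ = [
    "theta",
    "expected_diversity_exact",
    "expected_diversity_approx",
    "ewens_expected_abundance",
    "tau_eq",
    "neutral_step",
    "run_neutral",
    "AnalyticPredictionNeutral",
    "neutral_analytics",
]


def theta(M: int, nu: float) -> float:
    """Fundamental biodiversity number ``(M-1) * nu / (1-nu)``."""
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    if not (0.0 <= nu < 1.0):
        raise ValueError(f"nu must lie in [0, 1), got {nu}")
    return (M - 1) * nu / (1.0 - nu)


def expected_diversity_exact(M: int, nu: float) -> float:
    """Exact expected equilibrium diversity ``sum_{i=0}^{M-1} theta/(theta+i)``.

    Evaluated stably as ``theta * (psi(theta+M) - psi(theta))`` with the
    digamma function, which equals the finite sum identically.
    """
    if not (0.0 < nu < 1.0):
        raise ValueError(f"nu must lie in (0, 1), got {nu}")
    th = theta(M, nu)
    return float(th * (digamma(th + M) - digamma(th)))


def expected_diversity_approx(M: int, nu: float) -> float:
    """Large-M, small-nu approximation ``-M * nu * ln(nu)``."""
    if not (0.0 < nu < 1.0):
        raise ValueError(f"nu must lie in (0, 1), got {nu}")
    return -M * nu * math.log(nu)


def ewens_expected_abundance(M: int, nu: float, n) -> float | np.ndarray:
    """Expected number of species occupying exactly ``n`` patches at equilibrium.

    ``(theta/n) * Gamma(M+1) Gamma(M+theta-n) / (Gamma(M+1-n) Gamma(M+theta))``,
    computed through log-gamma differences. Accepts scalar or array ``n``.
    """
    if not (0.0 < nu < 1.0):
        raise ValueError(f"nu must lie in (0, 1), got {nu}")
    n_arr = np.asarray(n)
    if np.any((n_arr < 1) | (n_arr > M)):
        raise ValueError(f"n must lie in [1, M], got {n}")
    th = theta(M, nu)
    log_val = (
        math.log(th)
        - np.log(n_arr)
        + gammaln(M + 1)
        + gammaln(M + th - n_arr)
        - gammaln(M + 1 - n_arr)
        - gammaln(M + th)
    )
    out = np.exp(log_val)
    return float(out) if np.isscalar(n) else out


def tau_eq(M: int, nu: float) -> float:
    """Equilibration time of the neutral diversity, ``M / nu`` steps."""
    if nu <= 0:
        raise ValueError("nu = 0: equilibration time is infinite")
    return M / nu


def neutral_step(state: MetacommunityState, nu: float, rng) -> dict:
    """Apply one elementary event of the neutral dynamics in place.

    Returns an event record: ``{"event": "innovation", "patch", "label"}`` or
    ``{"event": "neutral_migration", "source", "target"}``.
    """
    if not (0.0 <= nu < 1.0):
        raise ValueError(f"nu must lie in [0, 1), got {nu}")
    rng = _as_rng(rng)
    M = state.M
    i = int(rng.integers(M))
    state.step += 1
    if rng.random() < nu:
        label = state.innovate(i)
        return {"event": "innovation", "patch": i, "label": label}
    j = int(rng.integers(M - 1))
    if j >= i:
        j += 1
    state.copy_species(i, j)
    return {"event": "neutral_migration", "source": i, "target": j}


def run_neutral(params: ModelParams, rng=None) -> Trajectory:
    """Simulate the neutral model from a monomorphic start (S(0) = 1)."""
    if params.arrival_mode != "none":
        raise ValueError("run_neutral requires arrival_mode='none'")
    rng = _as_rng(params.seed if rng is None else rng)
    state = new_monomorphic_state(params.M)
    counts = state.counts_array(state.next_label + params.n_steps + 1)
    rec_step, rec_S, S, next_label = _kernels.neutral_run(
        state.patch_species, counts, state.S, state.next_label,
        params.nu, params.n_steps, params.record_every, _kernel_seed(rng),
    )
    state.sync_from_counts(counts, next_label)
    state.step += params.n_steps
    return Trajectory(
        M=params.M,
        step=rec_step,
        S=rec_S,
        B=np.zeros_like(rec_S),
        arrivals_seen=np.zeros_like(rec_S),
    )


@dataclass(frozen=True)
class AnalyticPredictionNeutral:
    """Equilibrium predictions of the neutral model for one parameter set."""

    theta: float
    S0_exact: float
    S0_approx: float
    tau_eq_steps: float
    tau_eq_gen: float


def neutral_analytics(M: int, nu: float) -> AnalyticPredictionNeutral:
    return AnalyticPredictionNeutral(
        theta=theta(M, nu),
        S0_exact=expected_diversity_exact(M, nu),
        S0_approx=expected_diversity_approx(M, nu),
        tau_eq_steps=tau_eq(M, nu),
        tau_eq_gen=tau_eq(M, nu) / M,
    )
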