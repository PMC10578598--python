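"""Shared state and parameter containers for the metacommunity sweep models.

The model world is a set of ``M`` habitat patches. Each patch is occupied by
exactly one species, encoded as a non-negative integer label under the
infinite-allele convention (every innovation event mints a fresh label, so a
new species can never collide with an existing one). A patch may additionally
carry the currently sweeping beneficial gene; the number of carrier patches is
``B`` and the metacommunity diversity ``S`` is the number of distinct labels
present (``1 <= S <= M``).

Time is discrete: exactly one candidate event is drawn per elementary step,
and all rates (innovation ``nu``, migration-sweep ``p_m``, HGT-sweep ``p_h``)
are per-step probabilities. A "meta-generation" is ``M`` steps, i.e. one
expected event per patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels

__all__ = [
    "ARRIVAL_MODES",
    "ModelParams",
    "MicroRates",
    "MetacommunityState",
    "Trajectory",
    "EpisodeSummary",
    "new_monomorphic_state",
    "sample_equilibrium_state",
    "equilibrate_state",
    "diversity",
    "effective_rates",
    "validate_timescale_separation",
]

ARRIVAL_MODES = ("none", "single", "periodic", "poisson")


def _as_rng(rng) -> np.random.Generator:
    """Accept a Generator, an integer seed, or None (fresh entropy)."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _kernel_seed(rng: np.random.Generator) -> int:
    """Draw a 31-bit seed for a compiled event loop from a Generator."""
    return int(rng.integers(0, 2**31))


@dataclass(frozen=True)
class ModelParams:
    """Macroscopic rates and run controls for one simulation.

    Parameters
    ----------
    M:
        Number of patches (>= 2).
    nu:
        Innovation probability per step, in [0, 1). Each step is an
        innovation with probability ``nu``, otherwise a pair event.
    p_m, p_h:
        Migration-sweep and HGT-sweep probabilities applied when the drawn
        ordered pair is carrier -> non-carrier. ``p_m + p_h <= 1``; any
        remainder is a per-step no-op (the absolute time scale is kept so
        that the fixation time stays proportional to ``1/(p_m+p_h)``).
    omega:
        Beneficial-gene arrival frequency per step (used by the periodic
        and poisson arrival modes).
    arrival_mode:
        One of ``none``, ``single``, ``periodic``, ``poisson``.
    n_steps:
        Simulation horizon in elementary steps.
    record_every:
        Trajectory sampling stride in steps (>= 1).
    seed:
        Base seed; a run is fully determined by (params, seed). Replicate
        ``r`` of an ensemble uses ``seed + r``.
    """

    M: int
    nu: float = 0.0
    p_m: float = 0.0
    p_h: float = 0.0
    omega: float = 0.0
    arrival_mode: str = "none"
    n_steps: int = 0
    record_every: int = 1
    seed: int = 0

    def __post_init__(self):
        if int(self.M) != self.M or self.M < 2:
            raise ValueError(f"M must be an integer >= 2, got {self.M}")
        if not (0.0 <= self.nu < 1.0):
            raise ValueError(f"nu must lie in [0, 1), got {self.nu}")
        for name in ("p_m", "p_h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_m + self.p_h > 1.0 + 1e-12:
            raise ValueError(
                f"p_m + p_h must not exceed 1, got {self.p_m + self.p_h}"
            )
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if self.arrival_mode not in ARRIVAL_MODES:
            raise ValueError(
                f"arrival_mode must be one of {ARRIVAL_MODES}, got {self.arrival_mode!r}"
            )
        if self.arrival_mode in ("periodic", "poisson") and self.omega <= 0:
            raise ValueError(f"{self.arrival_mode} arrivals require omega > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MicroRates:
    """Microscopic (within-patch, per-generation) rates.

    ``N`` individuals per patch, selection coefficient ``s`` of the
    beneficial gene, and basal migration / HGT / innovation-arrival rates
    ``mu_m``, ``mu_h``, ``mu_I``. Under time-scale separation these map onto
    the patch-level per-step probabilities ``p_m = s*mu_m`` and
    ``p_h = s*mu_h`` (the factor ``s`` is the within-patch fixation
    probability of the beneficial variant).
    """

    N: int
    s: float
    mu_m: float = 0.0
    mu_h: float = 0.0
    mu_I: float = 0.0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if not (0.0 < self.s < 1.0):
            raise ValueError(f"s must lie in (0, 1), got {self.s}")
        for name in ("mu_m", "mu_h", "mu_I"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def effective_rates(micro: MicroRates) -> tuple[float, float]:
    """Map microscopic rates to per-step sweep probabilities.

    Returns ``(p_m, p_h) = (s*mu_m, s*mu_h)``. Raises if the sum exceeds 1,
    in which case the products cannot be interpreted as per-step
    probabilities.
    """
    p_m = micro.s * micro.mu_m
    p_h = micro.s * micro.mu_h
    if p_m + p_h > 1.0:
        raise ValueError(
            f"s*mu_m + s*mu_h = {p_m + p_h:.4g} > 1: not valid per-step probabilities"
        )
    return p_m, p_h


def validate_timescale_separation(
    micro: MicroRates, separation_factor: float = 10.0
) -> list[str]:
    """Check the time-scale hierarchy behind the patch-level model.

    The patch-level description assumes three separated time scales:
    within-patch fixation of a beneficial variant (rate ~ s/log(Ns)), sweeps
    across patches (rates s*mu_m ~ s*mu_h), and neutral turnover /
    innovation (rates mu_m/N ~ mu_I/N), together with 1/N << s << 1 and
    mu_I ~ mu_m ~ mu_h << 1/log(Ns).

    ``<<`` / ``>>`` are operationalised as a ratio of at least
    ``separation_factor`` (default 10), and ``~`` as a ratio within
    ``[1/separation_factor, separation_factor]``. Returns one human-readable
    entry per violated inequality; an empty list means the hierarchy holds.
    """
    if separation_factor <= 1:
        raise ValueError("separation_factor must be > 1")
    Ns = micro.N * micro.s
    if Ns <= 1:
        raise ValueError(f"N*s = {Ns:.4g} <= 1: log(Ns) is not positive")
    f = separation_factor
    L = math.log(Ns)
    out: list[str] = []

    def much_less(a, b, label):
        # a << b; a == 0 counts as infinitely smaller than b > 0
        if a == 0 and b > 0:
            return
        if a == 0 or b / a < f:
            out.append(f"{label}: ratio {b / a if a else float('nan'):.3g} < {f:g}")

    def approx(a, b, label):
        if a == 0 and b == 0:
            return
        if a == 0 or b == 0 or not (1 / f <= a / b <= f):
            r = a / b if b else float("inf")
            out.append(f"{label}: ratio {r:.3g} outside [{1/f:g}, {f:g}]")

    much_less(1 / micro.N, micro.s, "1/N << s")
    much_less(micro.s, 1.0, "s << 1")
    much_less(micro.s * micro.mu_m, micro.s / L, "s*mu_m << s/log(Ns)")
    much_less(micro.s * micro.mu_h, micro.s / L, "s*mu_h << s/log(Ns)")
    approx(micro.s * micro.mu_m, micro.s * micro.mu_h, "s*mu_m ~ s*mu_h")
    if micro.mu_m > 0:
        much_less(micro.mu_m / micro.N, micro.s * micro.mu_m, "mu_m/N << s*mu_m")
    if micro.mu_I > 0 or micro.mu_h > 0:
        much_less(micro.mu_I / micro.N, micro.s * micro.mu_h, "mu_I/N << s*mu_h")
    approx(micro.mu_m / micro.N, micro.mu_I / micro.N, "mu_m/N ~ mu_I/N")
    much_less(micro.mu_I, 1 / L, "mu_I << 1/log(Ns)")
    much_less(micro.mu_m, 1 / L, "mu_m << 1/log(Ns)")
    much_less(micro.mu_h, 1 / L, "mu_h << 1/log(Ns)")
    return out


@dataclass
class MetacommunityState:
    """Mutable metacommunity configuration with incremental bookkeeping.

    ``species_counts`` maps species label -> number of occupied patches and
    is kept consistent with ``patch_species`` by every mutator, so diversity
    is O(1) to read. ``next_label`` is the infinite-allele counter: every
    label in use is strictly below it and innovation never reuses a label.
    """

    patch_species: np.ndarray
    patch_carrier: np.ndarray
    species_counts: dict[int, int]
    next_label: int
    step: int = 0
    arrivals_seen: int = 0

    @property
    def M(self) -> int:
        return int(self.patch_species.shape[0])

    @property
    def S(self) -> int:
        return len(self.species_counts)

    @property
    def B(self) -> int:
        return int(self.patch_carrier.sum())

    def copy(self) -> "MetacommunityState":
        return MetacommunityState(
            patch_species=self.patch_species.copy(),
            patch_carrier=self.patch_carrier.copy(),
            species_counts=dict(self.species_counts),
            next_label=self.next_label,
            step=self.step,
            arrivals_seen=self.arrivals_seen,
        )

    # -- incremental mutators ------------------------------------------------

    def _decrement(self, label: int) -> None:
        c = self.species_counts[label] - 1
        if c:
            self.species_counts[label] = c
        else:
            del self.species_counts[label]

    def innovate(self, patch: int) -> int:
        """Replace the species at ``patch`` with a fresh label."""
        new = self.next_label
        self._decrement(int(self.patch_species[patch]))
        self.patch_species[patch] = new
        self.species_counts[new] = 1
        self.next_label = new + 1
        return new

    def copy_species(self, src: int, dst: int) -> None:
        """Patch ``dst`` is swept by the species occupying ``src``."""
        old = int(self.patch_species[dst])
        new = int(self.patch_species[src])
        if old != new:
            self._decrement(old)
            self.patch_species[dst] = new
            self.species_counts[new] += 1

    # -- kernel interop ------------------------------------------------------

    def counts_array(self, capacity: int) -> np.ndarray:
        """Dense counts vector (label-indexed) for the compiled event loops."""
        counts = np.zeros(capacity, dtype=np.int64)
        for label, c in self.species_counts.items():
            counts[label] = c
        return counts

    def sync_from_counts(self, counts: np.ndarray, next_label: int) -> None:
        labels = np.nonzero(counts[:next_label])[0]
        self.species_counts = {int(l): int(counts[l]) for l in labels}
        self.next_label = int(next_label)

    def check_invariants(self) -> None:
        """Full recount; raises AssertionError on any bookkeeping drift."""
        recount: dict[int, int] = {}
        for l in self.patch_species:
            recount[int(l)] = recount.get(int(l), 0) + 1
        assert recount == self.species_counts, "species_counts out of sync"
        assert sum(self.species_counts.values()) == self.M, "patch count not conserved"
        assert 1 <= self.S <= self.M
        assert 0 <= self.B <= self.M
        assert int(self.patch_species.max()) < self.next_label, "label reuse"


def new_monomorphic_state(M: int) -> MetacommunityState:
    """Single-species metacommunity: S = 1, no carriers."""
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    return MetacommunityState(
        patch_species=np.zeros(M, dtype=np.int64),
        patch_carrier=np.zeros(M, dtype=bool),
        species_counts={0: M},
        next_label=1,
    )


def sample_equilibrium_state(M: int, nu: float, rng=None) -> MetacommunityState:
    """Draw the neutral-model equilibrium by the Chinese-restaurant process.

    Patches are assigned sequentially: patch ``i`` starts a new species with
    probability ``theta/(theta+i)`` (``theta = (M-1)*nu/(1-nu)``) and
    otherwise copies a uniformly chosen earlier patch. This samples the
    stationary species partition of the neutral dynamics exactly, in O(M),
    so it is the default initial condition for sweep experiments (a burn-in
    alternative is :func:`equilibrate_state`). No patch carries the gene.
    """
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    if not (0.0 < nu < 1.0):
        raise ValueError(f"nu must lie in (0, 1), got {nu}")
    rng = _as_rng(rng)
    theta = (M - 1) * nu / (1.0 - nu)
    labels, n_labels = _kernels.crp_labels(M, theta, _kernel_seed(rng))
    counts = np.bincount(labels, minlength=n_labels)
    return MetacommunityState(
        patch_species=labels,
        patch_carrier=np.zeros(M, dtype=bool),
        species_counts={int(l): int(c) for l, c in enumerate(counts) if c},
        next_label=int(n_labels),
    )


def equilibrate_state(M: int, nu: float, rng=None, c: float = 5.0) -> MetacommunityState:
    """Burn-in alternative to the exact equilibrium sampler.

    Runs the neutral dynamics from a monomorphic start for ``c * M / nu``
    steps (``c = 5`` comfortably exceeds the equilibration time ``M/nu``).
    """
    if not (0.0 < nu < 1.0):
        raise ValueError(f"nu must lie in (0, 1), got {nu}")
    rng = _as_rng(rng)
    n_steps = int(round(c * M / nu))
    state = new_monomorphic_state(M)
    counts = state.counts_array(state.next_label + n_steps + 1)
    _, _, S, next_label = _kernels.neutral_run(
        state.patch_species, counts, state.S, state.next_label,
        nu, n_steps, max(n_steps, 1), _kernel_seed(rng),
    )
    state.sync_from_counts(counts, next_label)
    state.step += n_steps
    return state


def diversity(state: MetacommunityState) -> int:
    """Number of distinct species across the patches (O(1))."""
    return state.S


@dataclass
class Trajectory:
    """Sampled time series of diversity and carrier count.

    ``step`` is in elementary steps; ``generation`` is ``step / M``.
    """

    M: int
    step: np.ndarray
    S: np.ndarray
    B: np.ndarray
    arrivals_seen: np.ndarray

    def __post_init__(self):
        if len(self.step) and np.any(np.diff(self.step) <= 0):
            raise ValueError("trajectory steps must be strictly increasing")

    @property
    def generation(self) -> np.ndarray:
        return self.step / self.M

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "generation": self.generation,
                "S": self.S,
                "B": self.B,
                "arrivals_seen": self.arrivals_seen,
            }
        )

    def write_tsv(self, path, header: Optional[dict] = None) -> None:
        with open(path, "w") as fh:
            for key, val in (header or {}).items():
                fh.write(f"# {key} = {val}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


@dataclass
class EpisodeSummary:
    """Diversity statistics over one beneficial-gene arrival window.

    ``S_min_to_fixation`` restricts the minimum to the interval between the
    arrival and the first time the carrier count reaches M (equal to
    ``S_min`` when fixation is not reached); under a diversity-restoring
    dynamics the post-fixation rebound would otherwise mask the sweep
    minimum. ``S_mean`` is the per-step time average over the window.
    """

    window: tuple[int, int]
    S_start: int
    S_min: int
    S_max: int
    S_mean: float
    S_end: int
    S_min_to_fixation: int
    fixation_step: Optional[int] = None
    truncated: bool = False

    # aliases used in the single-sweep (no restoration) context
    @property
    def S_i(self) -> int:
        return self.S_start

    @property
    def S_f(self) -> int:
        return self.S_end
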