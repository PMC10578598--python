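# Methods

## Model and assumptions

The unit of state is a patch, occupied at all times by exactly one species.
This encodes a "periodic selection" picture of within-patch dynamics: local
populations are phenotypically homogeneous between sporadic, fast selective
sweeps, so a whole patch can be labelled by its resident species' consensus
genome. Diversity `S` counts distinct labels across patches
(pan-metagenomic richness, not intra-population heterozygosity). The model
is therefore blind to clonal interference, deleterious load, and any
within-patch standing variation; where those matter its diversity estimates
are lower bounds.

All patches are exchangeable: migration and HGT connect every ordered pair
at uniform rates, and spatial distance is not modelled. A patch that
receives the beneficial gene — whether by carrier immigration or by HGT —
is assumed to be swept completely, so the selection coefficient never
appears in the patch-level dynamics; it only enters the microscopic-rate
mapping below.

Time is discrete with exactly one candidate event per elementary step.
Rates are therefore per-step probabilities, and one meta-generation = `M`
steps (one expected event per patch). Output tables report both units.

### Event menus

*Neutral model*: focal patch `i` uniform; innovation (fresh label) with
probability `ν`, otherwise `i`'s species sweeps a uniform `j ≠ i`.

*Single-gene sweep*: ordered pair `(i, j)`, `i ≠ j`, uniform; only
carrier→non-carrier pairs act (migration-sweep `p_m`, HGT-sweep `p_h`,
no-op remainder). Non-carrier→carrier pairs are no-ops: selection protects
carriers from displacement. `p_m + p_h < 1` leaves a no-op remainder rather
than renormalising, so `τ_fix ∝ 1/(p_m+p_h)` keeps its absolute time scale.

*Full model*: innovation with probability `ν` (the new species carries the
gene with probability `f₀ = B/M`, the carrier fraction at the moment of the
event — the natural reading when innovation is immigration from a parallel
metacommunity, or mutation landing uniformly on genetic backgrounds);
otherwise a pair event as above, with same-status pairs undergoing neutral
migration-sweeps. On a gene arrival, all carrier flags are cleared and one
uniform patch seeds the new gene: the newest gene is assumed fittest, so
older genes become dynamically inert and are not tracked further. Whether
the seeding patch should instead be chosen through an innovation event is
not determined by the model description; uniform seeding is used (the
`patch` argument of `apply_gene_arrival` exposes the choice).

### Microscopic mapping

With `N` individuals per patch, selection coefficient `s`, and basal
migration/HGT/innovation-arrival rates `μ_m, μ_h, μ_I` per generation, the
patch-level probabilities are `p_m = s·μ_m` and `p_h = s·μ_h` (basal rate ×
within-patch fixation probability `≈ s`). The patch-level model is the
fast-intra-patch limit of this hierarchy:

    s/log(Ns)  ≫  s·μ_m ≈ s·μ_h  ≫  μ_m/N ≈ μ_I/N,
    1/N ≪ s ≪ 1,   μ_I ≈ μ_m ≈ μ_h ≪ 1/log(Ns).

`validate_timescale_separation` checks every link, reading `≫`/`≪` as a
ratio of at least `separation_factor` (default 10) and `≈` as a ratio
within `[1/factor, factor]`; the factor is configurable because the
hierarchy itself fixes no numeric threshold.

## Parameters

| name | meaning | default / typical | units |
|------|---------|-------------------|-------|
| `M` | patches | 10⁴ (paper scale), 10³ (desk) | — |
| `ν` | innovation probability | 0.005–0.02 | per step |
| `p_m` | migration-sweep probability | 0.8–0.9 | per step, per eligible pair draw |
| `p_h` | HGT-sweep probability | 0.1–0.2 | per step, per eligible pair draw |
| `ω` | gene arrival frequency | fractions of `ω₀` | per step |
| `record_every` | sampling stride | `M` (one record/generation) | steps |
| `seed` | base seed; replicate `r` uses `seed + r` | — | — |

## Initial conditions

Sweep experiments start from the neutral model's stationary state. The
default sampler is the sequential Chinese-restaurant construction with
concentration `θ = (M−1)ν/(1−ν)`: patch `i` opens a new species with
probability `θ/(θ+i)`, else copies a uniform earlier patch. This draws the
exact stationary partition in O(M); `equilibrate_state` provides the
burn-in alternative (`5·M/ν` steps from a monomorphic start), and a
two-sample test in the suite checks the two agree. The neutral simulator
itself starts monomorphic (`S(0) = 1`) to expose the equilibration
transient.

## Numerical choices

- The exact equilibrium diversity `Σ_{i<M} θ/(θ+i)` is evaluated as
  `θ(ψ(θ+M) − ψ(θ))` (digamma), an identity, not an approximation. The
  Ewens abundance spectrum uses log-gamma differences; its printed source
  form is pinned by two identities (`Σ n⟨S(n)⟩ = M`,
  `Σ ⟨S(n)⟩ = ⟨S₀⟩`) tested to 10⁻⁸ relative.
- `log` in `⟨S₀⟩ = −Mν log ν` is the natural logarithm (the integral
  `∫ θ/(θ+x) dx` that produces it yields `ln`).
- The logistic carrier curve is computed as `M/(1+(M−1)e^{−rt})` and the
  non-carrier decay `D(t) = m0·(M/(e^{rt}+M−1))^{p_m/(p_m+p_h)}` in log
  space (`logaddexp`) to avoid overflow at large `rt`. Both algebraic forms
  are the ones satisfying their defining ODEs and boundary conditions
  (`B(0)=1`, `B(τ_fix)=M−1`, `D(0)=m0`), which the suite verifies against
  central differences and adaptive integration.
- `Q₀` is clipped to `[0,1]` (1-ulp excursions at the `p_h → 0` limit) and
  `p_h = 0` returns exactly 0; `p_m = 0` with `p_h > 0` returns the limit
  value 1.
- Migration targets exclude the focal patch (`j ≠ i`); a self-copy would be
  a null event and the difference is O(1/M). Pair draws are without
  replacement for the same reason.
- Periodic arrival spacing rounds `1/ω` to the nearest integer step;
  Poisson arrivals use geometric gaps (the discrete-time exponential).
- Event loops are numba kernels operating on dense label-indexed count
  arrays, pre-sized so every possible innovation fits; the Python-level
  step functions implement the identical event rules on the dict-backed
  state and are cross-checked by the bookkeeping invariant tests.
- All stochastic entry points take an explicit `numpy.random.Generator` (or
  seed); kernels are seeded from it with 31-bit integers. A run is a pure
  function of (parameters, seed).

## What the simulations emulate — and what they do not

The simulator *is* the study system here: there is no external data. The
parameter defaults reproduce the published experimental conditions
(`M = 10⁴`, `ν ∈ [0.005, 0.02]`, `p_h/p_m ∈ [0.1, 0.25]`, 100 replicates);
the test suite and presets also use a desk scale `M = 10³` with identical
rates, which preserves every time-scale ratio while shrinking `S₀` (≈47 vs
≈466) and widening relative fluctuations. Passing tests therefore
demonstrate internal consistency of dynamics and theory at those scales,
not realism of any particular biological rate; mapping to real communities
goes through the microscopic-rate layer and its separation checks.

## Known limitations and documented discrepancies

Two analytic idealisations do not survive contact with the event-level
model at finite `M`, and the corresponding acceptance-level tests fail by
design rather than being weakened:

1. **Equilibration collapse is approximate.** Rescaling time by `M/ν` makes
   the mean `S(t)/S₀` relaxation curves for different `ν` nearly overlay,
   but the early transient (scaled time ≲ 1) retains a systematic `ν`-
   dependent offset of ~0.05–0.11 that does not shrink with `M` (checked at
   `M = 4000`). With 100 replicates this exceeds a 3-pooled-SE band even
   though the curves collapse to within plotting resolution.

2. **The ν → 0 limit of the full model is not the no-restoration model.**
   In the full event menu, same-carrier-status pairs undergo neutral
   migration-sweeps at joint rate `1 − ν`. At `ν = 0` this neutral drift
   keeps coalescing species lineages during the `τ_fix ≈ 2M ln M`-step
   sweep, so the observed minimum diversity (`Q ≈ 0.27` at desk scale)
   falls well below the no-restoration prediction `Q₀ ≈ 0.53`, which is
   derived for a dynamics with *no* neutral events at all. The discrete
   limit model (the single-gene sweep module) does reproduce `Q₀`, and the
   qualitative claims are untouched: `Q/Q₀` rises steeply with `ν`,
   periodic arrivals above `ω₀` suppress `S_max`, and Poisson arrivals
   depress the time-averaged diversity monotonically in `ω/ω₀`. Note that
   simply deleting neutral sweeps from the full model would break its other
   anchor — diversity could then never relax back to the Ewens plateau
   after fixation — so the tension is intrinsic to the model family, and
   the event menu is implemented as defined.

Further limitations: no gene loss or back-mutation; no simultaneous
competing genes with explicit fitnesses; no spatial kernels; episode
`S_mean` averages the post-event values within a window (the window-start
sample is excluded, a 1/length effect).
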