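# metasweep

Stochastic simulator and analytic toolkit for **gene-specific selective
sweeps in microbial metacommunities**.

Metagenomic surveys of wild bacterial populations often find that a
beneficial gene has swept through a community while the genomic diversity of
its hosts survived — the opposite of the classic population-genetics
expectation that the fittest genome hitchhikes to fixation with the gene and
erases diversity. `metasweep` implements an eco-evolutionary explanation
that requires only *moderate* horizontal gene transfer (HGT) rates: when a
community is spread over `M` discrete patches, each dominated by a single
species, the physical separation of patches slows the carrier genome's
expansion enough for the gene itself to hop across genetic backgrounds by
HGT before those backgrounds are displaced.

The package is aimed at theoretical ecologists and population geneticists
who want to simulate the model at event-level resolution, evaluate its
closed-form predictions, and check one against the other.

## Model

`M ≥ 2` patches, each occupied by one species (integer label, infinite
alleles) that may carry the currently sweeping beneficial gene. Time is
discrete; one candidate event is drawn per step, and a *meta-generation* is
`M` steps. Three model variants share this state:

- **Neutral model** (diversity maintenance): a uniform focal patch is
  replaced by a brand-new species with probability `ν` (innovation), else it
  sweeps a uniform other patch neutrally. The stationary species partition
  is the Ewens distribution with concentration `θ = (M−1)ν/(1−ν)`, so the
  expected equilibrium diversity is

  `⟨S₀⟩ = Σ_{i=0}^{M−1} θ/(θ+i)  ≈ −Mν ln ν`  (for `M ≫ 1`, `ν ≪ 1`),

  reached on the equilibration time `τ_eq ≃ M/ν` steps.

- **Single-gene sweep** (no restoration): an ordered patch pair `(i, j)` is
  drawn each step; if `i` carries the gene and `j` does not, `j` is swept by
  `i`'s genome with probability `p_m` (migration-sweep, removes diversity)
  or receives the gene alone with probability `p_h` (HGT-sweep, preserves
  diversity). Carriers `B(t)` grow logistically and fix after
  `τ_fix = 2M ln(M−1)/(p_m+p_h)` steps. The expected residual fraction of
  diversity is the **sweep parameter**

  `Q₀ = 1 − ln(1 − (1−ν) e^{−p_h/p_m}) / ln ν ∈ [0, 1]`,

  e.g. `Q₀ ≈ 0.5` already at `p_h/p_m = 0.1`, `ν = 0.01`: an HGT rate ten
  times slower than migration preserves half the diversity.

- **Full dynamics**: innovation, neutral sweeps between same-carrier-status
  patches, selective sweeps, and repeated gene arrivals (single, periodic,
  or Poisson with frequency `ω`; each arrival supersedes the previous gene).
  The competition of `τ_fix`, `τ_eq` and `1/ω` yields four regimes indexed
  by `ω(τ_fix+τ_eq)` and `τ_fix/τ_eq`, with the critical arrival frequency
  `ω₀ = 1/(τ_fix+τ_eq)` above which diversity cannot recover between sweeps.

Event loops are numba-compiled (~10⁷–10⁸ steps/s), so publication-scale
runs (`M = 10⁴`) are practical and the desk-scale defaults (`M = 10³`) run
in seconds.

## Worked example

```sh
metasweep analytic --M 10000 --nu 0.01 --pm 0.9 --ph 0.1
```

```json
{
  "M": 10000, "nu": 0.01, "p_m": 0.9, "p_h": 0.1, "omega": 0.0,
  "theta": 101.00000000000001,
  "S0_exact": 465.6280137767095,
  "S0_approx": 460.5170185988091,
  "tau_eq_steps": 1000000.0,  "tau_eq_gen": 100.0,
  "tau_fix_steps": 184204.807339517, "tau_fix_gen": 18.4204807339517,
  "Q0": 0.5286600950118584,
  "omega0": 8.444485225884541e-07,
  "x1": 0.0, "x2": 0.184204807339517,
  "regime": "full-recovery/deep-sweep"
}
```

Reading: a 10⁴-patch community at innovation rate 0.01 holds ≈466 species
at equilibrium (the `−Mν ln ν` approximation gives 460.5). A beneficial
gene fixes in ≈18.4 meta-generations, about 5× faster than the neutral
dynamics re-equilibrates (100 meta-generations, `x2 ≈ 0.18`), and the sweep
is expected to leave `Q₀ ≈ 0.53` of the initial diversity in place.

The simulation side, at desk scale (library call; the `metasweep ensemble`
subcommand writes the same table as TSV):

```python
from metasweep.experiments import run_ensemble
summary = run_ensemble({"model": "sweep", "M": 1000, "nu": 0.02,
                        "pm": 0.8, "ph": 0.2, "replicates": 5, "seed": 1,
                        "record_every": 1000})
print(summary.aggregate.loc["mean"])
```

```
S_i                  80.800000
S_f                  47.200000
S_min                47.200000
S_max                80.800000
S_mean               64.763083
fixation_steps    14759.600000
```

Five replicate sweeps from Ewens-equilibrium initial states lose diversity
from ⟨S_i⟩ ≈ 81 to ⟨S_f⟩ ≈ 47 — a residual fraction ≈ 0.58 against the
infinite-`M` prediction `Q₀(ν=0.02, p_h/p_m=0.25) = 0.632` — and fix after
≈14 800 steps (`τ_fix = 13 814`).

Other entry points: `metasweep neutral|sweep|full` write trajectory TSVs
(`step  generation  S  B  arrivals_seen`), `metasweep preset fig2|fig3|
fig4-single|fig4-periodic|fig4-poisson [--scale paper|desk]` prints the
configurations of the headline experiments, and flags can be mixed with a
flat YAML `--config` file (flags win).

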