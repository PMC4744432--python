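# topoburst

Stochastic simulation and analysis of **supercoiling-dependent transcription**
in bacteria.

Transcription overwinds the DNA ahead of RNA polymerase. In *E. coli*,
topoisomerase I quickly removes the compensating negative supercoils, so
positive supercoiling accumulates in the local chromosomal domain until gyrase
binds and relaxes it. Because positive supercoiling stabilises the duplex, it
raises the free-energy cost of melting the promoter and throttles initiation —
a structural mechanism for transcriptional bursting that also couples every
gene sharing the domain. `topoburst` implements this picture end to end for
anyone studying single-cell expression noise, bursting kinetics, or
topology-mediated gene regulation:

- **`topoburst.thermo`** — a Benham-type statistical-mechanical model of strand
  separation on a circular domain (N bp, promoter Np bp). A microstate with
  *n* melted base pairs in *n_j/2* bubbles has free energy
  `G = n(ε − TΔS) + (n_j/2)ε_o + G_s(n, σ) − k_B T ln g(n, n_j)` with
  superhelical-stress energy `G_s(n,σ) = C·N·(n/N + σ)² / (A²[1 + (α−1)n/N])`.
  Boltzmann-averaging gives the promoter-melting barrier ΔG(σ), its shift
  ΔΔG(σ) = ΔG(σ) − ΔG(0), the transition-state rate factor
  `k(σ) = k₀·e^{−ΔΔG/k_BT} ≈ e^{−wσ}`, and the initiation rate law
  `V(σ) = k_on / (k′·e^{wσ} + 1)` (with `k′ = k_off(0)/k_cat`) plus its linear
  approximation.
- **`topoburst.kinetics`** — the bursting network: per domain, `RCoil`
  (remaining transcription capacity) and `PCoil` (accumulated positive
  supercoils) with `RCoil + PCoil = max(RCoil)`, a single gyrase site, and per
  gene transcription `a_o·RCoil`, mRNA decay `γ`, translation `b_o·γ·mRNA` and
  protein decay `d`. Simulated exactly with the Gillespie direct method
  (numba-compiled), with trajectory, event-log and stationary-cell sampling
  modes.
- **`topoburst.trace_analysis`** — the single-molecule trace pipeline:
  intensity → cumulative transcripts → average-transcription-event times →
  per-event initiation rates → linear fit whose y-intercept is the maximal
  rate `a_o·max(RCoil)` and x-intercept the capacity `max(RCoil)`, plus a
  synthetic-trace generator for testing it.
- **`topoburst.distributions`** — Fano factors, Poisson and
  Poisson-with-zero-spike reference models, maximum-likelihood gamma fits of
  protein counts (burst frequency *a*, burst size *b*), gene–gene correlation
  matrices.
- **`topoburst.experiments`** — scripted studies: mRNA distributions for
  strong/weak promoters, Fano-factor scans over (a_o, K1), gamma-fit parameter
  biases, ten-gene linked-domain correlations, and negative regulation by a
  strong neighbour.

## Worked example

Fit a gamma distribution to the stationary protein counts of the full model
(a_o=90, max(RCoil)=4, b_o=2, γ=50, d=1, K1=10, K2=35, R=1000; 4000 cells):

```sh
$ topoburst experiment gamma-fit --seed 1 --out-dir out
fitted shape 14.32 (model 360, -96.0%), scale 13.40 (model 2, +570.2%)
```

Although the protein distribution is well described by a gamma, the fitted
burst frequency (14.3) and burst size (13.4) are each an order of magnitude
away from the underlying rates (a_o·max(RCoil)/d = 360 bursts per protein
lifetime, b_o = 2 proteins per transcript): supercoil stalling merges many
initiations into fewer, larger effective bursts, so gamma-fit parameters must
not be read as molecular rates for supercoiling-limited genes.

The same machinery in the library:

```python
from topoburst import single_gene_system, build_network, sample_cells, gamma_fit

net = build_network(single_gene_system(a_o=90))
cells = sample_cells(net, 4000, seed=1)          # 10 protein-lifetimes burn-in
fit = gamma_fit(cells.gene_counts("gene1", "protein"))
print(fit.shape, fit.scale)                      # 14.32..., 13.40...
```

The strong-promoter mRNA distribution deviates markedly from Poisson:

```sh
$ topoburst experiment mrna-dist --promoter strong --seed 1 --out-dir out
Fano factor 3.527; mean mRNA 1.990
```

and on the thermodynamic side, the barrier shift over the linear-response
grid σ ∈ [0, 0.02]:

```python
from topoburst.thermo import (ThermoParams, barrier_shift, rate_factor,
                              fit_exponential_w, default_sigma_grid)
p = ThermoParams()                                # published constants, 298.15 K
grid = default_sigma_grid()
fit = fit_exponential_w(grid[1:], [rate_factor(s, p) for s in grid[1:]])
print(barrier_shift(0.02, p), fit.w)              # 1.767 kcal/mol, w = 157.5
```

positive supercoiling *raises* the melting barrier (ΔΔG(0.02) ≈ +1.77
kcal/mol), and the rate factor decays as a single exponential in σ
(R² = 0.991), which is what licenses the linear `a_o·RCoil` propensity used in
the kinetic model.

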