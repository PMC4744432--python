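# Methods

## The melting model (`thermo`)

Strand separation on a circular domain of N base pairs is described by
microstates (n, n_j): n melted base pairs arranged in n_j/2 bubbles. The free
energy combines base pairing (ε − TΔS per bp), junction (stacking) cost ε_o
per helix–coil boundary pair, the torsional/bending energy of the residual
superhelical stress

    G_s(n, σ) = C · N · (n/N + σ)² / (A² [1 + (α − 1) n/N]),

and the placement entropy of the bubbles, with degeneracy

    g(n, n_j) = N (N−n−1)! (n−1)! / [(N−n−n_j/2)! (n−n_j/2)! (n_j/2−1)! (n_j/2)!].

Defaults: ε = 7.9, ε_o = 2.5 kcal/mol, ΔS = 0.024 kcal/(K·mol), C = 1638
kcal/(mol·rad²), α = 23.4, A = 10.4 bp/rad², N = 180 bp, Np = 8 bp,
T = 298.15 K. All factorials are evaluated in log space (log-gamma); nothing
in the main path uses big-integer arithmetic.

**Degeneracy sign.** Physically the Boltzmann weight of a melt number must be
g·e^(−E/k_BT): multiplicity lowers free energy. The package therefore uses
G = E − k_B T ln g by default. Because the opposite sign (+k_B T ln g) also
appears in the literature, every thermo routine accepts
`degeneracy_sign="as_printed"` to reproduce it; the barrier curves differ by
only a few percent at these parameters because melting is rare at room
temperature either way.

**Truncation.** The melt-number sum runs to n_max = ⌊0.06·N⌋ = 10 by default:
beyond a melted fraction of ~6 % the binomial argument used for the promoter
(below) breaks down because multiple melted promoter base pairs would share
one bubble. The n = 0 state is included with n_j = 0 and degeneracy 1.

**Promoter barrier.** Given P(n|σ) (Boltzmann over the truncated state space),
the number k of already-melted base pairs among the Np promoter base pairs is
binomial with success probability n/N, and the barrier is

    ΔG(σ) = Σ_n Σ_k P(n|σ) · Binom(k; Np, n/N) · [(Np−k)·ε + G_s(n+Np−k, σ) − G_s(n, σ)],

where the G_s argument n+Np−k ≤ n_max+Np stays well inside [0, N], so G_s is
evaluated directly without re-truncation. ΔΔG(σ) = ΔG(σ) − ΔG(0) and
k(σ) = k₀ e^(−ΔΔG/k_BT).

**Direction of the supercoiling effect.** For σ > 0 the stress term
(n/N + σ)² grows when n grows, so positive supercoiling *suppresses* melting:
P(0|σ) increases with σ, ΔΔG(σ) ≥ 0, and k(σ) decays. This matches the
experimental facts the model is built on (positive supercoiling raises the
melting temperature; initiation slows as positive supercoils accumulate). The
off-rate of the open complex carries the opposite sign (e^{+wσ}) because the
open complex must *maintain* the melted state, giving the decreasing
production rate V(σ) = k_on / (k′ e^{wσ} + 1) and, to first order,
V(σ) ≈ k_on/(k′+1) − k_on w k′ σ/(k′+1)², clipped at zero past its x-intercept
σ* = (k′+1)/(w k′) so that it can serve as a reaction propensity.

**Linear-response grid.** ΔΔG(σ) is close to linear only while σ is small
compared with the turnover point of the dominant stress difference
G_s(Np, σ) − G_s(0, σ), a downward parabola in σ with maximum at
σ* = 1/(α−1) ≈ 0.045 for the default geometry. The default fit grid is
therefore σ ∈ [0, 0.02] (25 points, ≈ σ*/2), where a straight line fits the
model's own curve with R² ≈ 0.996 and a single exponential fits k(σ) with
R² ≈ 0.991, yielding w ≈ 158. Over wider ranges (σ ≳ 0.03) the curve bends
over and is no longer exponential; a test documents this turnover. The grid is
configurable everywhere it is used.

**Fitting to event-indexed rates.** The supercoiling increment per
transcription event is not known, so when the rate laws are fitted to
per-event initiation rates the density is parameterised as σ = c·j; only the
products (k_on, k′, w·c) are identifiable and the fitted values are curve
parameters, not molecular rates.

## The kinetic model (`kinetics`)

Reactions per gene g in domain D (propensities in parentheses): transcription
(a_o·RCoil_D; RCoil→PCoil, mRNA+1), mRNA decay (γ·mRNA), translation
(b_o·γ·mRNA, mRNA catalytic — consuming the mRNA would contradict the
burst-size interpretation b = b_o), protein decay (d·Protein). Per domain:
gyrase binding (K1, site empty), unbinding (K2), relaxation (R·PCoil, site
occupied). RCoil + PCoil = max(RCoil) is conserved; all genes in a domain read
the same RCoil, which is what couples their bursts. Transcription is
instantaneous (no elongation delay or explicit RNAP), the volume is well
stirred, and simultaneous transcription of neighbours neither cancels nor
enhances the supercoils (no codirectional/divergent geometry).

Time unit: the protein lifetime (d = 1). Defaults: γ = 50 (mRNA lifetime
~2 min at a 1 h doubling time), b_o = 2, K1 = 10 (rebinding in a tenth of a
lifetime), K2 = 35 (weak site, K1/K2 = 0.28), R = 1000 (relaxation fast
relative to everything else), max(RCoil) = 4 (four rounds of transcription
before stalling in vivo). The in-vitro mode uses seconds, rate
a_o·max(RCoil) = 0.0032 s⁻¹ and capacity 13, with γ = K1 = K2 = R = 0 and 160
templates, and runs each template to exhaustion.

Simulation is the exact Gillespie direct method over mass-action propensities
(at most two reactant species per reaction; gyrase gating enters as a 0/1
catalyst copy number), compiled with numba. Initial state: domains fully
relaxed, gyrase site empty (an occupied start is available and tested to give
the same stationary statistics), no mRNA or protein. Stationary sampling takes
one end-state snapshot per replicate cell after a burn-in of 10 protein
lifetimes, each cell on an independent SeedSequence-derived stream — snapshots
are therefore exactly independent, at the price of re-running the burn-in per
cell. Identical (configuration, seed) gives byte-identical output.

## Trace processing (`trace_analysis`)

The cumulative sum of the intensity, divided by the per-transcript intensity
(13.5×10³ fluorescence units), counts transcripts; the j-th "average
transcription event" is the linear-interpolated time at which that count
crosses j·(number of templates); per-event rates are inverse inter-event
intervals with t₀ = 0 (assay start); rates are regressed by OLS against event
number j. The x-intercept standard error uses first-order propagation
including the slope–intercept covariance. Because the j-th interval spans
capacities from max(RCoil)−j+1 to max(RCoil)−j, the fitted line sits about
half an event above the nominal capacity; this offset is well inside the fit
uncertainty at 160 templates.

The synthetic fixture bins simulated event times into 50 s frames, scales by
the per-transcript intensity and adds Gaussian noise (default SD: a tenth of
one transcript per frame, clipped at zero). It emulates the *shape* of the
assay — a decaying initiation rate from a finite-capacity template pool — but
not its real noise sources (photobleaching, background drift, per-template
intensity variation), so passing the round trip validates the pipeline, not
any inference about the original instrument.

## Distribution analyses (`distributions`)

Fano factor: unbiased variance over mean. Zero-spike reference: the mixture
(1−f)·δ₀ + f·Poisson(a_o·max(RCoil)/γ) with f = K1/(K1+K2), i.e. a gene that
is fully on exactly while gyrase is bound — the stated switching picture
admits this two-component reading, which is the one implemented. Gamma fits
are maximum likelihood with location fixed at 0, treating counts as
continuous; when zeros are present a 0.5 continuity offset is added to all
values and flagged in the result. Moment estimates (mean²/var, var/mean) are
always reported alongside, so conclusions about fit-parameter bias can be
checked against the method choice. Correlations are plain Pearson on per-cell
counts; no significance testing is attached.

**Burst-model limit.** With the gyrase site permanently occupied and R large
the model reduces to the classic burst model: Poisson mRNA (Fano 1) and
bursty protein. Exact gamma recovery of (a_o·max(RCoil)/d, b_o) holds only for
continuous (exponential) burst sizes; the catalytic translation reaction gives
geometric bursts of mean b_o, so the stationary protein is negative-binomial
with mean ab and variance ab(1+b), and the matched gamma has shape a·b/(1+b)
and scale 1+b (240 and 3 at a = 360, b = 2). Tests assert these corrected
values tightly and the uncorrected mapping loosely — a discreteness effect of
tens of percent, against the order-of-magnitude bias the full supercoiling
model produces.

## Experiments (`experiments`)

Problem sizes are package defaults chosen to keep Monte-Carlo error well below
the effects under study: 4000 cells for single-gene distribution experiments,
2000 per grid point for scans (grids: a_o linearly spaced over [10, 200],
K1 log-spaced over [1, 100], 8×8 — the binding constant is a ratio-type
quantity, hence log spacing).

Linked domains: two five-gene domains with promoter strengths
(34, 20, 14, 10, 6) and (2, 3, 2.4, 0.4, 1.0), each with capacity
max(RCoil) = 20 so that every gene can be transcribed four times on average
before stalling, and one gyrase site per domain. The isolated control places
a gene alone on a loop of the *same* capacity (20): "its own supercoiling
domain" is the same physical loop minus the neighbours. A per-gene capacity
share (4) is available via `isolated_max_rcoil`, but note it throttles the
control itself — a rate analysis (bound-state transcription a_o·RCoil) shows
the capacity-4 control expresses *less* than the linked gene, which would
invert the comparison the experiment is designed to make.

Negative regulation: a single five-gene domain with strengths (34, 20, 14,
10, 6), capacity 20; inhibition multiplies gene 1's a_o by
`inhibition_factor` (default 0, full repression; the degree of repression in
the motivating setting is unspecified, so it is exposed). Both conditions use
the same master seed, making the silent-gene control exactly invariant.

## Known limitations

- The model is well stirred and zero-dimensional: no elongation, RNAP/ribosome
  copy numbers, spatial structure, cell division, or extrinsic noise. Fano
  factors and correlations here isolate the supercoiling contribution only.
- Topoisomerase I is implicit (negative supercoils relax instantly); gyrase
  kinetics are a single pseudo-first-order site per domain.
- A weak promoter with a_o = 20 has stationary mean mRNA
  a_o·max(RCoil)/γ = 1.6 in the no-supercoiling limit under these reaction
  definitions; descriptions quoting 0.4 for this case correspond to a_o/γ,
  i.e. a single-capacity convention, and the discrepancy is surfaced rather
  than resolved here.
- Sequence-dependent promoter energetics (AT/GC composition) and promoters
  activated by supercoiling are out of scope; the melting model treats all
  base pairs identically.
- The linear rate law underlying the a_o·RCoil propensity is valid only in the
  small-σ regime discussed above; systems driven far past the turnover point
  need the full V(σ).
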