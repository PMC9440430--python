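# Methods

## Equilibrium model

All binding is treated at thermodynamic equilibrium in nM concentration
units. A protein dimer P binding a DNA molecule D with one discrete site is
governed by Kd = [P][D]/[PD]; with total concentrations P₀, D₀ the complex
concentration is the smaller root of the quadratic mass balance, evaluated
as 2P₀D₀/(s + √(s² − 4P₀D₀)) with s = P₀ + D₀ + Kd to avoid catastrophic
cancellation when the complex is a tiny fraction of either total. The
hyperbolic isotherm θ = x/(x + Kd) is retained for the weak-binding regime
(Kd ≫ D₀), which is how nonspecific hairpin titrations are analyzed.

For two discrete sites the species ladder 00/10/01/11 carries weights
1, P/Kd₁, P/Kd₂ and ωP²/(Kd₁Kd₂), where ω is a first-class cooperativity
factor (ω = 1, the default, is the independent-site model the study data
support; the conclusion of no cooperativity is therefore testable as model
selection rather than baked in). Free protein is the unique root of
P + bound(P) = P₀ on [0, P₀]; bound(P) is strictly monotone, so a
bracketed scalar solve (Brent) at machine-precision relative tolerance is
guaranteed to converge, and both mass balances hold to 1e−9 relative. A
kinetic (ODE) treatment would relax to the same fixed point and is not
implemented. A vectorized bisection companion
(`free_protein_two_site`) evaluates whole titration curves inside fits.

## Finite-lattice footprint model

A DNA molecule of L bp is a one-dimensional lattice; each bound dimer
occludes a fixed footprint (default 10 bp, the segment a dimer needs to
bind efficiently). A placement exactly in register with a κB-site interval
binds with that site's specific Kd; every other start position with the
footprint fully on the DNA binds with a single homogeneous nonspecific Kd
(∞ disables nonspecific binding). Dimers interact only by hard-core
exclusion — no partial-register intermediate affinities and no lateral
cooperativity. Coordinates are 1-based inclusive bp intervals.

The grand-canonical weight of a configuration is Π P/Kd over its placed
dimers, so the per-molecule partition function is a polynomial
Z(P) = Σₙ aₙPⁿ whose coefficients are computed exactly by a right-to-left
transfer-matrix recursion (O(L·n_max)); an exhaustive recursive
enumeration, guarded to ≤ 200 bp, serves as an independent cross-check and
the two agree to 1e−8 on every lattice tested. Mass balance over all DNA
molecules (including several competing DNA species sharing one protein
pool) fixes the free-protein concentration; the occupancy distribution
p_n = aₙPⁿ/Z then predicts EMSA band fractions, with an optional "4+" bin
mirroring the unresolvable high-order smear on gels.

Competitor molecules whose affinity is known only as a whole-molecule
constant (e.g. a scrambled hairpin at 130 nM) are modeled as a single
binding unit at that constant, not as a lattice of per-position nonspecific
sites: the measured constant already contains the positional entropy, and
double-counting it (~18 start positions on a 27-mer) would inflate the
competitor's effective affinity by over an order of magnitude.

## Construct geometries

The printed construct facts are mutually inconsistent in one respect: the
EMSA tandem constructs (33 bp HIV-LTR with a 4-bp inter-site gap; scrambles
leaving 21 bp and 16 bp nonspecific stretches, which force 2 bp/7 bp
flanks) cannot also have the 3-bp flanks that put a 5′ label within the
anisotropy proximity cutoff of each outer site. The fixture registry
therefore carries two geometries per promoter: an `_emsa` construct
honoring the printed total length and stretch lengths, and a `_labeled`
construct honoring the 3-bp-flank labeling geometry (30 bp for HIV-LTR;
45 bp for *NFKBIA* with its 19-bp separation). For the 59-bp *NFKBIA* EMSA
construct the printed facts leave 20 flank bp unconstrained; they are split
10/10. Hairpins are single-site constructs (site at bp 1–10, the CCCCC
loop treated as non-binding spacer).

## Anisotropy readout

r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) with instrument G-factor 0.67. The
formula is implemented in this standard form; a variant with a minus sign
in the denominator is available behind `printed_denominator=True` for
reproducing legacy calculations but diverges for realistic intensity
ratios and is bounded by no physical range.

Binding is transmitted to the signal by a binary proximity rule: a site
contributes (weight 1) iff its nearest edge lies within 3 bp of the
fluorophore position; the observed drop-off with distance is sharp enough
that a smooth distance decay would add parameters without information. The
predicted signal is r = baseline + amplitude·(Σwθ)/(Σw): it saturates at
baseline + amplitude when all label-proximal sites fill, and sites the
label cannot sense contribute nothing. Amplitude and baseline are
per-curve nuisance parameters because labeling efficiency and plateau
anisotropy vary between DNA preparations.

## Fitting

Nonlinear parameters (Kd, ω) are optimized as natural logarithms, which
enforces positivity and lets multi-start searches span decades; five
log-spaced Kd starting values cover the sampled concentration range. For
any trial (Kd, ω) the per-curve amplitude and baseline enter the model
linearly and are profiled out exactly by linear least squares (variable
projection, amplitude clamped nonnegative), reducing the global two-site
fit to 1–3 nonlinear parameters. Global fits bound log Kd to [1e−4, 1e6] nM
and log ω to [1e−3, 1e3]: without bounds the cooperative model has a
degenerate ridge (Kd → ∞, ω → ∞ at fixed ωKd⁻², the all-or-none limit)
that noise can push fits onto. For the non-equal models one extra start is
seeded from the best equal-Kd solution, so the nested-model inequality
RSS(distinct) ≤ RSS(equal) holds by construction. Cost tolerance is 1e−10;
standard errors come from the Gauss–Newton covariance of the full
parameter vector (including the profiled linears) at the optimum. A fit
whose amplitude collapses below 1e−4 anisotropy units is flagged
non-converged: a flat curve cannot identify Kd.

Replicates are fit independently and aggregated as mean ± SEM
(SD(n−1)/√n), matching how the experimental constants were reported;
pooled fitting across replicates is possible by passing all curves to one
global fit. Model choice among equal-Kd, distinct-Kd and cooperative
(shared Kd + free ω, so the two 2-parameter alternatives are symmetric
siblings of the 1-parameter null) uses AICc with the parameter count
including the profiled per-curve linears and the noise variance; RSS is
floored at n·1e−20 (a 1e−10 per-point residual) so numerically perfect
zero-noise fits tie and the tie-break toward fewer parameters applies.
Group comparisons of per-replicate Kd values use a two-tailed Welch t-test
on the linear Kd scale (the test the mean ± SEM reporting style implies),
with a label-permutation test available as a distribution-free cross-check.

## Synthetic data

The generator reproduces the study design: 5 nM labeled DNA (10 nM κB
sites for tandem dsDNA), a concentration series of 12 log-spaced points
plus a zero point (default 0.1–2000 nM; wider for weak nonspecific
binding, e.g. up to 10–50 μM), three replicates, and i.i.d. Gaussian
anisotropy noise of σ = 0.003 — chosen so that 3-replicate SEMs are
comparable to the reported experimental SEMs. Default amplitude 0.08 and
baseline 0.17 are typical fluorescein-DNA anisotropy values. Replicate i
of a run draws from `SeedSequence(seed + i)`, so a triplicate at seed 1
uses replicate seeds 1–3 and any replicate can be regenerated alone. EMSA
tables apply truncated-Gaussian fractional noise to the lattice-model
fractions and renormalize each lane.

What the generator does *not* emulate: systematic (non-Gaussian,
correlated) instrument drift, photophysical effects on the fluorophore,
pipetting error in the concentration series, partial hairpin annealing,
and sequence-dependent affinity — synthetic recovery tests therefore
demonstrate estimator correctness and statistical power at the stated
noise, not robustness to those real-data pathologies.

## Identifiability limits worth knowing

- In the stoichiometric regime (Kd ≪ DNA concentration) titration curves
  are depletion-limited and nearly shape-invariant: cooperativity ω is
  then practically unidentifiable at realistic noise. The cooperativity
  model-selection demonstration therefore uses Kd = 10 nM (the weak-site
  value, at the site concentration), where ω = 5 is reliably detected;
  at Kd = 1.7 nM it is not, and no analysis should claim otherwise.
- Weak-site Kd estimates from global fits are right-skewed; means of few
  replicates inherit a small upward bias (~5% at the default design).

## Problem sizes and numerical defaults

Recovery runs use 3 replicates of 13-point titrations (the experimental
scale); model-selection rate checks use 50 simulated studies of 6 curves
each; lattice cross-checks enumerate lattices to 40 bp. Guinier fits start
from the lowest q, drop nonpositive-intensity points, and truncate the
upper range iteratively until q_max·Rg ≤ 1.3 (configurable); the fit is
σ-weighted on ln I vs q². The polymer scaling law uses R₀ = 1.927 Å,
ν = 0.598 (denatured-protein calibration). SAXS D_max/P(r) inversion,
sequence-level affinity prediction (PWM scoring), DNA bending/allostery,
and time-resolved kinetics are out of scope.
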