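# Methods

## Binding-curve model and fitting

Titration curves are fitted with the four-parameter logistic equation
F(C) = F0 + (F∞ − F0)/(1 + (EC50/C)^n). The zero-concentration wells enter
the fit through the continuity F(0) = F0. Replicate wells are averaged per
concentration before fitting, matching the convention of averaging
duplicate measurements; curves with fewer than 6 points or without a
zero-concentration point are refused.

Optimization uses bounded trust-region least squares (scipy `curve_fit`)
with initial values F0 = mean intensity at C = 0, F∞ = maximum intensity,
EC50 = linear interpolation of the half-rise concentration (geometric-mean
fallback) and n = 1, and box constraints EC50 ∈ [0.1, 10⁵] nM,
n ∈ [0.3, 5]. These bounds comfortably bracket the 23–670 nM affinities
and 1–2.4 Hill slopes typical of the systems modeled. Optimizer failure is
returned as a flagged fit (`converged = False`), never an exception. A
fitted dynamic range F∞/F0 below 1.1 (configurable) is classified
"no binding detected" and the parameters are withheld, mirroring titrations
whose signal change is too small to quantify.

Parameter uncertainty is reported two ways, clearly separated: per-fit
asymptotic SDs from the covariance of one experiment, and across-experiment
SDs from replicate fits (`summarize_replicates`; the SD is withheld when
only one experiment exists). Fitting is unweighted by default; an optional
`weighting="relative"` mode (σ ∝ intensity) matches the multiplicative
noise model, under which the per-fit 95% intervals (with a t quantile at
n − 4 degrees of freedom) show near-nominal coverage in simulation.
Whether points should be weighted in general is instrument-dependent, so
the default stays unweighted.

## Exact equilibrium models

`exact_bound_fraction` evaluates the 1:1 isotherm from the mass-balance
quadratic using the conjugate form 2·P·X/(b + √(b² − 4PX)), which avoids
catastrophic cancellation at small K_d. `apparent_ec50` root-finds the
partner concentration at which the exact bound fraction reaches half its
saturating value; the half-maximal point is defined on the bound fraction
(not on P_tot/2) so the empirical and exact EC50 definitions agree by
construction. Analytically this equals K_d + P_tot/2, which the tests use
as an independent oracle; it formalizes why an EC50 below the probe
concentration is only an upper limit on K_d (floor at P_tot/2).

The competition solver reduces the coupled equilibria of one probe and two
partners to a single strictly increasing conservation function of free
probe, solved by Brent's method on (0, P_tot]; conservation of all three
species is verified to a relative residual of 1e−10 at every titration
point, and violation raises an error naming the offending concentration.
Predicted fluorescence is a per-nM-coefficient-weighted sum of free probe
and the two complexes.

## FRET analysis

The acceptor-only series is subtracted pointwise from the donor+acceptor
series using replicate means; negative corrected values are excluded with
a logged warning rather than clipped. Only the bound fraction of the donor
is quenched, so the measured per-point quenching is E·f_bound(C). The
reported efficiency is the least-squares solution of
F_da(C) = F̂_d(C)(1 − E·f̂_bound(C)) over selected points, where F̂_d and
f̂_bound come from the logistic fit of the donor-only series. This
estimator is exact on noise-free data, recovers a single E across the
sub-saturating range, and in simulation is unbiased at 2% well noise —
unlike averaging per-point ratios (1 − F_da/F_d)/f_bound, whose 1/f_bound
and 1/F_d factors introduce a percent-level upward bias. Points are
selected where f̂_bound ≥ 0.2 (configurable): below that, the quenching
signal is dominated by noise. Per-point normalized efficiencies and raw
ratios are retained, and their agreement across low and sub-saturating
concentrations is itself a consistency check. How points should be pooled
into one E is not uniquely determined by the assay; the threshold-plus-
regression choice here is a declared design decision.

Distances use R = R0(1/E − 1)^(1/6) and the inverse
E = R0⁶/(R0⁶ + R⁶), with R0 = 55 Å (FAM/TMR) as a configurable constant;
distances are only defined for 0 < E < 1 and reported in Å. Swapping donor
and acceptor between the two proteins may legitimately change E (dipole
orientation); no symmetry is assumed, and the generator supports distinct
true efficiencies per orientation. The excitation/emission wavelengths
(485/520 nm) are metadata only.

## Hydrodynamics

Stokes–Einstein conversion uses k = 1.380649e−23 J/K, T defaulting to
297 K, and water viscosity from a 0–40 °C table with linear interpolation
(explicit viscosities override). The Perrin prolate factor
F(p) = p^(−1/3)√(p²−1)/ln(p + √(p²−1)) is continuous at p = 1 and strictly
increasing; the tests validate it against numerical evaluation of the
general ellipsoid friction integrals.

Ab-initio radii from hydrated volume use v̄ = 0.73 cm³/g and hydration
0.35 g/g by default, but instrument-reported radii rest on unknown volume
assumptions, so those defaults are not expected to reproduce any particular
published number. The module therefore provides a calibration mode: anchor
the equivalent-sphere radius to one measured state and predict other
oligomers by radius ∝ volume^(1/3) and shape scaling. Anchoring a prolate
(p = 8) monomer at 4.8 nm predicts 6.05 nm for the doubled-volume dimer at
p = 8 and 7.72 nm at p = 16 — scaling relations that are the testable
content of the ellipsoid model. The axial ratio of the XRCC1 monomer is
taken as 8 (configurable). Oligomeric-state assignment ranks candidates by
mean absolute relative deviation over the available observables (Mw, R_H),
breaking ties toward the smaller oligomer.

Units are explicit throughout: D in m²/s, R_H in nm, Mw in kDa, FRET
distances in Å; converters are provided rather than implicit rescaling.

## Synthetic-data generator

The generator emulates the study design the analyses assume: 40 nM probe,
duplicate wells, a grid of 0 plus 12 log-spaced concentrations from 1 to
1000 nM, three independent experiments per condition, EC50s in the tens to
hundreds of nM, saturation fold-changes of 1.9–2.8 and Hill slopes of
1–2.4 (defaults: F0 = 100 a.u., fold-change 2.2, n = 1.8 for hetero
pairs, n = 1 for self-association). Well noise is multiplicative Gaussian
with CV 0.02 — plate-reader fluorescence at these intensities is
gain-dominated, and this CV produces across-experiment EC50 SDs of the
same order as the ~10% typical of such titrations — plus an optional
additive floor (default 0 a.u., so zero-CV output equals the model
exactly). FRET triplets add an acceptor bleed-through series proportional
to the bound-acceptor signal (coefficient 0.2 by default) and construct the
donor+acceptor series as F_d(C)(1 − E_true·f_bound(C)) plus that bleed, so
the correction/efficiency pipeline on noise-free output returns E_true
exactly. Paired ±DNA experiments scale EC50 by a fold ratio and shift
E_true by a signed delta within one seeded stream.

Ground truth is always returned (and serialized) next to the data. Fixed
seeds give bit-identical output; all analysis code is deterministic, so
the generator is the only source of randomness.

What the generator does not emulate: Poisson photon statistics,
photobleaching, drift between series, pipetting-volume correlations across
wells, buffer/DNA-only backgrounds, or deviations of true binding from the
Hill form (e.g. mixed-stoichiometry oligomerization). Passing recovery
tests therefore demonstrates correctness of the estimators under the
declared noise model, not robustness to every artifact of real plates.

## Problem sizes

Monte-Carlo checks use 200 simulated datasets per condition (a compromise
giving standard errors of ~1% of the recovered quantities); the acceptance
script uses the same size, and smaller sets (40–150) are used for
secondary calibration tests.

## Known limitations

- The Hill curve is empirical; EC50 is an apparent constant, and no
  mechanistic multi-site model is attempted.
- The FRET treatment assumes the acceptor-only series fully captures
  bleed-through and that κ² orientation effects fold into E.
- The competition model assumes independent 1:1 sites and no ternary
  complexes.
- Oblate ellipsoids and bead models are out of scope for the hydrodynamic
  module.
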