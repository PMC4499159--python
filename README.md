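# berquant

Quantitative analysis of protein–protein interactions among base excision
repair (BER) proteins — APE1, Polβ, XRCC1, PARP1 and TDP1 — from
fluorescence plate-reader titrations, steady-state FRET and light-scattering
observables.

Binding of a partner protein to a fluorescein-labeled probe changes the
probe's fluorescence. Titrating the partner and fitting the intensity gives
an apparent dissociation constant; pairing a fluorescein donor with a
tetramethylrhodamine acceptor turns the same design into a FRET ruler; and
SEC-MALLS molecular weights or DLS diffusion coefficients report the
oligomeric state of the complexes. `berquant` implements the full analysis
chain for these experiments, together with exact equilibrium-binding models
and a synthetic-data generator that makes every stage testable without
instrument data.

## Models

**Empirical binding isotherm.** A titration at partner concentration *C* is
fitted with the four-parameter logistic (Hill) equation

    F(C) = F0 + (F∞ − F0) / (1 + (EC50 / C)^n)

where F0 is the probe-alone intensity, F∞ the saturating intensity, EC50
the half-maximal partner concentration (read as an apparent K_d) and *n*
the Hill coefficient. The fitter is a scikit-learn-style estimator
(`FourParamLogistic`) with bounded nonlinear least squares underneath.

**Exact equilibria.** `exact_bound_fraction` solves the 1:1 mass-balance
quadratic (stable conjugate branch), `apparent_ec50` locates the
half-saturation point of the exact isotherm — showing that a measured EC50
can never fall below max(K_d, P_tot/2), so EC50 values below the probe
concentration are upper limits on K_d — and `solve_competition` solves the
coupled mass-action equilibria of one probe shared between two partners,
the situation behind displacement titrations.

**FRET.** From the three matched series (donor-only, acceptor-only,
donor+acceptor), the acceptor bleed-through is subtracted pointwise
(F_da = F_da* − F_a), the transfer efficiency estimated from the donor
quenching E = 1 − F_da/F_d with the bound fraction accounted for, and the
donor–acceptor distance computed as R = R0 (1/E − 1)^(1/6) with
R0 = 55 Å for the FAM/TMR pair.

**Hydrodynamics.** R_H = kT/(6πηD) (Stokes–Einstein) converts DLS diffusion
coefficients to hydrodynamic radii; the Perrin translational friction
factor F(p) = p^(−1/3)·√(p²−1)/ln(p + √(p²−1)) models prolate particles
such as XRCC1 (axial ratio ~8); `assign_oligomeric_state` ranks candidate
monomer/dimer/heterodimer states against observed Mw and/or R_H.

## Worked example

Simulate three independent FRET titrations of 40 nM FAM-APE1 with
TMR-Polβ (EC50 93 nM, true E 0.16, 2% well noise), then run the full
analysis:

```python
import numpy as np
from berquant import (SyntheticConfig, fit_four_parameter, fret_efficiency,
                      generate_fret_triplet, summarize_replicates)

cfg = SyntheticConfig(ec50=93.0, hill_n=1.8, fold_change=2.2,
                      e_true=0.16, cv=0.02, seed=42,
                      probe_name="FAM-APE1", partner_name="TMR-Polb")
rng = np.random.default_rng(cfg.seed)
fits, effs = [], []
for _ in range(3):
    experiment, truth = generate_fret_triplet(cfg, rng)
    donor_fit = fit_four_parameter(experiment.series_d)
    fits.append(donor_fit)
    effs.append(fret_efficiency(experiment, donor_fit=donor_fit))

summary = summarize_replicates(fits)
print(f"EC50  = {summary['ec50'].mean:.0f} +/- {summary['ec50'].sd:.0f} nM "
      f"(n = {summary['ec50'].n_replicates})")
print(f"Hill n = {summary['hill_n'].mean:.2f}")
e = np.array([r.efficiency for r in effs])
print(f"E     = {e.mean():.3f} +/- {e.std(ddof=1):.3f}")
print(f"R     = {np.mean([r.distance for r in effs]):.1f} A")
```

Output:

```
EC50  = 99 +/- 6 nM (n = 3)
Hill n = 1.74
E     = 0.164 +/- 0.001
R     = 72.1 A
```

The mean EC50 of the three experiments scatters around the generating
93 nM with the few-percent SD expected at 2% well noise; the recovered
transfer efficiency matches the generating 0.16, which corresponds to a
donor–acceptor separation of about 72 Å for a 55 Å Förster radius.

A command-line interface mirrors the library
(`berquant simulate|fit|fret|hydro|report`); `berquant report --config
cfg.toml --out-dir out --seed 1` runs the whole pipeline and writes a
result table (TSV), all fits (JSON) and a run log.

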