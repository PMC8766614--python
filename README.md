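# memdiv — membrane rigidity and bacterial proliferation

`memdiv` links the mechanics of the bacterial cell envelope to the growth
kinetics of the colony.  It implements, end to end and on synthetic data,
the analysis chain for the hypothesis that *E. coli* proliferation is
regulated by membrane rigidity through the FtsZ-driven constriction
instability:

1. **Constriction stability model** (`memdiv.constriction`).  On a
   cylindrical cell of radius *R*, a shape perturbation of wavenumber *q*
   grows at the conserved-dynamics rate

   ω(q) = Λ q² [ζ·u_h − σ_t − κ/R² − κ q²],

   the balance of the FtsZ contractile drive F_c = ζ·u_h against the
   bending/tension resistance F_b = σ_t + κ/R².  Division requires an
   unstable low-q mode; the critical rigidity is
   κ_crit = R²(ζ·u_h − σ_t), and near threshold
   ω_max = Λ(κ_crit − κ)²/(4R⁴κ) — the quadratic criticality in the
   rigidity order parameter Δκ = κ_crit − κ.

2. **Population kinetics** (`memdiv.kinetics`).  Delayed-exponential
   counts N(t) = N₀ exp[G(t − t₀)] with doubling time τ_p = ln2/G,
   delayed-logistic turbidity curves, dose-response maps (linear
   inhibition for membrane stiffeners, Monod G = G_max·c/(K+c) for
   softeners), the effective-rate law G_eff = A·Δκ^β, the
   lag/division-success relation t₀(α), and a structured ODE simulator
   for heterogeneous normal/filament/dead populations whose effective
   optical density tracks biomass, not cell count.

3. **Flicker spectroscopy** (`memdiv.flicker`).  Sub-pixel tracking of
   the phase-contrast halo (maximal radial intensity gradient, parabolic
   refinement, drift and rotation correction), per-site fluctuation
   statistics (σ_h, skewness, Pearson kurtosis), the equipartition
   stiffness estimator K_eff = k_BT·A/Σ² with Σ² = ⟨σ_h²⟩_x, the
   layered-wall scaling K_eff/κ = (D/d)², and bending-modulus recovery
   from vesicle mode spectra.

4. **Fitting** (`memdiv.fitting`).  Nonlinear least-squares estimators
   for all forward models, cytometric phenotype classification at the
   2.9 µm filament threshold, cross-method rate correlation, and the
   master-scaling fit of (A, κ_crit, β) with bootstrap confidence
   intervals.

5. **Synthetic data** (`memdiv.synthetic`).  Seeded generators for every
   input: fluctuating contours with prescribed stiffness, rendered
   phase-contrast movies (50 nm/px, 2000 fps), growth-curve and
   cytometry tables, and master-plot datasets.

The repository is organized as an analysis project: the numbered scripts
under `analysis/` are thin narrative drivers over the library and write
their tables under `results/`.

## Worked example

Recovering the universal scaling from noisy synthetic master-plot data:

```sh
python analysis/04_master_scaling.py
```

prints

```
model: log-log slope of omega_max vs rigidity deficit near threshold = 2.030 (quadratic criticality)
ensemble of 100 noisy master plots (12 kappa points, lognormal sd 0.15):
  mean fitted exponent beta      = 1.979 +/- 0.141
  mean conditional log-log slope = 1.991
  mean fitted kappa_crit         = 35.98 +/- 0.44 kBT
```

The first line verifies on the model side that the maximal constriction
rate grows as Δκ² near the critical rigidity.  The ensemble lines fit
G_eff = A·(κ_crit − κ)^β to one hundred synthetic datasets (12 κ values
in [4, 34] k_BT, multiplicative lognormal noise): the exponent comes back
at 2 and the critical rigidity at 36 k_BT — a softened or stiffened
membrane moves a culture along one universal curve, and growth stops as
κ → κ_crit.

The same chain is available from the command line:

```sh
memdiv generate master --seed 2 --out master.csv
memdiv fit master --in master.csv --out fit.json
# beta=1.87  kappa_crit=35.6 kBT
```

Other entry points: `analysis/01_constriction_model.py` (dispersion
curves, state diagram), `analysis/02_growth_kinetics.py` (dose series,
structured populations, rate correlation), `analysis/03_flicker_stiffness.py`
(stiffness recovery, tracker accuracy, vesicle fits), and the
`memdiv {model,generate,simulate,fit,flicker,pipeline}` CLI.

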