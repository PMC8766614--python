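# Methods

This note documents the models, estimators and numerical choices behind
`memdiv`, and what the synthetic-data tests do and do not establish.

## Constriction stability model

The cell envelope is treated as a Canham–Helfrich membrane with bending
modulus κ (k_BT) and lateral tension σ_t (k_BT·µm⁻²) on a cylinder of
radius R, driven by a homogeneous FtsZ membrane fraction u_h with
contractile coupling ζ (k_BT·µm⁻²).  Since membrane material is locally
conserved, small axial perturbations follow Cahn–Hilliard-type dynamics;
we implement the minimal conserved-dynamics dispersion

ω(q) = Λ q² [ζ u_h − σ_t − κ/R² − κ q²].

This form carries all the structure the analysis needs: ω(0) = 0 exactly
(no uniform growth), a low-q unstable band when the contractile drive
F_c = ζu_h exceeds the resistance F_b = σ_t + κ/R², a linear critical
line κ_crit(u_h) = R²(ζu_h − σ_t) in the (κ, u_h) plane, and closed-form
extremum q* = √(A/2κ), ω_max = ΛA²/4κ with A = F_c − F_b, which yields
exactly the quadratic criticality ω_max ∼ (κ_crit − κ)² near threshold.
A full treatment would derive ω from the nonlinear constriction PDE;
only its linearization is in scope, and Λ absorbs all kinetic prefactors
(hydrodynamic q-dependence of the mobility is neglected).  The marginal
case A = 0 is classified stable (non-dividing).

**Calibration.**  κ₀ = 12 k_BT (bilayer modulus of *E. coli* lipid
extracts), R = 0.5 µm, σ_t = 0, ζ = 480 k_BT·µm⁻², u₀ = 0.3 and Λ = 1
(fixing the time unit).  These place κ_crit(u₀) = 36 k_BT = 3κ₀, so the
κ₀ / 2κ₀ / 3κ₀ triad spans unstable / near-marginal / stable, and
u_crit(κ₀) = 0.1 < 0.23.  All defaults are overridable.

**Finite cells.**  Only quantized axial modes q_n = nπ/L fit in a cell
of length L; `unstable_modes` returns {n ≥ 1 : ω(q_n) > 0}.  Cells
shorter than π√(κ/A) have no unstable mode and cannot divide.

**State diagram.**  The four proliferation regions are qualitative;
fixed cutoffs had to be chosen.  Stable side: region I (exhausted,
near-frozen) requires κ > 2κ_crit(u_h) *and* u_h < ½u_crit(κ₀),
otherwise region II (rigid, hindered).  Unstable side: region IV
(abnormal, softened) for κ < ½κ₀ or u_h > 2u₀, region III (normal) for
κ ∈ [½κ₀, 2κ₀], region II otherwise.  Using u₀ rather than u_crit as
the FtsZ-overload reference keeps the physiological point (κ₀, u₀) in
region III under this calibration, where a u_crit-based cutoff would
misplace it.

## Population kinetics

Counts follow the delayed exponential N(t) = N₀ exp[G(t − t₀)] with
doubling time τ_p = ln2/G and apparent inoculum N₀e^(−Gt₀).  Turbidity
follows the carrying-capacity logistic
OD(t) = Q_∞ / (1 + ((Q_∞−Q₀)/Q₀)e^(−G(t−t₀))), which reduces to the
delayed exponential with prefactor Q₀ while OD ≪ Q_∞.  Dose response:
stiffeners suppress the rate linearly, G = G₀(1 − c/c_inh), clipped at
zero; softeners follow the Monod law G = G_max c/(K+c) with defaults
G_max = 0.7 h⁻¹, K = 20 mM and c_inh = 90 mM.

**Lag and division success.**  With a per-generation division-success
fraction α ∈ (½, 1], the induction delay is modeled as
t₀ = τ_p [1/ln(2α) − 1/ln 2].  The bare 1/ln(2α) form is nonzero at
α = 1, contradicting the zero-lag limit of fully successful division;
subtracting the α = 1 baseline preserves both limits (t₀(1) = 0,
divergence as α → ½⁺, where the population barely replaces itself).

**Structured populations.**  Strata (u, κ, α, count, mean length) evolve
by linear ODEs: normal strata divide at rate αG — with G either given or
derived from G_eff = A·(κ_crit(u) − κ)^β via the constriction model —
filament strata keep constant count while their mean length grows
exponentially, dead strata are inert; optional death and
filament→normal re-entry channels are available (off by default, since
whether dividing filaments rejoin the normal pool is an open modeling
choice).  The generator matrix is propagated exactly with `expm`; strata
with α < 1 switch on after their lag t₀(α).  Effective optical density
is biomass (Σ count·length) times a calibration constant (default 1;
turbidity units are arbitrary), which is why a filamenting culture's EOD
outruns its cell count.  A seeded Gillespie-style birth process is
available as a stochastic variant.

## Fitting

All fitters are nonlinear least squares (lmfit).  Count fits minimize
residuals of log N (variance-stabilizing under multiplicative growth);
OD fits use untransformed residuals with the plateau bounded below by
the largest observation.  Under noise that bound biases Q_∞ slightly
high (the maximum of many noisy plateau points), which propagates to a
few-percent downward bias in G and t₀ — visible in the lag-recovery
ensembles and accepted as the price of the physical constraint.

**Identifiability of the lag.**  Both delayed growth laws depend on
(N₀, t₀) — respectively (Q₀, t₀) — only through a single combination
(the apparent inoculum, resp. the half-rise time), so a curve alone
cannot resolve the lag.  The fitters therefore accept the known inoculum
(N₀ or Q₀, known in practice from the seeding dilution) as an optional
fixed parameter; without it they return the apparent inoculum with
t₀ = 0 and a degeneracy warning rather than a spurious split.

**Master scaling.**  G_eff = A·(κ_crit − κ)^β is fitted on log G with
κ_crit bounded below by max(κ) observed; a conditional log-log slope at
fixed κ_crit is reported alongside the joint fit, and pair-resampling
bootstrap (seeded, 1000 draws by default) gives percentile CIs.  When
the κ grid stays far from threshold (min Δκ > κ_crit/2) the fit raises
an identifiability warning.  Initialization: κ_crit at 1.1·max(κ)+1,
β at 2.

**Cytometry.**  Cells are normal iff L ≤ 2.9 µm (= L₀ + σ_L for the
untreated strain; a cell exactly at threshold is normal).  The biomass
index approximates each cell's footprint as an L×D rectangle and
divides by the field area.

## Flicker spectroscopy

**Tracker.**  For each frame, 128 radial rays are cast from the current
center estimate; the image is sampled along each ray at 0.25 px steps by
cubic spline interpolation, the radial gradient is formed (optionally
Gaussian-smoothed along the ray, default 0.5 px), and the boundary is
the sub-pixel argmax of the signed gradient refined by a three-point
parabola.  The search is confined to a window (±8 px default) around the
previous frame's median radius, which rejects spurious gradient peaks in
noisy movies.  The center is re-fitted per frame by an algebraic circle
fit to the boundary points — its bias is second order in the center
offset, unlike the plain centroid — removing translational drift; a 2-D
Kabsch rotation against the mean shape removes rigid rotation.  The
displacement field is h_i(t) = (r_i(t) − r̄_i)·pixel size, with r̄ the
fiduciary (time-mean) shape.  Frames whose gradient peak falls below the
noise floor on more than 10% of rays are flagged and excluded; isolated
lost rays are filled by periodic interpolation.

On noiseless rendered halos at 50 nm/px the RMS localization error is
~1.4 nm, comfortably below the 5 nm instrument accuracy the method is
specified to reach; the error grows monotonically with image noise.  At
low SNR per-ray precision degrades faster than mode amplitudes do:
spatially coherent modes are still recovered from the contour's Fourier
spectrum after subtracting the white localization-noise floor estimated
from signal-free high modes.

**Moments and stiffness.**  Per-site variance, skewness and Pearson
kurtosis (Gaussian = 3) are computed over time; a site is "soft" when
kurtosis exceeds 3.5 (Gaussian value plus a practical margin), the
signature of intermittent active bursts.  Constant sites are flagged
degenerate with S = 0, kurtosis 3 by convention.  The global amplitude
is Σ² = ⟨σ_h²⟩_x (the variance-mean definition, which the stiffness
formula uses; the mean-of-SD variant is available behind a flag) and

K_eff = k_BT · A / Σ²,    A = πDL (cylindrical side area).

With Σ = 220 nm and A = π·1·3 µm², K_eff ≈ 195 ≈ 200 k_BT.  The
default reference K₀ is 200 k_BT; note the alternative literature-style
normalization K₀ ≈ 100 k_BT that arises when Σ is defined as ⟨σ_h⟩_x —
both conventions are computable here, and the discrepancy is documented
rather than resolved.  The layered-wall relation K_eff = κ(D/d)² links
the whole-envelope stiffness to the bilayer modulus: for D = 4d it gives
the 16-fold amplification (16·12 ≈ 192 k_BT), and for the measured
D = 21 nm, d = 5 nm, ≈ 212 k_BT.

**GUV spectra.**  Vesicle mode variances are fitted on a log scale to
the equipartition spectrum ⟨|h_q|²⟩ = k_BT/[A(κq⁴ + σ_t q²)], over a q
window from mode 3 up to where the variance falls below 4× the
localization noise floor.  If the tension term dominates every fitted
mode the bending modulus is flagged weakly identified.

## Synthetic data

Generators are pure functions of (parameters, seed); identical calls
give bit-identical output.

* **Contours.**  Per-site Ornstein–Uhlenbeck processes (correlation time
  10 ms — temporal correlations are not the analyzed quantity, only the
  stationary variance k_BT·A/K matters) realize the equipartition
  amplitude; soft sites add seeded compound-Poisson bursts (rate 5 s⁻¹,
  amplitude 5σ) that raise the kurtosis above 3 at a nearly unchanged
  variance floor.  An optional low-mode variant distributes the same
  per-site variance over Fourier modes m = 2…M+1 (breathing and
  translation excluded), producing fields smooth along arclength — the
  physical case for bending modes, and the right input for rendering,
  since site-to-site white displacement at 50 nm spacing lies below the
  optical resolution.
* **Images.**  The cell interior is dark; the boundary is a bright halo
  ring with a Gaussian radial profile (width 250 nm by default; the
  Airy halo's central lobe), any PSF width folded in by quadrature, and
  additive Gaussian readout noise.  The halo crest is placed one
  effective halo-width outside the membrane so that the steepest inner
  flank — the feature the tracker locks onto — coincides with the
  membrane, mirroring the calibration of real phase-contrast optics.
  Frames are float32, written as multi-page TIFF when exported.
* **Growth curves.**  Forward models from the kinetics module with
  Poisson noise on counts and additive Gaussian noise (SD = fraction of
  plateau) on OD; dose series map concentration to (G, t₀) via linear
  inhibition (stiffener) or Monod with a saturating lag that approaches
  the ~6 h ceiling (softener).
* **Cytometry.**  Normal pool: truncated Gaussians, L₀ = 1.8 µm,
  σ_L = 0.5 µm, D₀ = 0.52 µm, σ_D = 0.15 µm (the broader caption-style
  parameters σ_L = 1 µm are a preset); filament pool: lognormal lengths
  with arithmetic mean 6 µm, log-SD 0.5, truncated above 3 µm, slightly
  slender widths.
* **Master plots.**  The quadratic law with multiplicative lognormal
  noise (sd 0.15 in log) on 12 κ values uniform in [4, 34] k_BT.

**What the synthetic tests show.**  Parameter-recovery ensembles
establish that the estimators are unbiased at the stated noise levels
and sample sizes, and the render-track round trips establish that the
optical pipeline does not distort fluctuation statistics above the 10%
level.  They do not validate the biological model against real cells:
real movies contain focus drift, uneven illumination, halo asymmetries
and active dynamics with unknown temporal structure, none of which the
renderer emulates.

## Problem sizes and tolerances

Closed-form extremum vs numerical maximization agrees to 1e-6 relative;
the mode-dynamics cross-check (exponential amplification) to 1e-9.
Ensembles use 100 seeds (master scaling, Monod) and 50 seeds (lag
recovery), sizes at which ensemble means are an order of magnitude
tighter than the quoted experimental uncertainties; contour series use
128 sites × 4000 frames; render-track closure uses 40–600 frames at
radius 20–30 px, where the suite completes in well under a minute.
Bootstrap CIs use 1000 draws.  Degenerate inputs (zero variance, flat
dose response, two-point curves, contours leaving the frame) raise
typed errors rather than returning silent fits.
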