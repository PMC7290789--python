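# Methods

## Model

Survival follows a microdosimetric-kinetic picture: the nucleus is divided
into ~1 μm spherical domains; radiation induces potentially lethal lesions
in proportion to the specific energy deposited in each domain; lesions
convert to lethal ones first-order (rate a), pairwise second-order, or are
repaired (rate c). With the cell-cycle-dependent quantities held constant
(appropriate for slowly cycling melanoma, doubling time ≈ 1 day), the mean
number of lethal lesions per nucleus after a delivery split into N intervals
of length ΔT reduces to

    −ln S = Σ_n [(α₀ + γ*_n β₀) Ḋ_n ΔT + β₀ (Ḋ_n ΔT)²]
            + 2 Σ_{n<m} β₀ e^{−(m−n)(a+c)ΔT} Ḋ_n Ḋ_m ΔT²,

with survival S = exp(−⟨w⟩) under the Poisson assumption. Only the
composite parameters α₀ (Gy⁻¹), β₀ (Gy⁻²) and (a+c) (h⁻¹) are identifiable
from survival data; the microscopic rates (a, b_d, c, domain count p, PLL
yield k_d, DNA amounts g) are deliberately not represented individually.
Radiation quality enters only the first-order term, through
γ* = 0.1602·y*/(ρπr_d²) Gy — the dose-mean specific energy per event —
while the quadratic and cross terms carry β₀ alone (the standard MK-model
assumption of LET-independent β₀; a known alternative uses an LET-dependent
β₀ and is out of scope). The 0.1602 constant is 1.602×10⁻¹⁶ J/keV expressed
for keV/μm, g/cm³ and μm so that γ* comes out in Gy; it is exposed as
`KEV_PER_UM_TO_GY`.

For constant rate and quality, the ΔT → 0 limit gives
−ln S = (α₀ + γ*β₀)D + β₀ q(T) D², q(T) = 2[x + e^(−x) − 1]/x² with
x = (a+c)T — the Lea–Catcheside-type protraction factor: q(0) = 1 (acute),
q → 0 (infinitely protracted, quadratic term fully spared).

Internally the package works in hours, Gy and Gy/h; interface layers
(datasets, RBE, schedules, CLI) accept Gy/min because irradiation
conditions are conventionally quoted that way.

## Microdosimetric functionals

Spectra are handled as discretised densities with per-point quadrature
weights: composite trapezoid on the supplied (possibly non-uniform) grid
for continuous spectra, unit weights for point-mass (line) spectra.
Constructed densities are renormalised to unit integral; a factor off by
more than 1% logs a warning. The saturation-corrected dose mean is

    y* = y₀² ∫ [1 − exp(−y²/y₀²)] f(y) dy / ∫ y f(y) dy,

the standard saturation-corrected form with y₀ = 150 keV/μm, which
satisfies y* → y_D for low-LET fields and y* → y₀²/y for single high-y
lines (overkill). Because y* is a linear functional of the dose density,
the y* of a dose-weighted mixture is the dose-weighted mean of component
values; this underpins the two-component BNCT field model, in which the
capture-product dose rate is linear in the ¹⁰B concentration (capture rate
∝ ¹⁰B number density at fixed fluence). The bundled calibration —
background 1.0 Gy/min at y* = 41.36 keV/μm, total field 3.75 Gy/min at
68.50 keV/μm for 10 ppm — yields 0.275 Gy/min/ppm and a boron-component
y* ≈ 78.4 keV/μm. Whether the calibration values include photon
contamination of the neutron facility is a property of those inputs, not of
the mixing model.

## Parameters

| parameter | units | meaning | default / bundled |
|---|---|---|---|
| α₀ | Gy⁻¹ | intrinsic linear coefficient | HX34 0.263±0.016; M8 0.612±0.130; Mel-J 0.002±0.047 |
| β₀ | Gy⁻² | intrinsic quadratic coefficient | HX34 0.047±0.005; M8 0.066±0.020; Mel-J 0.050±0.009 |
| (a+c) | h⁻¹ | SLDR rate | HX34 8.857±2.175; M8 8.769±2.128; Mel-J 8.916±2.126 |
| y₀ | keV/μm | saturation (overkill) parameter | 150 |
| r_d, ρ | μm, g/cm³ | domain radius, density | 0.5, 1.0 |
| reference | — | photon y* and rate for RBE | 2.26 keV/μm, 10 Gy/min |

The photon reference is evaluated with the full protraction factor, not an
acute approximation, so RBE at the reference condition is exactly 1 and the
infinite-test-rate limit is ≈1.002.

## Fitting

The likelihood treats −ln S as Gaussian with a single global σ (estimated
jointly via 1/σ, matching the parameter vector θ = (α₀, β₀, a+c, 1/σ);
experimental per-point SDs, when present, are carried but not used to
weight the likelihood). Priors default to generous uniform boxes
(α₀ ∈ [0,3], β₀ ∈ [0,1], (a+c) ∈ [0,50], 1/σ ∈ (0,100]); sequential
updating turns one chain's posterior marginal into a zero-truncated normal
prior for the next cell line (this is how a well-measured SLDR rate
propagates from the dose-rate-rich HX34 data to M8 and Mel-J). Negative
candidates are rejected through the prior support, which implements the
truncation at zero.

The sampler is random-walk Metropolis, the textbook kernel for a
4-parameter posterior. Burn-in adapts in two phases: component-wise
proposals with per-coordinate widths tuned every 50 sweeps toward a 20–50%
acceptance rate, then the second half of burn-in estimates an empirical
covariance from which a frozen joint Gaussian proposal (2.38²/d scaling) is
built for the retained chain; the post-burn-in kernel is fixed, so the
retained draws target the exact posterior. Defaults are 10⁴ retained draws
after 10³ burn-in; a seed is mandatory and the same seed reproduces the
chain bit-for-bit. Acceptance rates outside [0.05, 0.8] raise a warning,
not an error. No gradient or ensemble samplers are provided; they would be
overkill at this dimensionality.

## MID and RBE

MID is ∫₀^∞ S(D) dD at fixed dose rate (delivery time T = D/Ḋ grows along
the integrand). The integral is truncated where −ln S = 46 (S ≈ 10⁻²⁰,
below double-precision relevance), the cutoff located by bracketing plus
Brent's method, and evaluated by adaptive quadrature at 1e-8 relative
tolerance. Degenerate parameter sets (α = β = 0) are rejected. Closed
forms used as test oracles: MID = 1/α for β = 0, and the acute LQ result
√(π/4β)·exp(α²/4β)·erfc(α/2√β).

Uncertainty bands (68% = 16th–84th percentiles of per-draw RBE) propagate
parameter draws. When only summary means/SDs are available, draws come from
independent normals truncated at zero. This surrogate loses the joint
posterior's correlations and shape; it matters little for cell lines whose
α₀ is many SDs from zero (M8, HX34), but for Mel-J (α₀ = 0.002 ± 0.047,
a posterior piled against the positivity boundary) the truncated-marginal
mean over-weights near-zero α₀ draws, and the resulting mean low-dose-rate
RBE (~0.21 at 1 mGy/min) sits well below what the full joint posterior
would give. The qualitative structure is robust: photon RBE falls
monotonically with dose rate, the fall is much larger for Mel-J than M8,
and the high-LET neutron/BNCT fields lose strictly less RBE than photons.
Draws with non-integrable survival curves are dropped and counted.
Inverse dose-rate effects (enhanced killing below ~0.1 Gy/min reported for
BNCT) are deliberately unmodelled.

## Schedules

A ¹⁰B timeline (monotone-preserving cubic interpolation by default — a
spline that cannot undershoot zero between non-negative knots; boundary
values held outside the knot range) plus a delivery plan (total physical
dose, duration, field components) produce a piecewise-constant schedule:
per-interval (rate, y*) from mixing at the interval-midpoint
concentration, then one global rate rescale so the summed dose equals the
plan total (the prescribed dose is authoritative; the timeline sets only
the shape). ΔT is chosen so (a+c)ΔT ≤ 0.05 and the per-interval dose is
≤ 0.1 Gy, and dose–response evaluations additionally halve ΔT until −ln S
is stable to 1e-4 relative. Truncating a plan at a partial dose is
implemented as re-discretising the shorter prefix, which keeps interval
lengths uniform. The acute reference curve uses the time-averaged
concentration over the delivery and the instantaneous-delivery (q = 1)
survival form.

## Synthetic data

The generators exist so every pipeline stage is testable without external
data, and they encode the study conditions rather than tunable knobs:

* survival datasets add N(0, σ²) noise to −ln S — exactly the fitting
  likelihood — over a default design of doses {1, 2, 4, 6, 8} Gy at rates
  {10, 1, 0.1, 0.01} Gy/min, which spans the protraction transition for
  (a+c) ≈ 9 h⁻¹; observed fractions are clipped at 1. σ = 0.15 is the
  noise scale used in recovery studies. Clipping slightly censors low-dose
  records, a deliberate mismatch with the likelihood that mirrors real
  plating data.
* lineal-energy spectra are deterministic mixtures of log-normal dose-
  density bumps near 0.3, 20 and 200 keV/μm (photon / proton-recoil /
  capture-product scales). They are phenomenological stand-ins with the
  right functional-analysis behaviour (saturation, mixing linearity), not
  track-structure output — passing tests say nothing about any specific
  facility spectrum.
* boron timelines are sin²-rise-then-exponential-decay curves at 1-min
  knots (default peak 25 ppm at 10 min, washout 0.01 min⁻¹, chosen as a
  plausible BPA-like pharmacokinetic shape). Real timelines should be
  loaded from measurement CSVs.

## Numerical choices

* q(T) switches to its series 1 − x/3 + x²/12 − x³/60 below x = 1e-4 to
  avoid cancellation; expm1 is used elsewhere.
* The schedule cross term runs in O(N) via S_m = e^{−(a+c)ΔT}(S_{m−1} +
  d_{m−1}); it agrees with the literal O(N²) double sum to 1e-12 relative.
* The sectioned sum treats each sub-interval as acute, so it converges to
  the constant-rate closed form first-order in ΔT.
* Spectrum quadrature is trapezoidal on the supplied grid (spectra arrive
  pre-binned); single-point spectra are point masses.
* Parameter recovery studies use 24-record designs, 2000 retained draws /
  500 burn-in, 50 replicates — sizes chosen to make the coverage check
  statistically meaningful while staying cheap.

## Known limitations

* No radiation transport: spectra, dose-rate calibrations and timelines are
  inputs.
* β₀ is LET-independent; cell-cycle redistribution, inverse dose-rate
  effects, intercellular communication and heterogeneous intratumoral ¹⁰B
  are all out of scope.
* Summary-level parameter draws ignore posterior correlations (see MID and
  RBE above) — supply real posterior samples via `PosteriorSet` when
  available.
* The Gaussian-on-−ln S likelihood with one global σ ignores per-point
  experimental SDs.
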