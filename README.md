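# imkbnct

Microdosimetric-kinetic modelling of clonogenic cell survival for boron
neutron capture therapy (BNCT) and other irradiations whose **dose rate and
radiation quality change during delivery**.

In BNCT, thermal neutrons captured by ¹⁰B inside tumour cells release short-range
α and ⁷Li particles, so both the absorbed dose rate and the field's
micro-scale energy-deposition density track the cellular ¹⁰B concentration —
which itself rises and decays over a 40–160 min delivery. `imkbnct` is aimed
at computational radiobiologists who need to predict survival, mean
inactivation dose (MID) and RBE under such time-varying conditions, fit the
model to clonogenic survival data, and explore delivery schedules.

## Model

Radiation quality enters through the saturation-corrected dose-mean lineal
energy of the field,

```
y* = y₀² ∫ [1 − exp(−y²/y₀²)] f(y) dy / ∫ y f(y) dy        (y₀ = 150 keV/μm)
```

converted to the dose-mean specific energy per event in a 1 μm domain,
γ* = 0.1602·y\*/(ρπr_d²) Gy. Delivery split into N intervals of length ΔT
with dose rates Ḋ_n and qualities γ*_n gives

```
−ln S = Σ_n [(α₀ + γ*_n β₀) Ḋ_n ΔT + β₀ (Ḋ_n ΔT)²]
        + 2 Σ_{n<m} β₀ e^{−(m−n)(a+c)ΔT} Ḋ_n Ḋ_m ΔT²
```

where α₀ (Gy⁻¹), β₀ (Gy⁻²) are intrinsic radiosensitivity parameters and
(a+c) (h⁻¹) is the sub-lethal damage repair (SLDR) rate. For constant rate
and quality this collapses to the linear-quadratic form
−ln S = (α₀+γ\*β₀)D + β₀ q(T) D² with the Lea–Catcheside-type protraction
factor q(T) = 2[(a+c)T + e^{−(a+c)T} − 1]/((a+c)T)².

On top of this the package provides:

* **microdosimetry** — y_F, y_D, y* from lineal-energy spectra; dose-weighted
  two-component quality mixing (background field + ¹⁰B capture products,
  linear in ppm) with a two-point calibration.
* **fitting** — random-walk Metropolis MCMC for θ = (α₀, β₀, a+c, 1/σ) with a
  Gaussian likelihood on −ln S, and posterior-to-prior updating across cell
  lines. Bundled posterior summaries for the HX34, M8 and Mel-J human
  melanoma lines.
* **rbe** — MID = ∫₀^∞ S(D) dD by adaptive quadrature and
  RBE = D̄_photon/D̄_test against the acute photon reference
  (y* = 2.26 keV/μm at 10 Gy/min), with 68% bands from parameter draws.
* **schedule** — ¹⁰B timelines → time-varying delivery schedules →
  dose–response curves for treatment plans.
* **synthetic** — generators for survival datasets, multi-peak spectra and
  boron timelines matching the model's statistical assumptions.

## Worked example

```python
from imkbnct import (load_cell_line, RadiationQuality, mean_inactivation_dose,
                     rbe_dose_rate_sweep, bnct_quality_components,
                     DeliveryPlan, plan_dose_response, gen_boron_timeline)

m8 = load_cell_line("m8")                       # α₀=0.612, β₀=0.066, a+c=8.769
co60 = RadiationQuality.from_y_star(2.26)       # ⁶⁰Co photons

mean_inactivation_dose(m8, co60, 10.0)          # 1.271 Gy (acute)
mean_inactivation_dose(m8, co60, 1e-3)          # 1.554 Gy (protracted: sparing)

res = rbe_dose_rate_sweep(m8, co60, [1e-3], n_draws=5000, seed=1)
res.mean[0], res.lo68[0], res.hi68[0]           # 0.812, 0.755, 0.869
```

The RBE of 0.81 says that at 1 mGy/min, sub-lethal damage repair makes ⁶⁰Co
γ-rays ~19% less effective per Gy (at the MID endpoint) than the acute
reference; the band propagates the parameter uncertainties.

A BNCT delivery plan with a rising-then-decaying ¹⁰B timeline:

```python
comps = bnct_quality_components()               # calibrated field components
tl = gen_boron_timeline(duration_min=170.0)
for dur in (40.0, 158.0):
    df = plan_dose_response(m8, DeliveryPlan(13.86, dur, comps), tl, [13.86])
    print(dur, df["survival"].iloc[0])
# 40 min  : S = 5.61e-12   (acute reference 8.60e-16)
# 158 min : S = 1.29e-10
```

Stretching the same 13.86 Gy from 40 to 158 min raises survival by a factor
~20: cell recovery during delivery is visible even for the high-LET BNCT
field.

There is also a CLI: `imkbnct --help` (subcommands `microdose`, `survival`,
`fit`, `rbe`, `plan`, `simulate`).

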