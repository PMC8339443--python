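# dcsim — simulating neuronal-activation signatures in diffuse correlation spectroscopy

Diffuse correlation spectroscopy (DCS) measures cerebral blood flow by
autocorrelating the speckle intensity of multiply scattered coherent light.
Neuronal activation perturbs the decay of the autocorrelation through three
mechanisms on very different timescales: fast ballistic motion of neuronal
cell membranes (~1 nm/ms, within ~100 ms of the action potential), dilation
of vessel walls, and the ensuing rise of cerebral blood volume and flow
(onset delayed ~450 ms). `dcsim` is a toolkit for asking, quantitatively,
*which of these signals a DCS instrument can actually detect*: it combines a
photon-migration Monte Carlo with momentum-transfer bookkeeping, speckle
autocorrelation synthesis, a single-compartment neurovascular model, and an
analytical correlator-noise model that converts contrasts into
contrast-to-noise ratios and required channel counts.

It is aimed at researchers designing multi-channel DCS / SPAD-camera systems
for functional brain monitoring and brain–computer interfaces.

## Model

A pencil beam enters a homogeneous semi-infinite medium (reduced scattering
μs′, absorption μa, wavelength λ, k₀ = 2π/λ). For every photon reaching a
detector disk (radius r at distance ρ), the Monte Carlo records the total
pathlength Lₙ and the accumulated dimensionless momentum transfer
Yₙ = Σₛ qₛ²/2k₀² (one unit per transport mean free path for isotropic
scattering), plus the same tallies (Lₙ₂, Yₙ₂) restricted to a localized
activation region. The field autocorrelation is then synthesized per photon:

    g1(τ) = C Σₙ exp(−⅓ α Yₙ k₀² ⟨Δr²(τ)⟩) · exp(−μa Lₙ)

with ⟨Δr²⟩ = 6Dτ for diffusive red-blood-cell motion (blood flow index αD)
and ⟨Δr²⟩ = v²τ² for ballistic cell/wall motion; g2 = 1 + β g1² (Siegert).
Each curve is reduced to a decay time τc by fitting exp(−τ/τc) over its
first 70 μs (within the single-exponential validity window τ < τs, where
τs/τc = √(¾ μa μs′ (ρ² + (z₀+z_b)²)) ≈ 2.6 for the defaults).

The hemodynamic response is a single-compartment model
rd(t) = 1 + Δd·t²·exp(−t²/σ_d²) (relative vessel diameter), with
rCBV = rd², rCBF = rd⁴ (Poiseuille), both peaking at t = σ_d. An activation
measured at delay t_d scales the blood flow index by rCBF(t_d); the relative
contrast is C = Δτc/τc from paired baseline/activated fits on the same
photon ensemble. The correlator noise model σ(τ) (bin time T_b, window T,
coherence β, photons per bin ⟨n⟩) feeds a Monte Carlo of noisy-g2 fits to
give std(τc), and detectability follows from CNR = C·τc/std(τc) with
√N_c channel averaging.

## Worked example

```python
from dcsim import *

medium   = OpticalMedium()              # mu_s'=1/mm, mu_a=0.01/mm, 800 nm
geometry = DetectionGeometry()          # rho=30 mm, detector radius 2 mm
records  = run_mc(medium, geometry, ActivationRegion(), 2_000_000, seed=123)
print(records.n_detected)               # -> 317 detected photons

g1 = g1_from_records(records, DynamicsSpec.baseline(1e-6))
print(fit_tau_c(g1).tau_c * 1e6)        # -> 40.6  (baseline tau_c in us)

model = HemodynamicModel()              # delta_d=0.07, sigma_d=1.83 s
res = contrast_hemodynamic(records, model,
                           MeasurementWindow(td=model.peak_time(), T=0.01))
print(res.contrast)                     # -> 0.271 (global peak Delta tau_c/tau_c)

dist = estimate_std_tau_c(NoiseParams(), n_instances=10_000, seed=7)
print(dist.std_ratio)                   # -> 0.0687 (noise floor std(tau_c)/tau_c)
print(required_channels(res.contrast, dist.std_ratio))   # -> 1 channel
```

The numbers above were printed by this code: a 2×10⁶-photon run detects 317
photons at ρ = 30 mm; the fitted baseline decay time is ≈ 41 μs; at the peak
of the flow response (1.83 s after dilation onset) the global activation
shifts τc by ≈ 27%, far above the single-channel noise floor of ≈ 7%, so a
single channel already detects it. Local activations and fast cell-motion
signals come out orders of magnitude smaller (≈ 4×10⁻³ and ≈ 10⁻⁵–10⁻⁷
respectively); see `docs/methods.md` for what that implies.

A command-line interface mirrors the library:

```
dcs-sim mc --n-photons 2e6 --seed 1 --out records.h5
dcs-sim g1 --records records.h5 --alpha-d 1e-6 --out g1.tsv
dcs-sim fit --in g1.tsv --window 70e-6
dcs-sim contrast --mechanism hemo --scope global --td 1.83 --records records.h5
dcs-sim noise --instances 10000 --nc 1
dcs-sim experiment --experiment fig10 --records records.h5 --out sweep.tsv
```

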