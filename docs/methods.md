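# Methods

This note documents the models in `dcsim`, the defaults they carry, the
numerical choices behind the fits, what the synthetic ensembles do and do not
represent, and the places where the design was genuinely open.

## Photon transport

The medium is a homogeneous half-space (z > 0). A pencil beam enters at the
origin along +z; free paths are exponential with mean 1/μs, and scattering is
isotropic. Because only the reduced scattering coefficient μs′ is specified
for brain tissue at this level of abstraction, we set g = 0 and μs = μs′:
under isotropic scattering the dimensionless momentum transfer per event,
q²/2k₀² = 1 − cosθ, averages to exactly 1, so the accumulated Y equals the
path length in transport mean free paths and the diffusing-wave exponent
⅓·Y·k₀²·⟨Δr²⟩ is exact. The identity ⟨Y⟩ = μs′⟨L⟩ is asserted in tests.

**Absorption** is never applied during transport. Each detected photon
carries its pathlength L, and every downstream curve weights it by
exp(−μa·L). Records are therefore independent of μa, which the tests check
by re-running the same seed at different absorptions. Transport is cut off
at a fixed maximum pathlength of 1400 mm — chosen so the neglected survival
weight exp(−μa·L) stays below 10⁻⁶ at the default μa = 0.01 mm⁻¹ — rather
than by an absorption-dependent roulette, precisely to preserve that
independence.

**Boundary.** Photons hitting z = 0 undergo unpolarized Fresnel
reflection/transmission with relative index n_rel. The default
n_rel = 1.3274 is the numerical solution of the Haskell effective-reflectance
integrals for an extrapolation parameter A = 2.5, which makes the Monte
Carlo consistent with the correlation-diffusion benchmark that uses
z₀ = 1/μs′ and z_b = (5/3)/μs′. The absorption-weighted detected fraction
agrees with the diffusion-theory reflectance integrated over the detector
disk to a few percent (tests require 25%). Transmitted photons are recorded
only if they exit through the detector disk (|r − (ρ,0,0)| ≤ r_det, all
angles accepted); all other exits terminate the photon.

**Pruning.** A photon is terminated early when the straight-line distance to
the nearest point of the detector disk exceeds its remaining pathlength
budget. Such a photon can never be recorded, and any surface exit outside
the detector terminates it anyway, so the pruning changes no recorded
statistic; it only saves time.

**Activation region.** Local tallies (L2, Y2) accumulate segment lengths
clipped against, and scattering events inside, an axis-aligned box. The
default box is 10×10×4 mm centred at (x, y, z) = (15, 0, 15) mm. The
wording "at z = 15 mm, x = 15 mm" is ambiguous between the box centre and a
face; we centre it (the symmetric reading) and make it configurable.
Local contrasts are sensitive to this choice: the weighted Y2/Y fraction is
≈ 1.6% for the centred box and roughly doubles if the box sits 2 mm
shallower, which is the main caveat when comparing local-scope numbers
against published ones. Setting the region to the whole half-space forces
L2 = L and Y2 = Y bitwise, which collapses the two-tissue decomposition to
the global form exactly — an identity the tests exploit.

**Reproducibility.** Photons are traced in fixed chunks of 10⁶ with chunk
seeds derived deterministically from the user seed, so output is
bit-reproducible and independent of detection-buffer sizes.

## Autocorrelation synthesis and the decay time

Every dynamics specification reduces, per photon, to a linear-plus-quadratic
exponent aₙτ + bₙτ²: diffusive components (blood) contribute
2·αD·k₀²·Y_scope to aₙ, ballistic components (cell membranes, vessel walls)
contribute ⅓·α·k₀²·v²·Y_scope to bₙ, and the within-window flow transient
αD(1 + Rτ) adds its cross term 2·αD·k₀²·R·Y_scope to bₙ. Scopes select Y
(global), Y2 (region) or Y − Y2 (outside). Normalization g1(0) = 1 is
automatic. The correlation-diffusion closed form for the semi-infinite
medium, with K² = 3μaμs′ + 6μs′²k₀²·αD·τ and decaying exponentials
exp(−K·r)/r, provides the independent analytic route; at the default
parameters the two routes agree to max|Δg1| ≤ 0.02 over [0, 3τc] — our
quantification of "good agreement", stated as a repo-defined acceptance.

The decay time τc is a least-squares fit of exp(−τ/τc) on a linear τ grid
(1-μs bins, window 70 μs ≈ 1.6 τc, safely inside the single-exponential
validity bound τs/τc ≈ 2.6). The fit has one free parameter; we solve the
stationarity condition of the sum of squares by bracketing and bisecting the
gradient to machine precision (relative tolerance 10⁻¹⁵). This matters
because paired contrasts as small as 10⁻⁸ are formed as differences of two
τc values: both fits run on the same photon ensemble and the same grid, so
Monte Carlo error cancels and solver error is the only floor. Least squares
is done on the linear scale (not log) to avoid over-weighting the tail.
A flat curve raises an explicit fit error.

The printed formula for the validity bound τs omits a square root: taken
literally, τc·(¾ μaμs′(ρ²+(z₀+z_b)²)) gives 6.8, inconsistent with the
stated value 2.6; the square-root reading √(¾ μaμs′(ρ²+(z₀+z_b)²)) = 2.608
reproduces it and is what `tau_s_ratio` implements.

For slowly decaying curves (neuronal motion only), the fit window is
meaningless at 70 μs, so the decay time is reported on an extended
log-spaced grid (1 μs – 300 ms) both as the 1/e crossing and as an
exp(−τ/τc) fit over the full grid. The two differ because the ensemble
curve is strongly non-exponential; the 1/e value is the primary one.
There is a useful exact relation here: baseline (diffusive, exponent ∝ Y·τ)
and neuronal-only (ballistic, exponent ∝ Y·τ²) curves are the same Laplace
transform of the weighted Y distribution evaluated at different arguments,
so their 1/e times obey τ_neuronal = √(6·αD·τ_base/v²) — ≈ 16 ms for
τ_base ≈ 43 μs at the defaults. A substantially larger neuronal decay time
is not attainable for any Y distribution consistent with the baseline τc.

## Activation mechanisms

**Hemodynamics.** rd(t) = 1 + Δd·t²·exp(−t²/σ_d²) with defaults Δd = 0.07
and σ_d = 1.83 s (the literature-recommended values for the single-
compartment model); rCBV = rd² (cylindrical vessels, fixed length),
rCBF = rd⁴ (Poiseuille at fixed pressure drop). Both peak at t = σ_d
exactly; `peak_time()` finds it by bounded 1-D search. The baseline blood
flow index is αD = 10⁻⁶ mm²/s (giving a physiologically plausible decay
time), the baseline RBC scattering probability α₀ = 2% (≈ vascular volume
fraction). During activation α scales with rCBV and D with flow speed;
their product is driven by rCBF, so the implementation scales αD directly
by rCBF(t_d). For measurements starting at t_d = 0 the only effect is the
within-window transient, linearized as αD·(1 + R·τ) with
R = (rCBF(t_d+T) − rCBF(t_d))/T; for t_d > 0 this term is several orders of
magnitude below the t_d effect and is off by default (a flag enables it).
The vessel-wall phase term uses v_wall = (d₀/2)·d(rd)/dt with a nominal
d₀ = 20 μm (no value is specified in the source literature; only the
"≥ 5 orders smaller than volume/flow" property is asserted, not an absolute).

**Cell motion.** Ballistic with v = 1 nm/ms and neuronal scattering
probability 1 (best case). Contrast scales as v² in the small-signal
regime (property-tested). The diffusive-equivalent variant chooses a
hypothetical diffusion coefficient whose neuronal-only curve has the same
1/e decay time as the ballistic one (root-found in log D), and shows the
2–3 order-of-magnitude contrast amplification a diffusive-like motion would
produce — the core of why ballistic nanometre motion is so hard to see.

**Paired evaluation.** Every contrast is computed from baseline and
activated fits on the *same* record set, making C a smooth deterministic
functional of the ensemble: at 2×10⁶ launched photons (a few hundred
detected) the global contrasts are stable to a few percent, the local ones
to tens of percent; seed-to-seed spread shrinks as N⁻¹ᐟ².

## Noise and detectability

σ(τ) implements the correlator noise model exactly as printed (√(T_b/T)
prefactor; β² correlation bracket over (1 − e^(−2ΓT_b)); shot-noise terms
2⟨n⟩⁻¹β(1+e^(−2Γτ)) and ⟨n⟩⁻²(1+βe^(−Γτ))), with τ restricted to the bin
grid m·T_b, m ≥ 1. Noisy curves add independent zero-mean Gaussian
perturbations per bin — optimistic relative to physically correlated
correlator noise, and stated as such. Fits of noisy curves fix β at its
true value and free only τc (vectorized bisection over the whole ensemble);
fits whose gradient never brackets a root are discarded and counted
(discard rate ≈ 0 at the default noise level). Channel averaging scales σ
by 1/√N_c, which is distributionally identical to averaging N_c Gaussian
channels and is verified against explicit averaging at N_c = 4. The default
ensemble is 10⁴ instances. Detectability: N_c(CNR=1) = ceil((std_ratio/C)²),
and the earliest detectable delay is the first point of the 50-ms t_d grid
(50 ms – 2 s) with C(t_d) ≥ 1/SNR; adding the 450-ms dilation-onset lag
converts to latency after neuronal activation.

With the stated parameters (T_b = 1 μs, T = 10 ms, β = 1, ⟨n⟩ = 0.1,
τc = 46 μs) this chain yields std(τc)/τc ≈ 0.069, in agreement with the
Cramér–Rao bound for a one-parameter fit over 70 one-microsecond bins
(σ_bin·τc/√(Σ u²e^(−2u)) ≈ 2.9 μs). Published figures around 0.28 for
comparable parameters correspond to substantially less informative fits
(e.g. a ~12-μs window or a threshold-crossing estimator); we keep the
stated protocol and report the number it produces.

## Problem sizes and what the tests show

Default budgets: 2×10⁶ launched photons in the test suite (~320 detected),
2×10⁷ in `scripts/acceptance.py` (~3200 detected), 10⁴ noise instances
everywhere; `--full`/`--n-photons` restores the 10⁸-photon scale on a
cluster. The synthetic ensembles emulate a homogeneous semi-infinite head
with a single activation box and uncorrelated scatterer motion. They do not
contain layered anatomy (scalp/skull/CSF), pulsatile or correlated flow,
detector afterpulsing or dead time, or pericyte/glial mechanics — so
passing tests demonstrate internal consistency of the transport,
correlation, and noise chains at these idealized conditions, not agreement
with in-vivo data.

## Known limitations

- Homogeneous medium only; no layered or voxelized geometry, no
  polarization, no time-of-flight gating.
- Single-compartment hemodynamics; multi-compartment (windkessel) delays
  between CBV and CBF peaks are out of scope.
- Bin-to-bin noise independence overstates the benefit of dense τ grids.
- Local-scope contrasts depend on the activation-box placement convention
  (see above) at the factor-of-two level.
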