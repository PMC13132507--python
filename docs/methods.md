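# Methods

This note records the model, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Two-time-scale thermoacoustic model

The pressure field obeys the thermoacoustic wave equation whose source is
the fast-time derivative of the heating rate, scaled by the Grüneisen-like
factor β/C_p.  Fast time t (microseconds, acoustic propagation) and slow
time τ (seconds, temperature and ablation state) are treated as
independent: within one 400 µs chirp the tissue state is frozen; between
one-second frames only the amplitude map evolves.  Thermal confinement
holds because the modulation period is far shorter than any thermal
diffusion time at the acoustic wavelengths involved.

Carrier-frequency terms (GHz and twice-carrier mixing products) attenuate
within micrometres and lie far outside the receiver band; the package
never synthesises them and models heating directly through the envelope
`g(t) = 1 − cos(4π(fr/2 t² + f0 t))`.  The analytic identity
`g = 2x²` (untapered) is enforced by test.

### Waveforms

The Hamming edge tapers reduce spectral leakage of the finite chirp; the
taper length is not physically constrained, so `taper_fraction` defaults
to 0.1 of the chirp and is configurable.  The hold segment that keeps the
delivered power at the clinical average is a single tone at `f1`
continuing the chirp's end phase, scaled so its mean squared modulation is
half the chirp's.  All generators are deterministic on a sample-centred
uniform grid starting at t = 0, so fixtures are reproducible bit for bit.

Instantaneous frequencies are measured, not assumed: the analytic-signal
phase is fitted with a local quadratic (exact for linear chirps) away from
the Hilbert edge artefacts and differentiated.

## Forward model and reconstruction

The forward operator is the 2-D ring-plane discretisation of the
delta-heating solution: for each element, pixel amplitudes are binned into
arrival-time samples (`|x − x_e|·fs/v_s`, linear interpolation) with
spherical-spreading weight `pixel_area/(2π·distance)`, followed by a
central-difference time derivative at the sampling rate.  The adjoint is
the exact algebraic transpose and is verified by inner-product tests; UBP
back-projection applies the filter `b(t) = 2p − 2t·dp/dt` with uniform
per-element weights and linear interpolation at fractional delays.
Element directivity, bandwidth and acoustic attenuation are not modelled;
the speed of sound is a per-run constant (default 1540 m/s — the
`metrics` module quantifies the ~0.6 mm displacement error a 20 m/s
thermal rise would cause over a 5 cm path, and the matching ~1.2 mm
coherence-limit wavelength).

Wiener deconvolution normalises the reference spectrum to unit peak power
before adding λ = 0.1, making the regulariser scale-free regardless of
amplitude units (the literature leaves the normalisation open; the
absolute reading would make 0.1 meaningless for arbitrary units).  FFT
length is the next power of two at least twice the trace length, so the
deconvolution is linear, and integer delays are recovered exactly.

The expected pulse-compression SNR gain of the chirp over a pulse of
equal peak power is implemented and tested as the square root of the
time–bandwidth product, √(tc·(f1−f0)) ≈ 19.5; some renderings print the
product without the root, but the root form is the standard
pulse-compression result and is what the Monte-Carlo matched-filter test
reproduces.

## Synthetic experiments

`make_probe_phantom` builds an anisotropic Gaussian deposition blob around
the probe (default 4 mm lateral / 8 mm axial standard deviations, 100 W
volume-integrated power, uniform effective conductivity 2 S/m with
`E0 = √(Q0/σ_eff)` so the quadratic field law holds).  The true
electric-field profile of a commercial probe is not published; the blob
is a stand-in whose scales are free parameters.

`rise_matched_phantom` (6 mm / 12 mm, 100 W) is the documented
configuration whose probe-tip heating rate is ~4 °C/s from an 18 °C
start.  It was sized by a closed-form argument: a 15–25 % amplitude rise
over 5 s with the linear β(T) model requires a tip-region heating density
near 1.4·10⁷ W/m³, which at 100 W total fixes the blob volume.  The
reconstructed tip amplitude of this configuration rises ~19 % over the
first five seconds, near-linearly — the regime in which the early-rise
calibration is valid (no ablation inside the fit window).

`synth_experiment` closes the loop: each frame's TA source is the true
heating map scaled pixelwise by β(T)/β(T_init) — switching to the constant
ablated-tissue β = 3·10⁻⁴ °C⁻¹ where the ground-truth damage integral has
crossed threshold — forward-projected with the chirp source profile
−π(β/C_p)·fm(t)·x2f(t) and corrupted by seeded white Gaussian channel
noise (SNR defined on the mean square of the coded trace block).  C_p
variation with temperature is deliberately not fed back into the TA
amplitude: the calibration models only the β rise, and the generator
matches that assumption so parameter-recovery tests isolate the pipeline
rather than the assumption.  Ground truth (heating map, mid-plane
temperature and damage histories, amplitude-scale maps) is returned so
every downstream error is computable without re-simulation.

What the generator does **not** emulate: tissue heterogeneity and
mm-scale acoustic texture, element directivity and bandwidth, acoustic
attenuation, speed-of-sound drift, steam bubbles, perfusion.  Passing
recovery tests therefore demonstrate internal consistency of the method
under its own assumptions, not field performance on real tissue.

## Thermal model

Explicit finite differences with face-averaged (arithmetic-mean)
diffusivity, Dirichlet ambient boundaries by default (water-immersed
sample; insulated optional), N-dimensional.  The stability bound
`max(α)·dt/dx² ≤ 1/(2·ndim)` is enforced.  Property evaluation is clamped
at 100 °C: the published ρC_p correlation grows super-exponentially
(≈24 MJ m⁻³ °C⁻¹ at 50 °C, ≈211 at 60 °C), which acts as a strong
enthalpy throttle well below boiling.  This is implemented exactly as
published and is the dominant model-side limitation: simulated
temperatures plateau in the high-40s to low-60s °C for clinically
plausible heating densities, so ablation boundaries sit close to the
Arrhenius threshold and are sensitive to small heating-amplitude errors.
Phase change, tissue shrinkage and perfusion are not modelled.

The axial weight `w(z) = √(r_probe² − z²)` (|z| < r_probe ≈ 1 cm) is read
as the chord profile of the radiating segment's circular cross-section
and normalised to unit z-integral, so a 2-D slice image inflates to a 3-D
volumetric density without changing total power; the normalisation
constant would otherwise be absorbed into K by the calibration.

Dimensionality is a run choice.  The default configuration solves the
2-D imaging plane (cheap, adequate for short-window calibration); the
monitoring pipeline and the ground-truth generator both support
`dimension: 3`, where the image stack is inflated by w(z), the true blob
extends as a Gaussian out of plane, and temperature/damage records are
mid-plane views.  End-to-end zone validation uses 3-D: in 2-D the absent
out-of-plane conduction lets the low-level artefact floor of the envelope
images (back-projection streaks rectified by the envelope, a few per cent
of peak) accumulate heat indefinitely and inflate the zone; in 3-D such
weak sources reach sub-threshold steady states and the recovered diameter
agrees with ground truth to a few per cent.

The damage integral uses trapezoidal accumulation at the recording
interval (1 s), second-order accurate for the smooth slow-time
temperature histories involved; the 60 s post-exposure cool-down is
always included.  The reported zone is the mid-plane Ω > 1 contour, and
its width the geometric mean of the second-moment (inertia-equivalent)
ellipse axes of the binary mask — deterministic and orientation-free.
Error tables aggregate signed per-sample percentage errors (signed mean,
signed-squared RMS), which reproduces published footers from published
per-sample values exactly.

## Calibration numerics

The scalar search runs Brent-style bounded minimisation over log₁₀K,
three decades either side of a slope-matched initial guess
(`K_guess = slope·β₀·ρC_p(T₀) / (β'·w(0)·Ī_tip)`), 1e-4 log-tolerance.
Series with no positive amplitude rise, or solutions pinned at the search
bounds, are flagged `degenerate` rather than trusted.  T₀ is the
experiment's initial temperature (not 37 °C): the normalisation is at
τ = 0, even though the β model is anchored at 37 °C.  Each trial K holds
the τ = 0 heating estimate constant across the 5 s window, consistent
with the observed stability of tissue dielectrics below ~50 °C.

Recovery scoring defines the ground-truth scale as
`K_true = ⟨Q₀_true⟩_tip / (w(0)·⟨I_TA(τ=0)⟩_tip)` — the scale for which
the calibrated image reproduces the true tip heating.  Measured recovery
on the documented configuration: within ~2–5 % noiseless and within ~4 %
per seed at 20 dB channel SNR.

## Desk-scale problem sizes

The full-resolution acquisition (512 × 512 pixels at 0.25 mm, 0.25 mm /
10 ms thermal grid, 3-D) is supported by the same code paths, but the
validation suite runs desk-scale configurations chosen once: 128-pixel /
1 mm imaging and thermal grids, 49 z-planes, 50–100 ms thermal steps,
120 s exposures, 128–512 ring elements.  Grid-refinement tests bound the
discretisation effect on peak temperature at under 2 %.
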