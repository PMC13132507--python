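# tamon — thermoacoustic monitoring of microwave ablation

Microwave ablation (MWA) necroses centimetre-scale tumours with a 2.45 GHz
needle antenna, but clinicians have no practical way to watch the thermal
lesion grow during the procedure.  `tamon` implements a monitoring method
that needs no extra hardware beyond amplitude modulation of the ablation
source: modulating the carrier with a linear chirp makes the tissue heating
rate — proportional to the squared electric field — oscillate at twice the
modulation frequency, launching thermoacoustic (TA) pressure waves.  A ring
of ultrasound receivers records those waves every second; pulse compression
and back-projection turn them into images of the spatial heat deposition;
a short self-calibration converts the images into an absolute heating
function that drives a bioheat model and a thermal-damage integral, giving
a live estimate of the ablation zone.

The package is aimed at researchers in photoacoustic/thermoacoustic imaging
and thermal-therapy modelling who want a complete, testable reference
pipeline plus a synthetic-data generator that closes the physics loop the
calibration must invert.

## The model

* **Excitation.** Modulating chirp `x(t) = sin(2π(fr/2·t² + f0·t))` with
  `f0 = 0.05 MHz`, `f1 = 1.0 MHz`, `tc = 400 µs`, chirp rate
  `fr = (f1−f0)/tc`.  Heating follows `g(t) = 1 − cos(4π(fr/2·t² + f0·t))`,
  so the TA source term rides on the frequency-doubled chirp
  `x2f(t) = sin(2π·fr·t² + 4π·f0·t)` (0.1–2.0 MHz), ramp-weighted by the
  instantaneous modulation frequency `fm(t) = fr·t + f0`.
* **Acquisition.** 512-element, 60 cm ring array, 1 MHz centre frequency,
  5 MSPS; one averaged frame per second of slow time τ.
* **Pulse compression.** Wiener deconvolution with the expected response
  `r(t) = fm(t)·x2f(t)` and a scale-free noise-to-signal regulariser
  λ = 0.1.
* **Reconstruction.** Universal back-projection (`b(t) = 2p − 2t·dp/dt`)
  of the deconvolved channels and of their Hilbert transform; the pixelwise
  modulus of the pair is a non-negative envelope image `I_TA`, masked to a
  5 cm disk around the probe.
* **Calibration.** Early in the ablation the tissue heats rapidly but is
  not yet ablated, so `I_TA` near the probe tip rises in proportion to the
  thermal-expansion coefficient `β(T) ≈ 3.5·10⁻⁴ + 3·10⁻⁶ (T − 37 °C)`.
  The scale `K̂` minimising the mismatch between the observed normalised
  rise and the rise modelled from `Q₀ = K·w(z)·I_TA` over τ = 0…5 s gives
  the heating function in W/m³ (`w(z) = √(r_probe² − z²)`, normalised).
* **Thermal model and damage.**
  `∂T/∂τ = ∇·(α(T)∇T) + Q₀/(ρC_p(T))` with the strongly
  temperature-dependent liver correlations
  `ρC_p(T) ≈ 3.542 + 1.79·10⁻⁴ e^{0.233T}` MJ m⁻³ °C⁻¹ and
  `α(T) ≈ 1.55·10⁻⁷ + 4.95·10⁻¹⁶ e^{0.201T}` m²/s, solved explicitly in
  2-D or 3-D, plus 60 s of cool-down.  Ablation is scored by the Arrhenius
  integral `Ω = A∫exp(−Ea/(R·T_K))dτ` with `A = 7.39·10³⁹ s⁻¹`,
  `Ea = 2.577·10⁵ J/mol`; `Ω > 1` (≈63 % cell kill) defines the zone, and
  the reported width is the geometric mean of the fitted ellipse axes.

## Worked example

Simulate a 30 s, 100 W ablation on a desk-scale grid and monitor it:

```bash
cat > desk.yaml <<'YAML'
array:       {n_elements: 128}
reconstruction: {n_pixels: 128, pixel_size: 0.001}
phantom:     {sigma_lateral: 0.006, sigma_axial: 0.012}
thermal:     {dx: 0.001, dt: 0.1, dimension: 3, nz: 49}
run:         {duration: 30.0, seed: 7}
YAML
tamon simulate -c desk.yaml -o run.h5
tamon monitor  -i run.h5 -c desk.yaml -o results.h5 --report report.txt
```

which prints

```
K_hat = 1.97058e-06 (residual 2.66e-07)
final geometric-mean ablation diameter: 21.8 mm
```

`K_hat` is the calibration scale converting envelope-image units into
W/m³ (together with the axial weight `w(0)`); its residual is the final
sum-of-squares mismatch between the observed and modelled five-second
amplitude rise.  The report adds the fitted ellipse axes (here
31.4 mm × 15.2 mm, elongated along the probe axis) and the estimated
diameter frame by frame, the quantity a closed-loop controller would
watch.  The same pipeline is available from Python via
`tamon.run_simulate` / `tamon.run_monitor`, and every stage
(waveforms, forward model, deconvolution, reconstruction, calibration,
thermal, damage, metrics) is importable on its own.

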