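# implumen

Coupled optical-reflectance, wireless-power and electromagnetic-dosimetry
modelling for an implantable photonic neurostimulator.

Implantable photobiomodulation devices face two design constraints at
once: the light source must be tuned to the wavelength at which cortical
blood vessels modulate the reflected signal most strongly over the
cardiac cycle, and the wireless power link that charges the implant must
keep electromagnetic absorption in the surrounding tissue below the
localized-exposure safety limit. `implumen` is a desk-scale pipeline that
treats both questions with analytic and Monte Carlo physics instead of a
commercial finite-element solver, for engineers and modellers evaluating
implant operating points before committing to full-wave simulation or
bench work.

## Models

**Pulsatile reflectance.** A layered brain phantom (polyurethane
encapsulant, CSF, gray/white matter, cerebellum; embedded vessel) is
driven by a piecewise cardiac pressure waveform
P(t) = (1−α)·sin(π(t−t₀)) during initialization and
(1−α)·cos(2π(t−t₀)) during the pulsatile phase, mapped to the vessel
blood volume fraction f(t) = f₀(1 + βP(t)). Reflectance follows a
double-pass modified Beer–Lambert model

    R(λ, t) = S_alb · exp(−Σₖ 2dₖμₐ,ₖ/cosθₖ − L_rt · μₐ,blood(λ, SO₂) · f(t)/f_ref)

with whole-blood absorption μₐ,blood = SO₂·μₐ,HbO₂ + (1−SO₂)·μₐ,Hb from a
packaged 400–890 nm table. The per-wavelength cardiac reflectance
variation ΔR = max_t R − min_t R is summarized over the 400–500, 500–600
and 600–800 nm bands; a 2D Monte Carlo transport engine (Henyey–Greenstein
scattering, Fresnel entry, exact energy bookkeeping) cross-validates the
analytic model in its closed-form limits.

**Wireless power link.** The 15 µH receiving coil is tuned with
C = 1/(L(2πf₀)²) to resonate at 1.35 MHz; the reflection coefficient
S11(f) = (Z−z₀)/(Z+z₀) of the series R-L-C branch gives the return loss
−20·log₁₀|S11| and delivered power 1−|S11|².

**SAR dosimetry.** On a voxelized head phantom (hemispherical brain, head
shell, implanted device), the coil's Biot–Savart vector potential gives
the magneto-quasistatic induced field |E| = ω|A|, pointwise
SAR = σ|E|²/ρ, and 10 g mass-averaged SAR via spherical, hemispherical or
adaptive air-excluding kernels (10 g at ρ = 1007 kg/m³ ⇒ sphere radius
1.33 cm). The peak of the averaged map is compared against the 2 W/kg
limit.

See `docs/methods.md` for assumptions, calibration constants and
limitations.

## Worked example

```python
from implumen import reflectance as ra, sar, wpt
from implumen.phantoms import make_phantom_2d, make_phantom_3d, Phantom3DConfig
from implumen.spectra import load_spectra

spectrum = load_spectra()
sweep = ra.wavelength_sweep(
    make_phantom_2d(), spectrum,
    wavelengths_nm=[l for l in spectrum.wavelengths_nm if 600 <= l <= 800])
(band,) = ra.band_analysis(sweep, bands=[(600, 800)])
print(f"optimal wavelength : {band.argmax_wavelength:.0f} nm")
print(f"delta-R at optimum : {max(band.delta_r_sim):.4f}")

report = wpt.design_report()
print(f"tuning capacitance : {report['capacitance_F']*1e12:.1f} pF")
print(f"return loss at dip : {report['min_return_loss_db']:.2f} dB")
print(f"power delivered    : {report['delivered_power_fraction']*100:.2f} %")

phantom = make_phantom_3d(Phantom3DConfig(voxel_m=0.004))
coil = wpt.CoilSpec()
field = sar.induced_efield(phantom, coil, sar.default_drive_current(coil), 1.35e6)
smap = sar.pointwise_sar(field, phantom)
avg = sar.mass_averaged_sar(smap, phantom, sar.AveragingKernel(shape="hemisphere"))
print(f"peak 10 g SAR      : {avg.peak:.3e} W/kg (limit 2.0)")
```

prints

```
optimal wavelength : 660 nm
delta-R at optimum : 0.0737
tuning capacitance : 926.6 pF
return loss at dip : 29.89 dB
power delivered    : 99.90 %
peak 10 g SAR      : 4.858e-06 W/kg (limit 2.0)
```

660 nm is the wavelength at which the cardiac cycle modulates reflectance
most strongly in the red/near-infrared band (ΔR ≈ 0.074 of the
backscatter albedo); the coil needs ≈927 pF to resonate at 1.35 MHz, where
the matching dip reflects ~0.1 % of incident power; and the peak 10 g
mass-averaged SAR of the implanted coil's induced field sits orders of
magnitude under the 2 W/kg localized-exposure limit (absolute SAR scales
with the square of the assumed 23.7 mA RMS drive current — see the
methods note).

The same stages run from the shell:

```sh
implumen all --seed 1 --out runs/demo     # fixtures, reflectance, bands, wpt, sar
implumen wpt --out runs/link              # Touchstone .s1p + design report only
```

Each run directory receives the effective config, per-stage artifacts
(band summary CSV/JSON, `coil.s1p`, SAR report) and a `summary.json`.

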