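# Methods

## Absorbance inference

The probe geometry gives no absolute reflectance calibration, so absorption
is inferred, not measured. The default rule treats light that did not return
to the probe as absorbed and takes the absolute difference between the lamp
reference and the measured spectrum. A bare difference is sensitive to
probe–tissue coupling (which varies with contact pressure and slippage), so
the reference is first amplitude-matched to the measured spectrum: it is
scaled by the ratio of mean intensities over an anchor sub-band, default
590–600 nm, where haemoglobin absorption is weakest within the fitting
window. Setting `scale_reference=False` disables the matching, which makes
the rule the exact inverse of the synthetic forward model. A `log-ratio`
variant, `A = log10(reference/measured)` with the measured spectrum floored
at `1e-6 × max(reference)`, is provided because the absolute difference is
not a Beer–Lambert absorbance; the absolute difference remains the default
for fidelity to the acquisition protocol this package targets. Both rules
restrict output to the 500–600 nm fitting window.

The amplitude matching slightly perturbs recovered absorbance shapes (the
residual term `(1−s)·reference` is smooth and is mostly absorbed by the
background polynomial); on noiseless synthetic data it shifts StO₂ by less
than 0.01, and it cancels entirely in differences over time, which is what
the event detection and step-down analyses consume.

## Haemoglobin model fit

The absorbance model is linear in the two haemoglobin amplitudes and the
background polynomial coefficients. The background uses a centred, scaled
coordinate `u = (λ − λ_c)/50` (λ_c the window centre) so the normal
equations stay well conditioned; default degree 2, enough to absorb
lamp-shape and scattering trends without competing with the ≈30 nm-wide
haemoglobin bands, and configurable. Amplitudes are constrained non-negative
so StO₂ = a_HbO₂/(a_HbO₂+a_Hb) stays in [0, 1]; the background is
unconstrained. Because the problem is convex, the solution is found exactly:
an unconstrained least-squares solve (with column scaling) is accepted
whenever the amplitude bounds are inactive, otherwise scipy's bounded
`lsq_linear` solves the constrained problem (tolerance 1e-10, 200-iteration
cap). This is deterministic and identical to what an iterative nonlinear
optimizer would converge to on this model. A fit that leaves both amplitudes
at zero has undefined saturation: StO₂ is recorded as missing (NaN, flag
`fit-failed`), never clamped.

Only the products path-length × concentration are identifiable, so
amplitudes are reported uncalibrated; StO₂, a ratio, is unaffected.

A delta-method propagation (`propagated_sto2_sd`) converts a per-wavelength
noise level into the implied StO₂ standard deviation through the
unconstrained solve; it is used as the flatness bound for control series.

## Extinction table

No coefficient values are bundled from a specific instrument calibration;
the packaged file `hb_extinction_synthetic.csv` is a synthetic
reconstruction: a monotone (PCHIP) interpolation through literature anchor
values of the standard oxy/deoxy haemoglobin compilations at 1 nm spacing
over 500–600 nm, reproducing the HbO₂ β/α bands near 542/577 nm, the single
broad Hb band near 555 nm and isosbestic crossings near 548/569/586 nm. The
two curves are far from collinear over the window (correlation ≈ 0.73), so
the unmixing is well posed. Because StO₂ depends only on the amplitude
ratio, approximate coefficients are adequate for uncalibrated saturation
work; calibrated concentration work requires substituting a tabulated
dataset (CSV dialect `wavelength_nm,eps_hbo2,eps_hb`, ≤ 2 nm spacing,
coverage of 500–600 nm enforced at load). Resampling onto instrument grids
is linear, which keeps interpolated values within their bracketing tabulated
values near the sharp bands.

## Quality flags

Two acquisition failure modes observed with hand-secured probes are flagged,
never silently corrected: `ambient-light` when the measured counts exceed
the reference anywhere by more than `ambient_excess_frac` (default 5%) —
light arrived that the lamp did not supply — and `probe-slip` when total
intensity jumps by more than `slip_jump_frac` (default 25%) relative to the
previous accepted spectrum. `fit-failed` is reserved for the fitting stage.
Flagged samples keep their fitted values in the series but are excluded from
median-smoothing windows.

## Time-series analyses

Row averages of four-site surveys are arithmetic means of the present site
values, reported to 3 decimals; phase averages pool the individual site
values (not row averages) on each side of the intervention time and report
integer percentages. All printed-style values round half away from zero on
the computed double. One cell of the packaged step-down kidney's survey is
worth noting: its published average (0.653) cannot be derived from its own
printed site values under any consistent rounding rule — the exact mean is
0.6535, which rounds to 0.654 — so the package reports 0.654 and documents
the discrepancy rather than special-casing it. Similarly, the pooled
pre-intervention mean of the rejection survey is 67.6% (≈ 68%), although the
experiment's narrative summary rounded it to "approximately 65%".

Median smoothing uses an odd window (default 5 samples ≈ 75 s at the 15 s
acquisition interval) of the nearest ok-flagged samples, shrinking at the
edges; timestamps are never altered.

The step-down analysis reports the adjacent flow pair with the maximal StO₂
decrease (ties broken toward the higher-flow pair — the earliest
physiological onset is the conservative report) and the plateau onset: the
first flow level after which every successive |ΔStO₂| stays within the
plateau tolerance (default 0.02) to the end of the profile.

Decompensation detection requires synchronization of the two independent
readouts: the median-smoothed StO₂ must fall by more than `sto2_drop_abs`
(default 0.02 absolute) within `span_s` (default 10 min) *and* the RBFi must
fall by more than `rbfi_drop_frac` (default 30%) of its running maximum over
an overlapping span. The defaults fire on an abrupt 0.95 → 0.92 fall with an
RBFi collapse and do not fire on baseline jitter at 1% detector noise (the
RBFi condition gates StO₂ noise excursions). The returned window runs from
one span before the first triggering sample to the last contiguous
triggering sample, so it contains the true onset for ramps shorter than the
span.

## Synthetic data generator

The generator emulates the acquisition conditions of normothermic
machine-perfusion experiments: a tungsten-halogen reference spectrum (Planck
curve at 3000 K with a gentle seeded ±2% quadratic throughput ripple, peak
5×10⁴ counts), reflectance spectra formed by subtracting a truth absorbance
from the lamp and applying 1% multiplicative Gaussian detector noise, and
scenario time courses sampled every 15 s:

* *rejection* — baseline StO₂ 0.68, a 0.12 fall starting 35 min after the
  intervention over a 5 min linear ramp, with synchronized RBFi collapse;
* *thrombosis* — pump flow stepped 100/75/50/25/0% at equal intervals, StO₂
  0.86 declining linearly with flow to 0.59 at the 25% perfusion threshold
  and plateauing below it, RBFi proportional to flow;
* *haemorrhage* — baseline 0.95 with a 0.03 fall late in the run;
* *control* — constant baseline 0.92.

The default summed haemoglobin amplitude (0.35 in count units) produces
≈50% reflectance dips at the strongest band, typical of a well-perfused
organ surface. Artifacts (`ambient-light` broadband offset, `probe-slip`
coupling loss) corrupt only the spectra, never the truth series. All
randomness derives from the scenario seed through a fixed `SeedSequence`
spawn order (lamp, detector noise, RBFi noise), making outputs
bit-reproducible.

Because the forward model inverts the default inference rule exactly, the
generator is an end-to-end oracle for pipeline correctness, not a
radiative-transfer simulation: passing tests demonstrate correct inference,
unmixing and time-series logic, not the physical accuracy of the
absolute-difference assumption on real tissue (scattering, specular sheen
and probe-pressure effects are outside its scope).

## Problem sizes and tolerances

Test and acceptance runs use scenario durations of 5–40 min (20–160 samples)
and 20–50 seeded replicates, sizes at which every stochastic check is stable
across seeds while the whole suite runs in seconds. Noiseless recovery is
asserted to 1e-3 (observed ~1e-15); noisy recovery to a median |ΔStO₂| of
0.02 over an 11-point saturation grid × two amplitude decades × 20 seeds
(observed ≈ 0.004); control-series flatness to 1.25× the delta-method bound
(the margin covers sampling error of an n≈160 standard-deviation estimate).

## Known limitations

* The absolute-difference absorbance is not a calibrated Beer–Lambert
  quantity; StO₂ values are comparative, not blood-gas-grade.
* Only two chromophores are modelled; water, methaemoglobin, cytochromes and
  scattering spectra are out of scope.
* The bundled extinction table is approximate (see above).
* Event detection is a thresholded change rule intended for retrospective
  analysis, not a validated clinical alarm.
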