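# Methods

This note documents the models implemented in probekit, the defaults and
why, the synthetic-data generators and their limits, and the numerical
choices that were genuinely open.

## Generalized polarization

GP = (I440 − I490)/(I440 + I490) is antisymmetric under channel swap and
bounded in [−1, 1] whenever both intensities are non-negative and not both
zero (both-zero raises a dedicated error rather than returning NaN).
`gp_from_spectrum` supports two read-out conventions behind one `bandwidth`
parameter: `bandwidth=0` linearly interpolates point intensities at exactly
440/490 nm (spectrofluorimeter convention), `bandwidth>0` trapezoid-
integrates each channel over center ± bandwidth/2 (the spectral-imaging
convention with 10 nm channels). Which convention a given spectrometer
measurement used is usually not recorded; both are first-class here and for
smooth two-band spectra they agree to within a few 0.01 GP units.

## Quantum yield, rates, brightness

Relative quantum yield uses the standard comparative formula
Φ = (S/S_r)(OD_r/OD)(n/n_r)²Φ_r with the optical-density guard left to the
experimenter (OD ≤ 0.05 avoids inner-filter effects; no correction beyond
that guard is attempted). The POPOP standard (Φ = 0.97 in cyclohexane,
τ = 1.35 ns in ethanol) is the conventional reference for this probe family.
k_r = Φ/τ and k_nr = (1−Φ)/τ satisfy k_r + k_nr = 1/τ identically.
Published tables round half-up; `round_half_up` mirrors that (with a 1e−9
epsilon so decimal ties stored as binary floats land on the intended side)
and is applied only at comparison/report time — internal values keep full
precision.

## TCSPC decay fitting

The decay model is amplitude-normalized, I(t) = Σ αᵢ e^(−t/τᵢ) with
Σαᵢ = 1; αᵢ are the quantities decay tables print as percentages. The mean
lifetime is intensity-weighted, ⟨τ⟩ = Σαᵢτᵢ²/Σαᵢτᵢ, which always lies
between the component lifetimes.

Fitting is weighted least squares over (log τᵢ, amplitude fraction, log
scale) with Neyman weights, variance = max(count, 1) — zero-count bins get
unit variance. With an IRF the model is the discrete linear convolution of
the normalized IRF with the decay and the fit window defaults to the full
histogram (the rising edge constrains the short component); without an IRF
the window is [peak bin, last bin with ≥ 1 count] and the fit is a tail
fit, which is also the delta-IRF mode used for synthetic data. A
measured-IRF reconvolution stands in for mono-exponential-reference
deconvolution (the historical variant differs between instrument vendors
and is underdetermined from published tables alone). Initial lifetimes come
from a deterministic two-segment log-linear split of the windowed decay
(tail segment → long τ, head segment → short τ, forced apart by 5× if the
segments give similar slopes); amplitudes start uniform. No random
restarts, so fits are reproducible bit-for-bit.

Only 1- and 2-component models are supported — the regime where TCSPC data
at 10⁶ counts actually constrains the parameters. `select_model` accepts
the 2-component model only when it improves reduced χ² by more than 10%
(relative), matching the practice of publishing a mono-exponential fit
when a second component is not warranted.

At the study conditions (α = 0.56/0.44, τ = 6.18/0.53 ns, 10⁶ counts,
2000 × 25 ps bins, Gaussian IRF with 0.5 ns FWHM centered at 2 ns) the
simulate-and-fit round trip recovers lifetimes with ~1% (long) and ~3–5%
(short) median relative error and amplitudes within 0.01.

Known limitation: published reduced-χ² values for this kind of data
sometimes exceed 4, suggesting the original instrument software weighted
residuals differently; that exact weighting is not reproduced and the χ²
values here are only internally comparable.

## Anisotropy and Perrin–Weber relaxation

r = (I_vv − G·I_vh)/(I_vv + 2G·I_vh), G = I_hv/I_hh. r is scale-invariant
in the four intensities. Values outside [−0.2, 0.4] are flagged
(`in_physical_range=False`) but not rejected: they are mathematically valid
and diagnose scatter or polarizer misalignment. The Perrin–Weber relation
is fixed as r₀/r = 1 + τ/θ, i.e. θ = τ·r/(r₀ − r), with r₀ = 0.4 — the
theoretical collinear-dipole one-photon limit — as a configurable default,
because per-probe fundamental anisotropies for this family are not firmly
established. θ is paired with the intensity-weighted mean lifetime ⟨τ⟩ of
the same sample; a component lifetime can be passed instead when that
pairing is preferred.

## Solvent polarity

Dioxane/water mixtures use the linear molar-fraction dielectric model
ε(x) = 2.2x + 80.1(1−x) (endpoints at 20 °C, configurable); mixing
non-ideality is deliberately ignored, matching how such ladders are
constructed in practice. Δf is the Lippert–Mataga form
(ε−1)/(2ε+1) − (n²−1)/(2n²+1). Refractive indices per solvent ship as a
built-in editable table (n_D20 from standard physical-chemistry tables)
since polarity tables usually list only ε.

## Thermal scans and insertion kinetics

Melting scans are fitted with a descending Boltzmann sigmoid
v(T) = lower + (upper − lower)/(1 + exp((T − Tm)/w)); the sigmoid argument
is clipped at ±500 to avoid overflow. Initialization: Tm at the steepest
finite-difference descent, plateaus from the first/last three points,
width = range/20 (≥ 0.5 °C). A transition is *detected* only when all of
(i) amplitude > 3× residual RMSE, (ii) Tm strictly inside the scanned
range, and (iii) fitted width ≥ half the temperature step. Condition (iii)
exists because a noisy flat scan can otherwise be "fitted" by a step
narrower than the grid spacing that clears the amplitude test; a transition
the grid cannot resolve is noise, not a melting event. Non-convergence
returns `detected=False` with diagnostics instead of raising, since flat
scans are an expected, valid input.

Insertion kinetics use the one-site saturation hyperbola through the
origin, I(t) = I_max·t/(t_half + t), so I(t_half) = I_max/2 by
construction — the natural reading of "one-site binding" for a trace that
starts at zero fluorescence. Fits whose t_half relative standard error
exceeds 50% are flagged `poorly_constrained` (typically traces sampled only
on the plateau).

## Imaging

GP maps apply the scalar GP formula pixelwise to the channels nearest
440/490 nm (matched within ±1 nm — 10 nm channels map to single-channel
reads, not band sums). Pixels below the intensity threshold, or with zero
total signal, are masked and carry NaN. No G-factor is applied in
two-photon GP maps and background subtraction defaults to 0 (a single
scalar per channel when used). The intensity threshold has no canonical
value; it is a required, recorded parameter. Orientation is fixed:
row-major, origin top-left, 0-based.

## Synthetic data — what it emulates, and what it does not

Generators are deterministic given a seed (NumPy `default_rng`). Count-like
data (decays, image pixels, polarized counts) get Poisson noise; analog
spectra get additive Gaussian noise; GP/anisotropy scan points get additive
Gaussian noise of configurable σ.

The emission model is two Gaussian bands (LE at 440 nm, ICT at 490 nm,
σ = 25 nm) on a 370–600 nm grid. The ICT weight is an affine calibration in
the dielectric constant with a protic bonus:
w = clip(0.14 + 0.004·ε + 0.55·protic, 0, 1), chosen once so that a
nonpolar solvent (ε ≈ 5) gives GP ≈ +0.5 and protic solvents with ε > 20
give GP < −0.2, bracketing the qualitative solvent pattern of these probes
(GP roughly linear in ε within a solvent class, protic solvents anomalously
red-shifted). These coefficients are package constants, not measurements.
The generator is shared by all four probes — it does not model
probe-specific head-group effects, time-dependent spectral relaxation,
vibronic structure, or scattering backgrounds. Consequently, passing tests
demonstrate that the *analysis* recovers what the generative model encodes;
they do not validate the generative model against real spectra.

Scene generation inverts the GP equation per region (I440 = I(1+GP)/2,
I490 = I(1−GP)/2) and fills the remaining 10-nm channels from a fixed
template spectrum; real cell images additionally have spatially varying
backgrounds, bleed-through and photobleaching, none of which are modeled.

## Problem sizes

Defaults used by the analysis drivers and the reproduction suite: TCSPC
histograms of 2000 × 25 ps bins at 10⁶ total counts, 20 seeds for recovery
studies; thermal scans on the 10–60 °C grid in 2 °C steps; insertion traces
sampled each minute for 60 min; image scenes of 64×64–128×128 pixels at
10⁴ expected counts per pixel. These sizes give stable statistics for every
estimator while keeping a full study run in well under a minute.
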