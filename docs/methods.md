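# Methods

This note documents the models implemented in `oisbold`, the defaults
chosen where the design was open, and what the synthetic study does and
does not establish.

## Synthetic study design

The generator emulates a whisker-stimulation imaging session in
anaesthetised rat: 60 s baseline, then 30 electrical-stimulation trials
(16 s each) at a 70 s inter-stimulus interval.  Optical data are
trial-locked windows (70 s at 8 Hz per wavelength, stimulus onset 10 s
into the window, ~80 μm pixels over a ~6 mm cranial window); fMRI is a
64×64 gradient-echo EPI series over a 30 mm field of view
(TR/TE = 1000/12 ms), so one optical pixel is ≈ 0.17 EPI voxels.

Ground truth is two disjoint disc regions:

* **positive (barrel) region** — ΔHbT peak +10 μM, ΔHbr peak −5 μM,
  transient peaking 4 s after onset then a plateau at half the peak; an
  early deoxy dip (+0.5 μM) and a post-stimulus lobe (1 μM extra Hbr
  washout) reproduce the transients seen in such data.  The post-
  stimulus BOLD "overshoot" is exposed as an optional lobe without any
  stance on its physiology.
* **negative (surround) region** — ΔHbT −5 μM, ΔHbr +2.5 μM, slower
  (peak 8 s, plateau 0.7), no dip.

Response shapes are gamma-variate lobes on a smoothed boxcar; regions
have a 1-pixel-σ Gaussian edge taper.  The amplitudes were chosen so the
forward-modelled BOLD lands near the few-percent positive and sub-percent
negative responses typical of 7 T rodent data.  The trial-locked field
is deterministic; measurement noise enters in the rendered attenuation
(log-domain Gaussian, matching where the inversion operates) and in the
EPI series (i.i.d. Gaussian, default 0.3% of baseline — the thermal
noise of a single subject is nearer 1%, but the study-style comparison
is against series averaged over ~10 subjects, and the generator emulates
that averaged series directly; an optional linear drift exists because
the analysis design matrix carries a ramp).

When the full pipeline renders the truth, the positive-region
concentration change is distributed over the superficial 0–1 mm of the
layered tissue and the negative-region change over 0–2 mm
(thickness-proportional).  This encodes the deeper origin of the
negative-BOLD haemodynamics while retaining the superficial vascular
component that makes it optically detectable at all; a change placed
*exclusively* below 1 mm is essentially invisible to visible-light
remission at these optical properties (two-way attenuation ~e⁻⁹) —
which is itself the depth-sensitivity problem the heterogeneous
analysis addresses.

What passing tests on this generator show: the inversion, forward
models and mapping machinery are mutually consistent and reproduce the
qualitative orderings (sign structure, tissue-model scaling, Y₀
sensitivity).  What they do not show: performance on real data with
vascular structure, physiological noise (cardiac/respiratory), EPI
distortion, or scattering changes — none of which are modelled.

## Photon transport

Weighted Monte Carlo in a layered semi-infinite slab: exponential step
sampling against μ<sub>t</sub> = μ<sub>a</sub> + μ<sub>s</sub>,
Henyey–Greenstein deflection, continuous absorption weighting
(w ← w·μ<sub>s</sub>/μ<sub>t</sub> per event), Russian roulette below
weight 10⁻⁴ with survival probability 0.1.  Matched refractive index at
the surface (the imaging well is fluid-filled), so photons crossing
z = 0 upward are remitted; their per-layer traversed paths, weighted by
exit weight, give the mean partial path lengths.  Roulette kills and
survival boosts are booked against the absorbed bucket so that
remitted + absorbed + transmitted equals launched weight to better than
10⁻⁹ in every run.

Defaults where the underlying studies print no value: μ<sub>s</sub> = 20 mm⁻¹
with g = 0.9 (reduced scattering 2 mm⁻¹, grey matter), background
(non-haem) absorption 0.02 mm⁻¹, five heterogeneous layers with
boundaries at 0.3/0.6/1/2 mm over a 10 mm slab, blood volume 6% above
1 mm and 4% below.  All configurable.

The lookup table stores per-layer mean partial paths on a
(band, μ<sub>a</sub>) grid — one simulation per node with the whole slab
at that μ<sub>a</sub> — and lookups interpolate linearly, indexing each
layer by its own local absorption.  The default μ<sub>a</sub> grid
(0.3–1.6 mm⁻¹, 14 nodes) covers the four filter bands across baseline
saturations from 30 to 90% plus the response excursions.

Haemoglobin extinction coefficients are an approximate anchor table
(450–650 nm) in the shape of the standard compiled absorption spectra,
monotone-cubic interpolated to 1 nm; the oxy α/β bands, the 555 nm
deoxy band and the isosbestic points near 500/545/570/584 nm are
reproduced.  Filter bands enter by centre wavelength by default
(band-averaged extinction is a flag); forward rendering and inversion
share the table, so closed-loop results do not depend on its absolute
accuracy.

## Spectroscopic inversion (PLSA)

Per pixel and frame the algorithm iterates: evaluate per-layer
μ<sub>a</sub> at the current concentration estimate; look up path
lengths; solve the four-band, two-chromophore linear system by least
squares; repeat until the concentration moves less than 10⁻³ μM
(maximum 50 iterations; non-converged pixels keep the final iterate and
are flagged).  A surface-observed concentration change is distributed
over depth by layer weights w<sub>l</sub>, by default proportional to
the baseline partial path lengths; the residual per pixel is kept for
QC.  Two chromophores only (HbO₂, Hbr); scattering changes are not
estimated.  ΔHbT = ΔHbO₂ + ΔHbr holds exactly by construction.

The 6% ↔ 104 μM anchor implies a whole-blood haemoglobin concentration
of ≈ 1733 μM, exposed as configuration.  The Hill dissociation curve
uses rat defaults p₅₀ = 38 mmHg, n = 2.6.

Linearity caveat: halving a noise-free stack halves the recovered
concentrations to within 1% at moderate amplitudes; at the generator's
peak excursions the second-order path-length rescaling reaches ~2%.

## MR signal attenuation

Randomly oriented infinite cylinders in a periodic cube (edge 20×
radius) are added until a Monte Carlo estimate of the occupied volume
reaches the target blood volume fraction.  Protons start extravascular,
random-walk with D = 10⁻⁹ m²/s in steps of dt = 0.2 ms (TE/60), are
elastically rejected at vessel walls (optional), and accrue phase from
the analytic inside/outside field of each cylinder in B₀ = 7 T with
susceptibility offset Δχ = 0.18 ppm (cgs) × Hct(0.4) × (1−Y).  The
signal is S(TE) = |⟨e^{iφ}⟩| and ΔR2\* = −ln(S/S₀)/TE relative to the
baseline state (V₀ = 6%, Y₀ = 50%) — the same baseline the optical
analysis uses.  BOLD fraction = exp(−ΔR2\*·TE) − 1; the intravascular
compartment (~7% of the signal at 7 T for capillaries) is deliberately
excluded.

Two variance-reduction choices matter numerically.  First, phases are
accumulated per cylinder, so nested subsets of one master geometry
realise every volume fraction with fully correlated statistics: the
V axis of the ΔR2\* table is smooth and the baseline anchors to exactly
zero, which is what makes the small (≈ 0.5%) volume excursions of the
haemodynamic response resolvable.  Second, because geometry-realisation
variance dominates over per-proton noise, several independent cylinder
configurations are averaged (`n_geometries`, default 8; the Y₀ sweep
uses 24) with the proton budget split among them.  Phase linearity in
Δχ makes the saturation axis free of charge.

The lookup table stores absolute R2\* on (V, Y, radius) grids (defaults
V ∈ [0.02, 0.12] with 11 nodes, Y ∈ [0.2, 0.9] with 15, r ∈ {3, 10, 20} μm);
predictions interpolate tri-linearly and subtract the baseline.  Pixel
states map as V = V₀·HbT/HbT₀ and Y = HbO₂/HbT; saturations leaving
[0, 1] are clipped and counted in QC.  The prediction envelope is the
elementwise min/mid/max over the 3/10/20 μm radii; gradient-echo ΔR2\*
plateaus above ~15 μm, so the upper edge is insensitive to the exact
large-vessel radius.

The Y₀ sweep rebuilds the analysis baseline at each saturation setting,
re-inverts the same stack, and pushes each recovery through the forward
model at the mid radius.  Two opposing trends shape the outcome: the
recovered |ΔHbr| grows with analysis Y₀ (lower baseline absorption at
the Hbr-sensitive bands lengthens the paths), while the dephasing
sensitivity to a given ΔHbr falls as (1−Y₀) shrinks, collapsing
entirely as saturation clips near Y₀ → 1.  At 7 T, TE 12 ms and 10 μm
radius their product peaks at the 50% setting used to generate the
data, and varies only mildly over 40–70%.

## GLM mapping

Ordinary least squares per voxel against [response, ramp, DC]; the
response column is a plain trial-locked boxcar by default (a convolved
kernel is an option — the literature is ambiguous on this point), the
ramp is normalised to [0,1].  z = β/SE(β) from the residual variance
and design covariance; zero-residual voxels receive a ±10⁶ sentinel and
a QC flag.  No autocorrelation correction is applied (trial-averaged
series need none here).  Cluster thresholding keeps connected
components (4-neighbour default) of at least six voxels — the reading
of "greater than five adjacent voxels" — above z = 4 or below z = −2;
`min_cluster` is configurable for ≥5 readings.  The two-pass
refinement replaces the boxcar by the detrended, unit-peak region mean
and refits.  Measured fMRI series are cubic-interpolated to 8 Hz for
comparison with optical series.

## Spatial comparison

The measured parameter map is smoothed with a σ = 489 μm Gaussian
(≈ 1.04 EPI pixels); the predicted map is cropped around the active
regions and matched by exhaustive zero-mean normalised cross-correlation
over scale 0.10–0.25 (step 0.01), rotation ±15° (step 1°) and all
integer translations.  Rotation is about the template centre with a
central crop to avoid fill-in; candidates smaller than 6 px are skipped
as carrying no discriminating structure.  No sub-pixel refinement by
default.  The nominal optics-to-EPI scale here is 80/468.75 ≈ 0.17;
the search grid brackets it, and the grid value the correlation
actually selects is reported, not asserted.  Projective registration
uses the plain (unnormalised) DLT solved by SVD, so four exact pairs
give zero residual and overdetermined fits agree with a normal-equations
solution; warping is inverse-mapped bilinear interpolation with a
sentinel fill.

## Problem sizes

Default library settings are 10⁵ photons per light-LUT node and 10⁴
protons per MR geometry set.  The test suite runs the same code at
2–5× smaller Monte Carlo sizes, and the end-to-end run in
`RunConfig.reduced()` uses a 48-pixel optical grid with 8×10³ photons
and 1.5×10³ protons; these sizes keep every statistic well inside its
test tolerance while the whole suite stays desk-scale.  The acceptance
script uses the full 10⁵ photons / 10⁴ protons for the Y₀ sweep.

## Known limitations

* The extinction table is an approximate transcription; absolute
  concentrations on real data would inherit its error.
* Layer path lengths are tabulated with the whole slab at one
  μ<sub>a</sub> (single-axis LUT), an approximation for strongly
  heterogeneous absorption profiles.
* Cylinder geometry uses minimum-image distances for periodic images,
  the standard approximation for infinite cylinders in a periodic box.
* Admitting spins into vessels (reflection off) shifts ΔR2\* by ~7% at
  V = 6%: wall treatment is a genuine modelling sensitivity.
* No physiological noise, EPI distortion, inflow, spin-echo sequences,
  vessel networks, or scattering-change estimation.
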