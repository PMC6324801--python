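# Methods

`linacmc` is a desk-scale Monte-Carlo model of two megavoltage photon beam
lines sharing one treatment head: a flattened 6 MV beam and a
flattening-filter-free (FFF) 7 MV beam whose primary electron energy is
raised so that the two depth-dose curves match ("pdd-matched" beams).  The
package simulates primary electrons striking a bremsstrahlung target,
transports the photons (and the contaminant electrons born in the filter
and the air column) through a parameterised head into a 40 x 40 x 40 cm^3
water phantom at SSD 100 cm, and analyses the resulting dose grids and
fluence spectra with the standard water-tank metrics.

## Beam-line model

**Primary electrons.** Gaussian energy spectrum (mean E0, spread sigma) and
an isotropic 2-D Gaussian focal spot (FWHM); direction +z.  The accepted
sources are E0 = 8.8 MeV (FFF) and 7.5 MeV (flat), sigma = 0.4 MeV,
FWHM = 1 mm, and these are shipped as the `fff7mv` / `flat6mv` presets.

**Target.** The target is parametric rather than microscopically
transported.  Each electron radiates a mean number of photons
n = f_cone * y(E0) * E0 / <k>, with y(E) = E/(E + E_c) a thick-target
radiative-yield form (E_c = 8.1 MeV for tungsten), <k> the mean of the
sampled spectrum, and f_cone = 0.25 the fraction entering the modelled
forward cone (an absolute-scale constant; it cancels in every reported
ratio).  Photon energies follow a thin-target Schiff-type spectrum
(1/k)(1 - k/E0 + 0.75 (k/E0)^2) on (0.05 MeV, E0], filtered by analog
attenuation through 0.9 mm of tungsten (the effective target
self-filtration, which imposes the soft-photon cutoff).  Emission angles
follow an *effective thick-target* intensity
(1 + (theta/theta0)^2)^(-q), theta0 = 0.8 m_e c^2/(E0 + m_e c^2),
with the shallow exponent q = 0.24 calibrated once so that the unflattened
fluence cone reproduces the characteristic off-axis ratios of a pdd-matched
7 MV FFF beam (about 1/1.15, 1/1.38 and 1/1.89 at 5, 10 and 20 cm off
axis); electron multiple scattering inside a real target broadens the raw
single-interaction lobe to exactly this kind of shallow cone.  The energy
spectrum is independent of angle (separable model) and the characteristic
angle is evaluated at the beam's mean energy, so the FFF off-axis spectrum
is radius-independent by construction; the trade-off is that the gradual
downstream hardening a correlated model would show at the staged scoring
planes is absent (the staged mean energy is flat instead of rising).

**Head geometry.** Target at z = 0, primary collimator cone (half-angle
0.28 rad, spanning z = 1-10 cm), flattening filter centred at z = 12 cm
(flat mode only), square jaws at z = 30 cm, phantom surface at z = 100 cm.
Field sizes are defined at the surface plane; the jaw half-aperture is
field/2 x 30/100.  Photons outside the collimator cone or the jaw aperture
are absorbed.  Only ratios of these dimensions matter materially; absolute
values are conventional.

**Flattening filter.** No vendor drawing is used: the filter is *designed*
by the package.  For each design radius the spectrum-weighted transmitted
energy fluence at the surface plane (hardening included, by attenuating the
full sampled spectrum) is matched by Brent root-finding to the fluence at
80% of the 40 cm reference field edge, where the filter has its floor
thickness (1 mm).  The result is a monotone profile of stainless-steel-like
alloy, about 22 mm thick on axis.  The absolute FFF/flat dose-rate ratio
depends directly on this on-axis thickness; with the cone calibration above
the simulated ratio comes out near 2.4 (measured machines of this type
report 2.8, and published values for other vendors span 2.2-3.0).

**Contaminant electrons.** Compton interactions in the filter and in the
air column launch electrons explicitly (no parametric electron source).
Filter electrons escape if their CSDA range beats the residual forward
thickness at the sampled interaction depth; air electrons are carried to
the phantom with straight-line CSDA loss plus a single Highland
multiple-scattering kick and the correlated lateral displacement
(sigma_r = theta0 L / sqrt 3).  The model has no target-exit or
collimator-face electron sources, so absolute surface-dose and
contamination fractions are smaller than on a real machine (roughly 25-33%
surface dose and 12-58% contamination share instead of 42-60% and 42-61%);
the orderings - flattened above FFF, growing with field size - are
preserved and are what the tests assert.

## Transport

Photons in water are transported analog: free paths from the total
attenuation coefficient, channel choice by partial coefficients,
Klein-Nishina Compton sampling (two-branch composition/rejection),
photoelectric absorption, and pair production with equal electron/positron
energy split; positrons annihilate at track end into two 511 keV photons.
Rayleigh scattering and triplet production are omitted.  Electrons use
condensed-history stepping: steps bounded by min(1 mm, voxel/2), CSDA
energy loss from the embedded range tables, Gaussian (Highland) angular
kicks, and local deposition of the residual energy below the production
threshold derived from the 1 mm range cut (0.35 MeV in water).
Bremsstrahlung from electrons *in water* is neglected (sub-percent below
10 MeV).  Energy bookkeeping (entering = deposited + exiting) closes to
about 1e-4 relative and is asserted in the tests.

**Data.** Attenuation channels and CSDA ranges are embedded per material
(water, air, tungsten, steel).  The Compton channel is exact Klein-Nishina
times the electron density; photoelectric and pair coefficients are
approximate transcriptions of the standard compilations (2-5% accuracy;
tungsten shell edges are smoothed).  This feeds directly into the
penetration index: the simulated D20/D10 carries a model tolerance of
about +-0.045 on top of Monte-Carlo noise.

**Randomness.** One master seed; per-batch (default 10) and per-chunk
child streams from `SeedSequence.spawn`.  Runs are bitwise reproducible
for a fixed configuration.  Per-voxel uncertainty is the batch standard
error and scales as 1/sqrt(N) (asserted over a 4x ladder).

**Source-side efficiency.** Two exact-weight devices keep desk-scale runs
inside minutes: (a) deterministic source splitting - each primary emits M
photons of weight n/M (water transport stays analog, all weights in water
are equal); (b) jaw pre-culling - emission angles are sampled only inside
the cone that can geometrically reach the jaw aperture (plus margin), with
the exact angular-CDF weight factor applied.  Photons outside that cone are
absorbed by the collimation with certainty; only their negligible air-
rescatter contribution is lost.  For spectrum-only scoring (no dose), the
emission angle may additionally be importance-sampled with a more
forward-peaked exponent and re-weighted exactly; within a 5 x 5 mm^2
scoring cell the weights are effectively constant, so the mean-energy
estimator keeps its nominal variance while the central-cell count rises
about threefold.

**Phase space and recycling.** Particles can be captured at z = 29 cm
(above the jaws) in a compact binary format (documented in
`linacmc/psf.py`), replayed as a virtual source, and recycled: each record
re-emitted with an independent azimuthal rotation about the CAX, valid only
above the jaws (asserted).  Recycling improves voxel statistics but cannot
beat the same number of fresh histories (latent variance), which the tests
check empirically.

## Scoring and analysis

Dose is accumulated in half-open voxels (5 mm standard, 1 mm for the
buildup/surface region) over a configurable sub-volume, with per-batch
sub-grids for uncertainty; an optional CAX cylindrical depth tally (radius
1-3 cm) provides low-noise depth-dose curves.  The CAX column is the voxel
column nearest the axis, ties towards +x/+y.  Surface dose is the
first-millimetre CAX layer relative to CAX dmax, on the 1 mm grid only
(the 5 mm grid cannot resolve the boundary and is rejected); for
desk-scale statistics the layer may be averaged over a 1 cm-radius disk.
Off-axis depth doses shift the column along *both* x and y (an OAD of
n cm means a geometric radius n sqrt 2).

Profile metrics follow the water-tank conventions: 20-80% penumbra by
monotone interpolation; dosimetric field size between the inflection
points (extremum of a Savitzky-Golay-smoothed derivative, window 5,
quadratic, with parabolic refinement); unflatness D_CAX over the mean dose
at 80% of the field size; side slopes between 1/3 and 2/3 of the
half-profile (reported in %/mm); peak position as the intersection of the
two side-slope line fits; symmetry as the maximum |D(x) - D(-x)| inside
the field.  FFF profiles are first renormalised at the shoulder point,
operationalised as the maximum-magnitude of the smoothed second derivative
between the peak region and each inflection point; the mean shoulder dose
is rescaled to 100%.  This operationalisation is a documented stand-in for
the published renormalisation recipe, which is named but not reproduced
here; it is idempotent and scale-invariant by construction.

Fluence spectra are plane-crossing counts weighted by statistical weight,
binned at 0.1 MeV over [0, 10] MeV, normalised per primary; mean energy is
the weight-averaged bin centre.  The off-axis scan uses 5 x 5 mm^2 cells
at (n, n) cm; off-axis cells may be averaged over their mirror images
(the head is mirror-symmetric above the jaws), which is exact and improves
counting statistics.

## Source commissioning (tuning)

Two stages over a (mean energy, spread, FWHM) grid.  Stage 1 fixes the
energy from the depth-dose match beyond dmax; stage 2 fixes spread and
spot FWHM from the lateral profiles at the dmax region and 10 cm.  The
*reported* objective is the validation statistic: the maximum absolute
point difference between normalised curves after light Savitzky-Golay
smoothing (window 11 for PDD, 9 for profiles), with the acceptance bar at
2 percent points.  Two estimator details matter at desk scale: profiles
are CAX-normalised to the mean over |x| <= 12.5 mm rather than one
interpolated point (a single-point denominator shifts the whole curve by
its own noise, and the max statistic collects exactly that common-mode
excursion), and the comparison profiles average 15 perpendicular rows and
5 depth slabs - the jaw edge is straight in the perpendicular direction,
so this costs no lateral resolution.  The *selection* statistics differ, because at desk
scale the max statistic is noise-dominated: stage 1 selects on the
absolute mean signed difference over the descending PDD (monotone in beam
penetration, far lower variance), and stage 2 selects on the fitted
edge-blur mismatch (an error-function regression over each penumbra; the
spot size acts on the profile almost exclusively through this blur).
Stage 2 also uses heavier source splitting (32 photons per primary):
edge-blur information per primary is the bottleneck for the spot search.
All candidates within a stage share one random stream (common random
numbers).  On simulator-generated references the procedure recovers the
true source within one grid step of a reduced 5 x 2 x 2 grid at 2e5
histories per point, and exactly at the tested seeds.

## Synthetic reference data

The generator emulates scanned water-tank data on a 1 mm grid: depth dose
= buildup (1 - e^{-bz}) x exponential falloff x inverse square, with b
solved so the maximum sits at the requested dmax; profiles = error-function
penumbrae under a flat top (optional ripple) or a linear/quadratic conical
peak, with an optional linear asymmetry factor and additive Gaussian noise
(default 0.3 percent points).  Defaults mirror the emulated machine: dmax
19 mm (FFF) / 16 mm (flat), effective falloff chosen to reproduce D20/D10
of 0.587/0.578 at 10 x 10, cone coefficient giving unflatness about 1.15
at 10 x 10.  Every metric has a closed-form value on these curves.  What
the generator does *not* emulate: chamber volume averaging, scan-arm
positional error, beam-current drift; passing tests therefore demonstrate
correctness of the analysis pipeline and self-consistency of the
simulator, not agreement with any particular machine's measurements.

## Problem sizes and numerical choices

Desk-scale runs use 1-40 x 10^6 primary electrons (with source splitting
8-10), chosen so the relevant estimators resolve their targets: about 1%
per-point depth-dose noise for penetration indices, about 0.2% standard
error per off-axis plane for the spectral-constancy check, and max-
difference validation noise comfortably under the 2% bar at 1.2 x 10^7
histories per run.  The tests state every size explicitly.  Degenerate
inputs are defined: zero range cut falls back to the lowest tabulated
energy; a zero-dose run warns instead of failing; empty spectra and
uncrossed metric levels raise typed errors.

## Known limitations

- dmax comes out 2-4 mm deeper than the nominal 19/16 mm of the emulated
  machine (simplified buildup physics: no in-water bremsstrahlung, local
  pair-production kinematics, forward-biased photoelectron directions);
  the buildup-band tests assert a physical window rather than +-1 voxel.
- Absolute surface dose and contamination fractions are low (missing
  target-exit/collimator electron sources); orderings are faithful.
- The separable target spectrum suppresses the staged downstream hardening
  and any off-axis softening of the *unflattened* beam; the flattened
  beam's off-axis softening (filter hardening strongest on axis) is
  reproduced.
- Tungsten data below 100 keV are smoothed across shell edges; sub-0.1 MeV
  spectra in high-Z materials are indicative only.
- The slope metric is reported in %/mm; per-centimetre conventions differ
  by a factor 10.
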