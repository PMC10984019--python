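# Methods

`lungmech` reconstructs, on synthetic phantoms, a complete image-based
lung-biomechanics pipeline: magnetic resonance elastography (MRE) inversion
of harmonic shear-wave images into shear-stiffness maps, multi-echo
relaxometry for lung density, lofting of axial outlines into a meshed 3D
lung-section model, hyperelastic finite-element simulation of tidal
inflation with the measured heterogeneous stiffness, and strain /
strain-gradient statistics in healthy-like and CF-like (consolidated)
lungs.  This note records the models, the parameter choices and their
rationale, the numerical decisions, and what the synthetic phantoms do and
do not establish.

## Shear-wave phantoms and the forward model

Stiffness fields are log-normal Gaussian random fields: log G carries a
zero-mean Gaussian perturbation with squared-exponential spatial
correlation, scaled so the coefficient of variation of G matches the
requested value (default 0.3) and centred so the median equals the base
modulus (default 3 kPa, the reference shear modulus of the inflation
model).  The default correlation length is 3 cm: a 50 Hz shear wave in
lung-like tissue has a wavelength of ~5 cm, and stiffness texture far below
that scale is physically invisible to MRE, so an "MRE-visible" heterogeneity
phantom must be smooth at the cm scale.  A CF-like phantom adds a spherical
consolidation: *homogeneous* at `inclusion_factor` x base modulus (dense
mucus/scar replaces the heterogeneous air-tissue matrix), with the edge
smoothed over one correlation length (capped at half the radius so small
inclusions keep a full-contrast core).  The ROI label marks the fully
consolidated core — tissue in the smoothed rim is only partially
consolidated.

Wave images are synthesized by solving the heterogeneous scalar wave
equation div(G grad u) + rho omega^2 u = 0 per slice (flux-form 5-point
finite differences), with the incident plane wave of each requested compass
direction imposed as Dirichlet data on the image boundary.  An eikonal
ray-phase method is retained as a cheap option, but the Helmholtz solve is
the default: ray phase accumulates transverse decorrelation over long paths
(no diffraction healing) and corrupts inversion tests on heterogeneous
fields.  The incident wavenumber uses the dispersion relation of the
*discrete* operator, so on a uniform field the synthesized wave is an exact
fixed point of the forward/inverse pair, and the physical wavelength
sqrt(G/rho)/f is matched to O((k dx)^2).  Boundary-condition mismatch in
heterogeneous media produces weak reflected components — which is realistic,
and is what the directional filter is for.

Noise is additive complex Gaussian at a target SNR (default 20 dB).
Optionally the noise is scaled per pixel by the inverse of a relative
magnitude-signal map: displacement in MRE is phase-derived, so its noise is
inversely proportional to the magnitude signal, and dense consolidated
tissue (~2x brighter than aerated lung) yields proportionally quieter wave
images.

Multi-TE magnitude images follow S = I0 exp(-TE/T2*) with a constant-signal
doped-water phantom block; Rician or Gaussian noise is optional.  Lung
outlines are star-shaped polygons with low-order Fourier perturbations
drifting smoothly in z and a mild apical/basal taper; the inner outline
(the cropped extent of the stiffness maps) is a radial inward offset.

## Inversion

The first temporal harmonic is extracted from >= 3 equally spaced phase
offsets by exact DFT.  The directional filter multiplies the 2D spectrum by
a radial Butterworth bandpass (order 4) in waves-per-FOV and by smooth
angular windows (truncated cos^16, normalised to partition unity over the
forward half-planes) centred on 8 directions.  The module default band is
[2, 40] waves/FOV; the *pipeline* default is wavelength-adapted, [2, 16] at
the 40 cm FOV, mirroring the acquisition practice of choosing cutoffs from
the measured pixels-per-wavelength.  The adaptation matters quantitatively:
the direct inversion divides by |laplacian u|^2, which amplifies in-band
noise by (kappa_hi / kappa_signal)^2 — about two orders of magnitude at 40
waves/FOV and 20 dB SNR, enough to destroy the stiffness map, versus a
stable, ~0.9-correlated recovery at the adapted cutoff.

Direct inversion computes, per direction, G_d = -rho omega^2
Re(u conj(lap u)) / |lap u|^2 with a 5-point Laplacian, masks
pixel-directions below relative amplitude and Laplacian floors, and
combines directions by amplitude^2 weighting; pixels with no surviving
direction (or a non-positive estimate) are invalid, not zero.
Postprocessing applies a 3x3 ROI-restricted nan-median filter (edge pixels
use the neighbours available) and removes pixels above the 95th percentile
(linear-interpolation quantiles, pooled per lung).  Density correction
rescales by LD / rho_assumed.  Summaries (median, IQR) exclude a 2-pixel
rim of the ROI.

## Lung density

Per-pixel log-linear least squares on S = I0 exp(-TE/T2*) (exact two-point
solution at 2 echoes; pixels without decay keep I0 and are flagged), then
LD = I0 / (CR x I_ph) in g/cm^3, with I_ph the mean doped-water phantom
signal and CR = 1.873 the short-TR recovery correction.  CR divides
(rather than multiplies) because it scales the under-recovered phantom
reference upward: the phantom's long decay constant keeps it from reaching
steady state at TR = 10 ms.  Default lung density is 0.5 g/cm^3 (residual
volume).

## Geometry and meshing

Outlines are arc-length resampled to a common vertex count with the seam
aligned by centroid-to-first-vertex angle, and lofted with natural cubic
splines in z; self-intersecting inputs or interpolated cross-sections are
rejected with a diagnostic.  The mesh sweeps a triangulated cross-section
template (rings from the centroid to the inner boundary to the outer
boundary) along z; prisms are split into tetrahedra with the minimum-vertex
diagonal rule, which guarantees a conforming partition, and midside nodes
make straight-sided (affine) 10-node quadratic tetrahedra.  Discretization
parameters are chosen by a scan to land within ~30% of the requested
element count.  Boundary faces are labelled apical/basal on the extreme
z-planes; lateral faces whose outward normal lies within 60 degrees of the
medial direction are mediastinal (the anatomical mediastinal contact is the
medial face, not half the surface), the rest are outer-lateral and receive
the pressure load.

Stiffness maps are interpolated onto inner-solid nodes (bilinear in-plane,
linear in z, clamped beyond the extreme slices; invalid pixels are filled
nearest-valid and such nodes counted); outer-shell nodes take the mean
interpolated inner value.  Inner nodal values are convex combinations of
valid pixels, so field bounds are preserved.

## Hyperelastic inflation

Total-Lagrangian Mooney-Rivlin on the isochoric invariants,
W = c1 (I1b - 3) + c2 (I2b - 3) + kappa (J - 1)^2 with c1 = c2 = G/4 and
kappa = 2G(1+nu)/(3(1-2nu)); the second Piola-Kirchhoff stress is derived
consistently from this W, and G (hence kappa) may be a nodal field.
Baseline nu = 0.2.  Boundary conditions: rolling (u_z = 0) on the apical
and basal cut planes; a linear spring foundation on the mediastinal patch
(kn = Es(1-nu_t)/(ds(1+nu_t)(1-2nu_t)), ks = Es/(2 ds (1+nu_t)); defaults
Es = 800 kPa, nu_t = 0.4, ds = 10 cm, all configurable), applied in the
reference configuration against total displacement; and the vacuum pressure
as a follower load on the outer-lateral surface (deformed-normal traction,
matching pleural pressure; the mediastinal surface is not loaded).

Quadrature: 4-point (degree 2) for stresses, 5-point (degree 3) for the
deformed-volume integral (det F is cubic per affine element), exact
closed-form barycentric integration for the consistent mass.  Newton uses
tangents from complex-step differentiation of the element residuals —
exact to machine precision, so convergence is quadratic — with relative
residual tolerance 1e-8, backtracking line search, and automatic load
subdivision (non-finite residuals, i.e. inverted elements, raise cleanly
into the subdivision path).  Sparse LU uses minimum-degree ordering on
K + K^T (the follower load makes K unsymmetric but structurally symmetric);
this is ~7x faster than the default ordering at ~20k dof.  The default
mode is quasi-static (breathing at 0.2 Hz is quasi-static to high
accuracy); a Newmark average-acceleration dynamic mode exists and agrees
with the quasi-static peak to well under 2% volume ratio.

Pressure calibration finds p with |VR(p) - target| <= 1e-3 by secant
iteration on the monotone volume-ratio response, warm-starting each solve;
targets are 1.167 (healthy: 0.5 L tidal volume over 3 L FRC) and 1.083
(CF: 50% reduced tidal volume).  On the default phantom the calibrated
healthy pressure lands in the several-hundred-Pa range, the same scale as
the subject-calibrated pressures in vivo.

## Strain analysis

The first principal strain eps_p1 is the largest eigenvalue of the
Gauss-averaged Green-Lagrange tensor per element.  The strain gradient
|grad eps_p1| is evaluated from a *recovered* continuous nodal field
(volume-weighted element-to-node averaging) using quadratic shape-function
derivatives at element centroids — raw inter-element jumps would otherwise
dominate the statistic; linear fields are reproduced exactly.  Statistics
are volume-weighted over inner-domain elements at end inspiration; the
outer buffer shell is excluded.  The quantile convention everywhere is
linear interpolation between order statistics.

## Cohort driver and statistics

The experiment driver mirrors the imaged cohort: 6 healthy lung-subjects
(right lungs) and 6 CF lung-subjects (both lungs of 3 people, 3 lungs
consolidated), each lung an independent "subject".  Per lung: phantom
generation, wave synthesis, inversion, density correction, lofting/meshing,
pressure-calibrated inflation (an additional uniform-stiffness variant for
healthy lungs, at the subject's median measured stiffness), and strain
statistics per region.  Group analyses: paired two-tailed t-tests
(uniform vs MRE-based, healthy) and one-way ANOVA (healthy /
CF-non-consolidated / CF-consolidated), unadjusted p-values, with
zero-variance paired differences resolved analytically.  The
Kolmogorov-Smirnov screen fits normal and log-normal laws and reports
tenability at 0.05.

## Problem sizes

Desk-scale defaults keep the full suite and the acceptance script within
minutes: cohort meshes ~700 quadratic tetrahedra (~5k dof), single-phantom
verification runs 1.5k–5k elements, imaging grids 128x128 over a 40 cm
FOV with 5 slices.  The mesh-convergence property is exercised at a
scaled-down ladder (0.7k/2k/4.5k elements: successive median-strain changes
contract, 5.1% then 0.7%); production-scale meshes (tens of thousands of
elements) follow the same code path.

## What the phantoms do and do not show

The phantoms share the acquisition's statistical structure (heterogeneity
law, SNR, phase-offset sampling, slice geometry, echo times) but are
simplifications: single-component scalar waves rather than full
vector-field elastodynamics in a torso, no physiologic motion or breathing
drift, hand-specified rather than anatomical outlines, and a spherical
consolidation.  Passing tests therefore validate the *method
implementations* and their interactions, not claims about human lungs.

Two findings from the phantom study deserve emphasis:

* **Consolidation contrast is resolution-limited at 50 Hz.**  Inside a 3x
  stiff inclusion the wavelength is ~12 cm; a 5–6 cm consolidation is
  sub-wavelength, and the measured stiffness plateau is strongly smoothed,
  so the measured-map route preserves the *direction* of the stiffness
  contrast but attenuates it.  The consolidation strain-gradient analysis
  therefore applies the constructed stiffness maps to the mesh directly;
  the fully-measured route is reported by the cohort driver but not
  asserted.

* **The sensitivity claims are only partly reproducible here.**  With p
  recalibrated to the fixed volume-ratio target, median strain is
  insensitive to nu (<= 6% over 0.2–0.45; 0.5 itself is excluded because
  the bulk modulus diverges).  The median strain *gradient*, however,
  rises with nu (~19% at 1.8k elements, decreasing under refinement —
  partly numerical, partly the material law's coupling kappa ∝ G, which couples
  near-incompressibility into the heterogeneous strain field while the
  calibrated p grows ~6x).  Varying the mediastinal spring stiffness Es
  from 800 Pa to 8e10 Pa spans an effectively-free to effectively-rigid
  medial boundary at these load levels and changes the section phantom's
  deformation mode (median strain ~ -11%, gradient ~ -31%).  These
  sensitivities appear to be genuine properties of this phantom geometry;
  the corresponding acceptance check is left failing rather than weakened,
  and the discrepancy with the reported insensitivity is attributed to the
  unknown patient-specific section geometry and the ~30k-element meshes
  used there.

## Known limitations

2D per-slice inversion only (no 3D or viscoelastic inversion); no
multifrequency MRE; no image segmentation (outlines are inputs); no
contact, gravity, airway coupling or poro-viscoelasticity; both lungs of a
CF subject are treated as independent subjects (replicating the study
design, not endorsing it); the CLI is a thin wrapper and the library API is
the primary interface.
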