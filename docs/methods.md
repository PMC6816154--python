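# Methods

This note documents the models, algorithms and parameter choices behind
`aortacs`, in the order data flows through the package, and closes with
what the synthetic experiments can and cannot say about real scans.

## Digital phantom

The phantom models the infrarenal aorta as a straight, axially aligned
tube — the abdominal aorta is braced against the spine, and tortuosity is
out of scope. Each axial cross-section consists of concentric regions:
flowing lumen (signal-suppressed, as in black-blood imaging), an
intraluminal thrombus (ILT) annulus, and a vessel wall of fixed thickness
(default 2 mm). The lumen radius and ILT thickness are continuous radial
profiles of the axial coordinate; the default is a Gaussian fusiform bulge
(`base + amplitude · exp(−z²/2σ²)`, σ = 8 mm). Because the geometry is
analytic, the truth record — maximal outer diameter, lumen and ILT+wall
areas at the widest slice, mean-ILT-to-muscle intensity ratio — is
evaluated from the profiles at slice centres, never by re-measuring the
raster. On an even-length grid the slice centres straddle the continuous
apex, so the recorded maximum can sit up to half a voxel below it.

A psoas-muscle cylinder (the clinical intensity reference) and a spine
cylinder sit at 42 mm and 44 mm from the axis; these offsets clear the
largest supported aneurysm (5.5 cm outer diameter → 27.5 mm radius), so
the outer wall always faces background tissue. An elliptical "body"
cross-section (92% of the field of view per axis) separates
signal-bearing tissue from near-zero air at the corners, which is what
makes a sensitivity-map support meaningful.

Default tissue intensities (arbitrary units): lumen 0.3, iso-intense ILT
1.0, bright ILT 1.5, wall 0.9, muscle 1.0, spine 0.7, background 0.2, air
0.02. These are chosen so that the 1.2 × muscle brightness threshold
cleanly separates the two ILT signal classes and the ILT-to-lumen
contrast ratio lands in the 2.5–5 range typical of T1-weighted black-blood
images. ILT types are realised constructively: type 1 assigns all ILT
voxels the bright intensity, type 2 assigns a contiguous angular sector
(default half) bright and the rest iso, type 3 is all iso, type 4 has zero
ILT thickness. Intensities use partial-volume anti-aliasing (2×
supersampled in-plane rasterisation, averaged); labels are voxel-centre
classes. ILT has no intra-class texture — the four types differ by
sector structure only, which is noted as a simplification.

## Coil model and acquisition

Coil sensitivities are smooth complex Gaussian bumps centred on a ring
outside the body (mimicking surface-coil elements) with slowly varying
linear phase, root-sum-of-squares-normalised to 1. Variation along the
slab axis is kept small: over a ~3 cm slab a body-coil element's
sensitivity changes little, and the estimator can only recover what the
low-resolution calibration data resolve. Only smoothness and
normalisation matter to the reconstruction contract; the default is 4
coils (configurable) to keep simulations cheap.

The acquisition applies the orthonormal centred 3D DFT to each
coil-weighted image, restricts to the sampled phase-encode locations (the
readout axis is always fully sampled, matching a 3D fast-spin-echo
geometry), and adds i.i.d. complex Gaussian noise with E|ε|² = σ²
(default σ = 0.02 against a peak tissue intensity of 1.5, i.e. an SNR a
well-set-up 3 T acquisition reaches). Unsampled entries are stored as
exactly zero.

## Undersampling mask

The mask lives on the ny × nz phase-encode grid with elliptical coverage.
Points are drawn by dart throwing over a seeded random permutation of the
in-ellipse grid locations; a candidate is accepted if no accepted point
lies within its local minimum distance r(ρ) = r₀(1 + αρ), where ρ ∈ [0,1]
is the normalised elliptical radius and α (default 2.0) sets how fast
density falls toward the periphery. The central calibration ellipse
(default 4% of the in-ellipse area) is always fully sampled. r₀ is
calibrated by bisection (≤ 30 steps) until the in-ellipse sampling
fraction is within 0.005 of 1/R; the "20% of k-space" at R = 5 is
interpreted relative to the elliptical region, since elliptical scanning
is part of the protocol in both arms (`sampling_fraction` exposes the
quantity directly). With no density decay the achievable fractions are
quantised by the integer grid, so uniform-density masks may need a looser
tolerance.

Diagnostics report the per-annulus minimum pairwise distance (which must
dominate r(ρ) at the annulus inner edge — the Poisson-disc guarantee) and
the point-spread-function peak-to-max-sidelobe ratio. Two baselines are
provided for PSF comparisons: plain uniform random, the fair comparator
for uniform-density masks, and a density-matched random mask
(`matched_density_random_mask`), the fair comparator for variable-density
masks — against a flat random baseline, the density modulation itself
adds coherent sidelobes that can mask the benefit of the minimum-distance
property.

## Reconstruction

The solver minimises ½ Σₙ‖yₙ − F_u(CSMₙ ⊙ x)‖² + λ‖Wx‖₁ with accelerated
proximal gradient (FISTA). Design choices:

* **Wavelet W**: orthogonal Daubechies-4, 3 levels, periodization
  boundary; orthonormality makes the proximal step exact complex
  soft-thresholding and gives Parseval bookkeeping for the cost trace.
  Levels are clamped to what the grid supports.
* **Step size**: 1/L with L from power iteration on the normal operator
  (8 iterations; L ≤ 1 for RSS-normalised maps, the estimate protects
  against non-normalised inputs).
* **Monotone safeguard** (default on): a candidate iterate that increases
  the cost is rejected and momentum restarts, so the recorded cost trace
  is non-increasing by construction. With the safeguard off, three
  consecutive cost increases abort with the trace attached.
* **Normalisation**: data are scaled so the zero-filled coil-combined
  image has unit peak magnitude; λ = 0.002 (the protocol's operating
  point) applies on that scale and the output is scaled back. Whether the
  scanner's λ applies to raw or normalised data is not observable from
  outside; this convention is declared, not inferred.
* **Initialisation**: the zero-filled adjoint image; the image stays
  complex throughout and magnitude is taken only at measurement time.
* The cost trace stores total, fidelity and sparsity terms at every
  iterate including the initialisation (length = iterations + 1).

Sensitivity maps are estimated from the calibration ellipse: Hann
apodisation over the calibration extent, inverse transform, division by
the root-sum-of-squares image, stabilised by an RSS²-weighted Gaussian
smoothing (σ = 2 voxels) of the ratio maps, then RSS-normalised. The
support is where the low-resolution RSS exceeds 10% of its maximum —
high enough to exclude the air fringe, where the ratio is one-sided
extrapolation and its error peaks. Off support the smoothed extrapolation
is kept (RSS = 1 everywhere) so low-signal periphery still reconstructs;
the support is used by the reference reconstruction for its fallback and
by validity checks. At the calibration resolution (a ~10-voxel kernel)
the estimator recovers the true maps to a mean absolute error < 0.02 on
support in the noiseless limit.

The reference arm is combined directly: Σₙ conj(CSMₙ)·IFT(yₙ) / Σₙ|CSMₙ|²
on support, root-sum-of-squares off support. Both study arms estimate
their maps from their own calibration data — neither sees the simulator's
true maps, as on a scanner. Even at R = 1 the two arms are not bit
identical: elliptical scanning leaves the k-space corners unsampled, and
the iterative solver treats them as unknowns while the direct combination
zero-fills them.

Image fidelity is quantified by NRMSE: RMS error over the volume divided
by the reference intensity range.

## Morphometry

Contours are found per axial slice by casting 64 radial rays from the
centreline at quarter-voxel steps. A scale-invariant Otsu threshold
(computed on the peak-normalised slice, so all geometry is equivariant
under intensity scaling) separates the dark lumen/background from the
bright ILT+wall annulus; a slice is considered measurable only if the two
Otsu classes differ by at least half the threshold — flat or noise-only
slices fail this bimodality check and are flagged invalid. Along each ray
the inner boundary is the first up-crossing and the outer boundary the
next down-crossing, each refined to the extremal-gradient position within
±1 voxel. Failed rays (no crossings) are angularly interpolated from
their neighbours; a slice with more than 25% failed rays is invalid. The
radii are smoothed by a 5-ray circular moving average — without it,
per-ray noise jitter biases the maximal-caliper statistic upward by up to
two voxels. Areas come from the shoelace formula on the 64-point
polygons; the per-slice diameter is the maximal Feret width of the outer
polygon, and the volume diameter its maximum over valid slices.

ILT signal statistics are taken at the maximal-diameter slice over the
annulus between the inner contour and the outer contour shrunk by the
wall thickness (default margin 2 mm — wall and thrombus cannot be
separated by signal alone) with a half-voxel guard band at both contours
against partial-volume contamination. The muscle ROI is the eroded
labelled muscle region for phantoms, or a user-supplied mask. ILT typing
applies the 1.2 × muscle voxel-wise brightness threshold: with f the
bright fraction, type 1 if f ≥ 0.7, type 2 if 0.3 ≤ f < 0.7, type 3
otherwise, and type 4 when the ILT area is below 0.5 cm². The 0.7/0.3
cutoffs and the area floor quantify the qualitative labels "dominantly
bright" and "mixture" and are exposed in `MetricConfig`. The ILT-to-lumen
"contrast ratio" is implemented as the ratio of mean intensities (not a
contrast-to-noise expression — the convention is flagged here because
both readings exist in the literature).

Boundary sharpness follows the inverse-transition-distance convention
consistent with mm⁻¹ units: profiles through the section centroid along
the two in-plane axes, interpolated at quarter-voxel spacing; edge
amplitude from flanking plateau medians; sharpness = 1/(distance between
the 20% and 80% amplitude crossings of the widest monotone segment),
averaged over directions and sides per interface. Closed forms used as
oracles: a linear ramp of width w has 20–80% distance 0.6w; a
Gaussian-blurred step of width σ has 2·Φ⁻¹(0.8)·σ = 1.683σ.

Growth rate is the endpoint formula: (last − first diameter, in mm)
divided by the follow-up duration in 365.25-day years; intermediate time
points are ignored by construction.

## Agreement statistics

Bland-Altman (bias, SD of differences with n−1 denominator, LOA = bias ±
1.96·SD), within-subject CV (root mean per-subject variance over the
grand mean, ×100; the SD-of-differences convention is available as an
option since the headline convention is ambiguous in common usage), ICC
(two-way random effects from the subjects × raters mean-squares
decomposition; absolute agreement ICC(2,1) by default as appropriate for
method comparison, consistency ICC(3,1) selectable), and Cohen's κ from
the marginal-product chance correction. All four are bespoke direct
implementations; `pingouin` and `scikit-learn` serve as independent
cross-checks in the tests only. Degenerate inputs are defined explicitly:
zero total variance with identical columns gives ICC = 1; perfect
agreement with a degenerate marginal gives κ = 1.

## Study pipeline

`run_experiment` simulates the paired-protocol design: each phantom in
the cohort (diameters uniform over 3–5.5 cm, ILT types cycled so all four
occur, default 20 phantoms) is acquired twice — fully sampled reference
and Poisson-disc R = 5 with CS reconstruction — measured identically, and
summarised by per-metric agreement reports plus κ for ILT types. A failed
phantom is flagged and excluded; more than 50% failures aborts the run.
`longitudinal_series` grows each subject's diameter linearly (default 3.3
mm/year), scans every time point on both arms with the same per-subject
coil setup and sampling pattern (repeat scans of one patient reuse the
same hardware, and this makes systematic per-setup bias cancel in the
growth rate), and compares recovered rates. All randomness derives from
one master seed through `SeedSequence` spawning; a rerun with the same
seed is bit-identical.

Problem sizes: the default grid is 96 × 96 × 24 voxels at 1.3 mm — large
enough to hold a 5.5 cm aneurysm plus the muscle and spine references
with margin, small enough that the full 20-phantom two-arm study runs in
about a minute on one core. The protocol-scale 246 × 52 phase-encode grid
is used where the claim being checked is about the mask itself.

## What the synthetic experiments show — and what they don't

Passing tests establish that the chain is internally correct: the mask
has the stated density and fraction, the solver minimises the stated
cost, measurements recover analytic truth within a voxel, and the
accelerated arm agrees with the reference arm at the study's operating
point on phantoms. They do not establish clinical performance: the
phantom has homogeneous tissue classes, no motion, no flow artefacts, no
pulse-sequence physics (contrast is prescribed), a circular cross-section
(so the caliper diameter is insensitive to plane selection), and
reader-free automated contouring in place of human readers. Two known
consequences: the CS arm here is always slightly *smoother* than the
reference (in vivo the accelerated scan can be sharper because the
shorter scan accumulates less motion), and agreement ICCs on phantoms are
optimistic because between-phantom geometric variance is large and
controlled. The growth-rate tolerance of the longitudinal simulation is
one voxel per year (1.3 mm/year at 1.3 mm resolution): differencing two
independent sub-voxel measurement errors cannot be guaranteed tighter
than the raster itself.

## Numerical conventions

Centred orthonormal DFTs throughout (`fftshift`-sandwiched, norm
"ortho"); complex noise SD is E|ε|² = σ² (σ/√2 per real component);
lengths in mm internally, reported in cm (areas cm², sharpness mm⁻¹);
ties in the per-slice diameter maximum resolve to the lower slice index;
the phase of reconstructed images is retained until measurement.
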