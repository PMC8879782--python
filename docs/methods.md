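# Methods

`fluorovol` generates fluoroscopic (time-resolved) 3D images of a
breathing thorax from single cone-beam projections, using a
patient-specific principal-component motion model derived from
respiratory-correlated cone-beam CT (4D-CBCT) acquired in treatment
position. This note documents the model, the numerical choices, the
synthetic phantom the package is validated on, and what those
validations do and do not demonstrate.

## The model

**Motion model.** Every 4D-CBCT phase is registered to a reference phase
(peak-exhale) with Demons deformable registration, yielding one
displacement vector field (DVF) per phase on the reference grid.
Principal component analysis of the flattened DVF set gives

    D(u) = D̄ + Σ_{i=1..N} u_i v_i

with mean field D̄, orthonormal spatial eigenmodes v_i sorted by
descending eigenvalue, and scalar coefficients u_i. N = 3 modes are
retained by default; on both the phantom and in the literature the
eigenvalue spectrum collapses after the first few modes because quasi-
periodic breathing is intrinsically low-dimensional.

**Per-projection estimation.** For each incoming projection x the
coefficients are found by minimizing

    J(u) = || M ⊙ ( P f(D(u), f0) − λ x ) ||²

where f0 is the reference volume, f(D, f0) the volume warped by D,
P the cone-beam forward projector, λ a scalar intensity scale, and M a
binary detector region of interest (ROI) surrounding the projected
tumor and diaphragm apex. The squared norm is used (differentiable
everywhere). The warped volume at coefficients u* is the fluoroscopic
frame; the tumor position is read off the model field at the reference
tumor centroid.

## Conventions

* World axes: x = left–right, y = anterior–posterior, z = superior–
  inferior (+z superior); all lengths in mm. Volumes are indexed
  `[ix, iy, iz]`, world position = origin + index · spacing, isocenter
  at the volume center.
* Gantry angle 0° puts the source on the anterior side; rotation is
  counter-clockwise viewed from superior. Detector coordinates are in
  mm, (0,0) at the principal point, v parallel to +z.
* **DVF convention.** All fields are stored in the reference-sampling
  (pull-back) form: `warp(vol, d)(p) = vol(p + d(p))`. Demons is run
  with *fixed = phase, moving = reference*, so each stored field
  deforms the reference toward that phase — exactly the form the cost
  function needs. Consequently a field value +δ ẑ means the warped
  anatomy appears δ *inferior* of its reference position; tumor
  positions are therefore defined everywhere as the apparent location
  of the reference centroid in the warped volume, obtained by a
  fixed-point inversion `p ← c0 − d(p)` (exact for uniform fields,
  sub-0.1-voxel for breathing-scale smooth fields). This definition
  agrees with the centroid of the warped tumor mask, which is what an
  observer of the images would measure.

## Numerical components

**Projector.** Ray-driven line integrals: each detector pixel's ray is
sampled at a fixed step of min(spacing)/2 and the trilinear
interpolant is summed (midpoint rule). The back projector is the exact
matched transpose of the same discretization, so ⟨Pv, q⟩ = ⟨v, Pᵀq⟩
holds to rounding error. The warp gradient uses the *exact* derivative
of the trilinear interpolant (corner-difference weights), not a
smoothed estimate. Together these make the analytic gradient of J the
true derivative of the discrete objective, verified against central
finite differences to better than 1e-3 (in practice ~1e-6 once the
step is small enough that interpolation-cell boundaries are rarely
crossed inside the difference interval).

**λ update.** λ is re-estimated in closed form (least squares over the
ROI) at every cost evaluation — a block-coordinate treatment of the
joint problem in (u, λ). By the envelope theorem the fixed-λ gradient
equals the gradient of the λ-minimized objective, and J becomes
invariant to any global intensity rescaling of x.

**Optimizer.** Plain gradient descent with Armijo backtracking
(c = 1e-4, shrink 0.5, step re-expanded ×2 after acceptance), initial
step calibrated so the first move is half the first mode's training
score standard deviation. Stopping: relative cost drop < 1e-4 or 50
iterations. Frames are processed in time order with warm starts
(u_init = previous frame's u*), which typically converges in ~5–15
iterations per frame. Accepted steps never increase J.

**ROI.** A per-angle rectangle: the projected reference tumor centroid
and diaphragm apex, padded by 30 mm at isocenter scale (magnified onto
the panel), clipped to the detector. It concentrates the data term on
the structures that move with breathing and excludes regions where
reconstruction streaks dominate.

**FDK.** Cosine pre-weighting, Parker short-scan weighting (the arc is
200° = 180° + 2·10°, so conjugate rays must be feathered), row-wise
Ram-Lak ramp filter via zero-padded FFT (optional Hann apodization),
voxel-driven backprojection with the 1/U² distance factor. Per-view
angular weights use the actual angular gaps within a phase bin, which
are irregular after phase sorting. Absolute output values are on a
consistent linear scale but not calibrated to mm⁻¹; all downstream
consumers (Demons after range normalization, λ) depend only on
linearity.

**Demons.** SimpleITK's symmetric-forces Demons inside a hand-written
coarse-to-fine loop (shrink 4/2/1, 100/60/40 iterations, previous
level's field upsampled as initialization). Images are linearly
rescaled to [0, 100] first — the Demons force normalization is not
intensity-scale invariant and raw attenuation values (~0.02) freeze
the solver. Field and update smoothing sigmas are 1 voxel of the
current level (the native unit of the ITK smoother; sub-voxel sigmas
destabilize it). The fields entering PCA are zeroed outside a
feathered patient-outline mask derived from the reference FDK volume
(threshold + largest component + hole filling): without this, Demons
responses to view-sampling streaks in the air around the patient
contribute spurious high-variance PCA modes that carry no anatomy.

**Respiratory sorting.** Amsterdam-shroud style: SI derivative of each
projection, percentile clipping (1/99) against edge spikes, lateral
collapse to one column per frame, consecutive-column normalized cross
correlation with parabolic sub-pixel refinement, cumulative sum,
linear detrend, min–max normalization oriented inhale-high (content
moves inferior on the panel during inhale; the panel v axis points
superior). Peaks (end-inhale) segment cycles; phase is linear in time
within each cycle; six phase bins by default. The reference phase is
the bin with the lowest mean trace amplitude (peak-exhale), exhale
being the most reproducible breathing state.

## The synthetic phantom

Patient data of the kind this method targets is not redistributable,
so the package ships a deformable digital thorax used by every
end-to-end test:

* Anatomy: body ellipsoid (semi-axes 110/85/140 mm), two lung
  ellipsoids truncated from below by parabolic diaphragm domes
  (apex z = −35 mm, curvature 60 mm), optional vertebral column, and a
  12 mm-radius spherical tumor in the right lower lobe. Attenuations
  (relative mm⁻¹): soft tissue 0.020, lung 0.004, tumor 0.024, bone
  0.040. Smooth seeded random texture (σ ≈ 7 mm; amplitude 0.0015 in
  lung, 0.0012 in soft tissue) emulates parenchymal vessels and tissue
  heterogeneity and gives registration intensity signal inside
  otherwise uniform regions.
* Motion: a single spatial pattern — SI-dominant displacement,
  amplitude 12 mm at the diaphragm apex, smoothstep decay to zero at
  the lung apex, AP/LR components 0.3/0.1 of SI, feathered to zero at
  the body surface — scaled by the breathing signal
  s(t) = ((1 − cos 2πt/T)/2)^k with T = 4 s and k = 2 (exhale-weighted
  waveform), cycle-amplitude jitter of 5% (seeded), and optional
  linear baseline drift in mm/min. These are generic free-breathing
  values, not fitted to any patient.
* Acquisition: 200° arc at 5.5 frames/s. The desk preset (the default
  study condition and the one the acceptance checks run at) uses a
  64³ grid at 4 mm, a 96² panel at 4 mm pitch and a 1-minute scan
  (330 frames); a clinical-scale preset (176×228×256 at 1.1 mm, 512²
  panel, 4-minute/1320-frame scan) is config-selectable. SAD 1000 mm /
  SDD 1536 mm / 0.8 mm pixels at 512² are typical kV on-board imager
  values. Projections are ideal log-converted line integrals; additive
  Gaussian noise is optional and seeded.

**What the phantom does not emulate:** scatter, beam hardening,
detector lag and glare, cardiac motion, hysteresis (inhale/exhale path
asymmetry), irregular cycle lengths, and anatomy beyond the simple
geometric primitives. Its motion is intrinsically low-rank (one
dominant latent factor), so the PCA spectrum collapses faster than for
real patients. Passing the end-to-end checks therefore demonstrates
internal consistency of the full chain under known ground truth — not
clinical accuracy on patient data, where image quality and breathing
variability are far less forgiving.

## Evaluation protocol

Tumor error is reported along SI only, in mm at isocenter: the
estimated 3D tumor position is perspective-projected onto the panel,
the v-difference to the ground-truth detector coordinate is taken and
divided by the magnification SDD/SAD. Summary statistics are the mean
absolute error and the 95th percentile of |error| (linear-interpolated
inclusive percentile). On phantom runs the ground truth comes from the
simulator's per-frame tumor positions; the diaphragm-apex → tumor
linear-regression surrogate (automated apex detection, ordinary least
squares on the apex SI coordinate) is implemented and tested for data
without native truth.

## Known limitations

* The estimator searches only the span of the retained modes; motion
  outside that span (e.g. large baseline drift absent from the
  training phases) is recovered only up to its projection onto the
  model.
* One projection constrains motion along the ray direction weakly;
  accuracy is reported SI-only, consistent with the evaluation
  protocol.
* FDK output is uncalibrated in absolute terms; λ absorbs global
  scale, but locally nonlinear intensity distortions (scatter, beam
  hardening on real scanners) would violate the linear-intensity
  assumption of the cost.
* The Demons backend is CPU-bound; clinical-scale grids are supported
  but slow (the desk preset exists precisely to keep the full chain
  interactive).
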