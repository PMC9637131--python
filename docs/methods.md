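# Methods

`wbreg` re-implements, on CPU, a step-wise registration method for
whole-body CT (field of view mid-thigh to skull base, arms up) that
combines low-level features (the CT image in Hounsfield units) with
high-level features (threshold-derived tissue masks) to establish
point correspondence between scans of different subjects or of the same
subject over time.  This note documents the model, its parameters, the
synthetic validation phantoms, and the numerical choices.

## Pre-processing

Five masks are derived from each scan:

* **body** — voxels above an air cut (default −500 HU, chosen midway
  between air and lean tissue), largest connected component, axial
  slice-wise hole fill.  Table-like objects are detached by a one-voxel
  morphological opening before component selection; the unopened
  component containing the largest opened component is kept, so the body
  surface is not shaved.
* **bone / lean / adipose** — HU windows: bone > +200; lean soft tissue
  −29 to +150 (inclusive); adipose −190 to −30 (inclusive).  The window
  endpoints follow the printed conventions (strict bound for bone,
  inclusive range dashes for the soft-tissue windows).
* **inside-SAT** — the body region strictly enclosed by the subcutaneous
  adipose (SAT) shell.  Per axial slice and per body component, the
  adipose component(s) touching the body boundary form the shell; the
  largest interior component not touching the boundary is kept.  Slices
  without a closed shell fall back to a two-pixel erosion of the body.

Before registering two scans, voxel spacing is harmonized per axis to the
larger of the two whenever the difference exceeds ε = 0.1 mm (linear
interpolation for HU, nearest-neighbor for masks).  Masks are computed
after harmonization.

## Registration pipeline

One affine and four deformable steps, with constraints accumulating
between steps so aligned tissue cannot be disturbed later:

1. **Piece-wise affine skeleton.**  A nine-parameter no-shear affine
   (translation, Euler rotation x→y→z about the region centroid,
   per-axis log-scale) is fitted to the bone masks by SSD, first on the
   torso, then refined on five subregions (right arm, head, left arm,
   chest, pelvis) located from the bone/body geometry: the torso lateral
   extent is read from the body width at a low torso level, bone lateral
   of it forms the arms, and the shoulder line is the widest gap in the
   central-bone z-profile.  Subregion transforms are blended into one
   smooth field with Gaussian weights of the distance to each subregion
   box (σ_blend = 30 mm, a shoulder-scale transition width).  Powell's
   method with bound constraints (±30 mm, ±15°, ±0.25 log-scale for the
   torso; half that for subregions) provides the local search; a
   center-of-mass translation start supplements the identity start at
   the coarsest stage.  Bounding the search matters: sparse bone masks
   admit degenerate optima (e.g. scale collapse onto a bone-dense spot).
2. **Deformable bone** — channels CT (Pearson) + bone mask (SSD).  Bone
   voxels (source bone warped through the current field) are then locked.
3. **Soft tissue I** — CT + inside-SAT + adipose.  The one-voxel outer
   boundary shell of the warped inside-SAT mask is then locked.
4. **Soft tissue II** — CT + lean + adipose.  Non-adipose tissue
   excluding the skin (a two-voxel inner shell of the body mask) is then
   locked.
5. **SAT** — body mask only, completing the subcutaneous fat alignment.

Channel weights default to 1.0 each.  The Pearson similarity is computed
over cubic windows of radius 2 voxels: a global correlation coefficient
would provide no per-voxel unary term for the discrete solver, so a
windowed form is used; it retains the invariance to linear intensity
changes (contrast agents, calibration offsets) that motivates using
correlation on CT channels.

### Energy model

    E(u) = Σ_c w_c Σ_x m(x)·D_c(x;u)
         + Σ_{(x,y)∈N6} ½(w(x)+w(y))·|u(x)−u(y)|² / |x−y|²

with D_c the per-voxel squared difference (masks) or 1 − r_window (CT),
m(x) an optional cost-function mask, and w(x) tissue-specific
regularization weights sampled from the warped source masks at the start
of each step: bone 1.0, lean 0.4, adipose 0.1, air 0.05 (stiff where
elasticity is low).  A sweep over global scalings of these weights
(×1, ×0.25, ×0.1) on phantom pairs showed the defaults dominating on
every evaluation metric; softer settings chase noise.

### Discrete optimization

The energy is minimized by binary move-making: for a step vector δ each
voxel either keeps its displacement or adds δ; the optimal labeling is a
min-cut of an s–t graph (Kolmogorov–Zabih construction).  For this move
family the pairwise terms are always submodular
(V01+V10−V00−V11 = 2W|δ|² ≥ 0), so no truncation is ever needed.  The
max-flow problem is solved with `scipy.sparse.csgraph.maximum_flow` on
int32 capacities (fixed-point scale 10⁶); constraint voxels are pinned by
a large unary cost and additionally restored bitwise after each step.
Every move accepted by the cut is re-scored against the exact energy and
applied only if it lowers it, so the logged energy trajectory is monotone
non-increasing by construction (the windowed-Pearson unary is otherwise
an approximation that treats neighbors as fixed).

Moves are swept over the six axis directions within a Gaussian pyramid
running from level 4 down to level 2 (level i = downsampling factor 2^i).
Within each level the step anneals 2 → 1 → 0.5 voxels, continuing to
0.0625 voxel at the terminal level so the displacement quantization in mm
stays well below the level spacing; sweeps stop when no move lowers the
energy (cap 20 sweeps per step size).  The final field is produced at
level 2 and upsampled to the native lattice for application.

Two resolution choices deserve note, both motivated by the desk-scale
grids (3 mm isotropic) being much coarser than clinical CT (~1 mm
in-plane), so that a literal level-2 terminal resolution means 12 mm:

* The pyramid uses exact box averaging (mean pooling) rather than
  Gaussian smoothing + decimation; pooled mask values preserve
  partial-volume fractions, so sub-voxel boundary shifts remain visible
  to the coarse SSD.  Pooled grids are treated as sampled at the box
  centers (the level origin shifts by (f−1)/2 voxels).
* The terminal affine stage evaluates level-1 images on a stride-2
  (level-2-spaced) cost lattice.  Measured on a scale-recovery oracle,
  heavy pyramid blur biases the recovered scale by ~0.03 (blurring does
  not commute with affine scaling); sharper images on the same physical
  cost lattice remove the bias at no extra cost.

### Cost-function masking

Lesion (MTV) masks, when provided, are blurred with a σ = 3 mm Gaussian
and subtracted from one to form per-voxel data-term weights in [0, 1], so
voxels near tumors contribute less to every matching term.  The source
mask is warped through the current field at each step; a target-side mask
is applied as well when given.  The weights multiply data terms only,
never the smoothness term.

### Between- and within-subject use

For cohort work, every subject is registered to a template subject and
back; the template is the neutrally positioned subject whose body fat
percentage (adipose fraction of the body mask, a surrogate of fat mass)
is closest to the cohort median, ties to the lower id.  Within-subject
(longitudinal) registration uses the same machinery with the post-therapy
scan as source and the pre-therapy scan as target.

## Evaluation metrics

With T_ij the field from registering image i to image j (pull-back
convention: the point map x → x + u(x) sends target-frame points to
source-frame points), inverse consistency over a body region Ω is

    VME = mean over Ω of |x − (T_ji ∘ T_ij)(x)|          [mm]
    IME = mean over Ω of |I_i(x) − I_i((T_ji∘T_ij)(x))|  [HU]

with both composition orders averaged into one value per pair.  Ω is the
body mask of the image whose frame the composition starts in.  Tissue
overlap under the round-trip transform is scored with Dice on the adipose
and lean masks (nearest-neighbor warping).  Transform regularity is the
percentage of body voxels with negative Jacobian determinant
(det(I + ∂u/∂x), central differences in mm, one-sided at boundaries).
Template-space statistics are the voxel-wise median, IQR (P75 − P25,
linear-interpolated quantiles — fixed for determinism) and mean absolute
error against the template scan.

## Voxel-wise applications

* **Tumor distribution maps**: subject MTVs are pulled onto the template
  lattice through the subject→template registration field
  (nearest-neighbor, stays binary); voxel-wise occurrence counts over the
  cohort, normalized by cohort size, give percentages in [0, 100].
* **Volume change / tissue loss**: the Jacobian determinant of the
  within-subject (post→pre) field is the local volume-change map;
  ΔV = Σ_body (J−1)·v_voxel the whole-body change.  Maps transferred to
  template space (linear pull-back) are floored at q = 0.05 (folding
  correction) and averaged; the average tissue-loss map is
  max(−log J̄, 0).

## Synthetic phantoms

Phantoms are stylized, not anatomical: an elliptical torso (lean core of
configurable radius wrapped in a closed subcutaneous fat shell of
configurable thickness), neck and ellipsoidal head, vertical lateral arm
tubes joined through shoulder bridges (arms-up positioning), air-filled
lungs, and a skeleton of periodic-radius tubes (vertebra-like bumps break
the z-translation degeneracy of smooth tubes), a pelvis ellipsoid, femur
stubs, arm bones and a skull.  Class HU values are air −1000, lung −880,
adipose −110, lean +45 (plus an optional contrast offset), bone +420,
with additive Gaussian noise (default SD 10 HU, a typical soft-tissue
noise level) clipped inside each class window after a small
partial-volume smoothing, so interior class purity is exact by
construction.  Ground-truth masks are the painted class maps, never
re-thresholded.  Focal lesions are spheres at +70 HU with a separate MTV
mask.  The default grid is 64×64×128 at 3 mm isotropic, covering the
same 192×192×384 mm field of view at any test resolution; this size runs
the full pipeline in about half a minute per direction on one CPU core.

**Between-subject pairs** differ in fat-shell thickness, torso radius,
skeletal pose and lean contrast offset.  The ground-truth map from
target-frame to source-frame points is the composition of
Gaussian-blended per-subregion rigid offsets (σ = 15 mm, so the map is
essentially rigid deep inside each subregion) with an exact ray-wise
elliptical shell remap: along each ray from the torso axis the interior
and shell intervals of one geometry map linearly onto those of the
other, the outside offset decaying exponentially (20 mm scale), all
feathered in z to the torso band.  The second image is the pull-back of
the first phantom's noiseless base through this map plus fresh seeded
noise — so the truth field reproduces image_b exactly up to interpolation
and noise.  A fat-shell difference of Δ with equal core radius moves the
shell midpoint by Δ/2 radially, and the lean interior not at all.

**Longitudinal pairs** impose a smooth, foldless radial contraction of
the soft tissue about the torso axis, sparing the skeletal core (ramp
from 18 to 48 mm radius).  The amplitude is calibrated by a Brent root
find so the analytic Jacobian integrates to exactly −(shrink fraction) ×
body volume; the Jacobian grid is stored with the pair.

**Landmarks** (bone centers, lung centers, fat-shell midpoint rings) are
analytic geometry points snapped to target-lattice voxel centers and
paired through the stored field, making them exactly consistent with it.

**Study cohorts.**  The between-subject analog cohort holds five pairs
with fat-shell differences of 4–10 mm, head/arm pose offsets up to
8 mm / 5°, torso offsets up to 4 mm / 3°, and contrast offsets up to
±20 HU; the longitudinal cohort holds five pairs with 5–15% whole-body
volume loss.  All randomness flows from one integer seed per phantom.

### What the phantoms do and do not emulate

They reproduce the HU class structure, the closed-shell/interior/skeleton
topology, spacing heterogeneity, between-subject shape and pose
variation, contrast offsets, and exact deformation ground truth.  They do
not model CT physics (beam hardening, metal, scatter), anatomical detail,
sliding interfaces, or textured organs — compartment interiors are flat
plus independent noise, so the CT correlation channel carries alignment
signal only near class boundaries.  Passing tests therefore demonstrate
the mechanics and consistency of the method at desk scale, not clinical
accuracy.

## Known limitations

* Axis-aligned volumes only; oblique NIfTI orientations are rejected.
* At 3 mm desk-scale voxels, deformations below about half a voxel
  (e.g. the boundary shift of a 5% whole-body volume loss) are at the
  edge of identifiability: binary-mask voxelization noise is of the same
  order as the misalignment signal, and the recovered volume change
  underestimates small imposed changes (while tracking them monotonically
  — the cohort log-log correlation between recovered and imposed change
  exceeds 0.8).  Ground-truth recovery tests on such pairs measure the
  method's accuracy floor (~1 mm) rather than its convergence.
* The field is produced at pyramid level 2 and upsampled; structures
  finer than the terminal resolution are smoothed over.
* Binary moves along the six axis directions cannot represent arbitrary
  per-sweep rotations; they rely on annealing and multiple sweeps.
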