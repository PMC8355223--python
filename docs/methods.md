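# Methods

## Problem and model

A multimodal brain MRI case is an irregular solid (the brain occupies
roughly 12–20% of the scan cuboid) with four grayscale channels (FLAIR, T1,
T1CE, T2) and a tumor label field (0 healthy, 1/2/3 the nested BraTS
classes: whole tumor WT = {1,2,3} ⊇ tumor core TC = {2,3} ⊇ enhancing tumor
ET = {3}).  Volumetric segmentation networks want a dense regular tensor;
cropping or tiling the cuboid wastes capacity on air and loses global
context.  The package instead *transports* the brain onto a regular n³ cube
with local mass preservation and minimal deformation, in two stages:

1. **Brain → ball.**  The brain is represented as a tetrahedral mesh
   (M, ρ) normalized to volume 4π/3, with a vertex density
   ρ(v) = exp(φ(v)) ∈ [1, e] built from grayscale φ ∈ [0, 1].  Simplex
   densities are vertex means, ρ(τ) = ¼Σρ(v_i) and ρ(α) = ⅓Σρ(v_i), and the
   local measures are m_ρ(v) = ¼ρ(v)Σ_{τ∋v}|τ| and a_ρ(v) = ⅓ρ(v)Σ_{α∋v}|α|.
   A discrete optimal-mass-transport map f*_ρ : M → B³ minimizes the
   transport cost T_c(f) = Σ_v ‖v − f(v)‖² m_ρ(v) subject to
   ρ(τ)|τ| = |f(τ)| per tetrahedron.
2. **Ball → cube.**  A case-independent transport map f*_δ of a Kuhn
   tetrahedralized cube (constant density δ ≡ 1, volume 4π/3) onto the same
   ball is precomputed once per resolution; the composition
   f*_{ρ,δ} = f*_δ⁻¹ ∘ f*_ρ maps the brain onto the cube and inherits local
   mass preservation from the two stages.  A direct brain → cube solve is
   not attempted: the spherical alternating scheme below needs a rotationally
   symmetric target.

Because ρ is largest where the (histogram-equalized) grayscale is large —
tumor tissue — the tumor claims a proportionally larger share of the cube's
voxels, rebalancing the foreground/background ratio that segmentation
training sees.

## Numerical solvers

**Boundary stage.**  The boundary map g : ∂M → S² minimizes the regularized
area-stretch energy

    E_A(g) = Σ_ℓ ‖L_A(g) g^ℓ‖² + λ Σ_i ‖g_i − v_i/‖v_i‖‖² a_ρ(v_i),

where L_A(g) is the area-weighted Laplacian with off-diagonals
−½ Σ_α cot(θ_ij(g))/σ_{g⁻¹}(α) over the two faces containing edge (i, j),
and σ_{g⁻¹}(α) = ρ(α)|α|/|g(α)| is the area-stretch factor.  Two
implementation identities matter:

- cot(θ(g))/σ equals (image-edge dot product)/(2ρ(α)|α|) exactly; this
  "stretch-energy" form is finite even for degenerate image triangles and is
  what the assembly computes.
- σ ≈ 1 is only meaningful after normalizing both measures to unit total
  (the boundary's total area measure need not equal 4π); reported stretch
  factors are measure-normalized, while the Laplacian uses the raw formula
  (a global constant in σ rescales the linear system without changing its
  solution).

The energy is minimized by alternating hemisphere solves in the
stereographic plane: southern vertices (g₃ ≤ 0) solve
(L_A + λ diag(a_ρ)) h = λ a_ρ u with the northern vertices fixed, the
sphere is flipped (the plane inversion z ↦ 1/z̄), and the roles swap.
Alignment weights of vertices whose target lies near the projection pole are
zeroed for that half-step (their planar image is unbounded).  Iterates that
do not decrease E_A are rejected; the best iterate is returned, with
convergence declared on relative energy stagnation below `tol`.

*Initialization.*  The default initial map is the normalized radial
projection v/‖v‖: on the star-shaped solids this package builds it is
fold-free, it is the exact minimizer of the alignment term, and the
alternating solves converge cleanly from it (measured on a digitized ball:
mean σ → 1.002, zero folds).  A punctured-harmonic initializer (cotangent
flattening after removing the triangle farthest from the centroid, median
rescale, inverse stereographic projection, centroid centering) is available
as `init='harmonic'`; its extreme area concentration near the puncture makes
the subsequent iteration markedly less stable, which is why it is not the
default.

*Rotation equivariance.*  The hemisphere alternation singles out the z axis,
so the raw scheme depends on how the input happens to be oriented.  The
solve therefore runs in the boundary's area-weighted principal-axes frame
(signs fixed deterministically by third moments) and rotates the result
back; the transport cost of a rigidly rotated case then agrees with the
original to machine precision.

**Interior stage.**  With the homotopy g_t(v) = (1−t)v + t g(v) on a uniform
schedule t_k = k/p (default p = 8; cost rises and distortion falls
monotonically in p, crossing near 8), each knot solves

    [L_V(f^(k−1))]_II f^(k)_I = −[L_V(f^(k−1))]_IB g_{t_k},

where L_V has the mass-modified cotangent weights
w_ij = 1/9 Σ_τ |f([v_i,v_k,v_ℓ])||f([v_j,v_ℓ,v_k])| cos θ / (ρ(τ)|τ|)
(θ the image dihedral angle at the opposite edge; for the identity map and
ρ ≡ 1 this reduces to the classical |e| cot θ / 6).  Systems are solved by
direct sparse LU factorization — same input, bitwise-identical output.  The
pipeline re-assembles L_V once per knot at the fresh iterate
(`inner_iterations=2`): a single assembly per knot leaves visibly more local
mass distortion (stretch mean 1.022 vs 1.009 on the default phantom), short
of the convergence quality the method is known to reach.

**Folded elements** (image tets with non-positive volume under the source
orientation) are counted and reported, never repaired.

## Mesh construction ("remeshing")

Masks come from thresholding (any modality > 0; background is exactly zero),
largest 6-connected component, a monotone plaquette repair that fills
diagonal checkerboard configurations (voxels meeting only along an edge or
corner would make the boundary non-manifold), morphological
closing/dilation escalation, and cavity filling, until the boundary is a
topological sphere.

Each voxel cell splits into six positively oriented tetrahedra along a
globally fixed diagonal (Kuhn split), which conforms across neighbours and
preserves volume exactly.  Three further steps make the raw grid mesh
solver-ready (`build_solid_mesh`):

- **Boundary smoothing** (30 rounds): locally damped Laplacian smoothing of
  the boundary along the surface graph with Jacobi relaxation of the
  interior; a vertex's displacement is halved (repeatedly) whenever an
  incident tet would drop below a small positive volume floor, so smoothing
  proceeds everywhere except exactly where it would invert an element.
- **Pinned-tet collapse**: a tet with all four vertices on the boundary has
  its image volume dictated entirely by the boundary map, and across a
  concave crease its spherical image is orientation-forced to fold
  (flattening a concave wedge to convex would require passing through zero
  volume).  Every such tet is removed by collapsing one of its edges
  (shortest first, midpoint placement), subject to all surviving tets
  staying positively oriented, iterated to exhaustion.
- **Light re-smoothing** (10 rounds) and normalization (volume-weighted
  centroid to the origin, volume to 4π/3; the affine is stored so voxel
  coordinates are recoverable exactly).

The mesh budget follows the method's remeshing ratio of roughly 7–8 brain
voxels per mesh vertex: the pipeline block-downsamples every mask by a
factor of 2 (majority rule, ties filled), escalating further only if the
vertex count would exceed 2.5×10⁵.  A full 240³ case therefore lands at
~2×10⁵ vertices, and phantoms are meshed at the same ratio the method is
validated at.

## Resampling, inverse labels, augmentation, voting

All four modalities share one map (built from the equalized-FLAIR density
ρ̃₁ by default; the four-view mean density ρ₂ = exp(¼Σφ_i) is the
augmentation alternative).  Grayscale is standardized per modality over the
mask ((x − mean)/SD, then min–max to [0, 1]; the printed "/variance" recipe
differs only by an affine factor that the min–max shift absorbs), and the
density channel is additionally sharpened by masked 256-bin histogram
equalization (normalize first, then equalize).

Forward resampling evaluates the inverse map at every cube voxel centre w:
grayscale channels are trilinear samples at the pulled-back brain point,
labels are nearest-voxel.  Inverse label conversion uses the two-rule
procedure: a brain voxel containing pulled-back cube centres takes their
majority label (ties towards the larger, tumor-preserving, label); every
remaining mask voxel takes the label of the nearest pulled-back centre.
Point location in deformed images uses a KD-tree over image-tet centroids
with barycentric containment checks and nearest-tet snapping in the thin
curved boundary layer; location in grid meshes is closed-form (cell index
plus the rank permutation of the fractional coordinates).

Augmentation rotates the unit ball between the stages by a uniformly random
rotation (seeded).  Test-time postprocessing supports the four cube schemes
R₁ (90° counterclockwise quarter-turn, slice-wise in the first two axes),
R₂ (left-right mirror), R₃ (up-down mirror), R₄ = R₂ then R₁, with exact
inverses, and a five-way probability vote.  The literal decision rule
Σp_k > 1 − Σp_k (i.e. Σp_k > ½) is the default; because that threshold is
very permissive for five probabilities, the mean-majority variant
Σp_k > 5/2 is selectable (`rule='mean'`).

## Quality metrics

Transport cost T_c (as above); total mass-measure distortion
D_M(f) = ¼ Σ_v |m̂(v) − v̂(v)| and local stretch ratio R_M(f, v) = m̂(v)/v̂(v),
where m̂ and v̂ are the vertex-star source mass and image volume, each
normalized to unit total; bijectivity rate = (1 − folded/total)·100%;
conversion loss = 1 − Dice between original labels and labels after a
forward/inverse round trip.  Segmentation metrics are Dice, sensitivity,
specificity, and the Hausdorff distance: boundaries are voxels with a face
neighbour outside the set (6-connectivity), distances are voxel units
(isotropic 1 mm), HD95 takes the maximum of the two directed 95th
percentiles (linear interpolation), mirroring the max–min structure of the
plain HD; a symmetric pooled variant is available.  Empty sets yield +inf
(HD) or a flagged perfect agreement (two empty sets in the Dice-type
metrics) rather than silent numbers.

## Synthetic phantom

The phantom emulates the structure the pipeline consumes: a genus-zero
brain (superellipsoid, exponent 2.3, semi-axes (0.375, 0.32, 0.28) of the
grid size ≈ 14% fill, with a band-limited radial perturbation), nested
ellipsoidal tumor labels targeting WT ≈ 7% of the brain with TC/ET radius
ratios 0.72/0.57 (volume ratios matching the ~7.2/2.6/1.4% class mix of
real cases), and four smooth grayscale channels (Gaussian-filtered seeded
noise, σ = 5 voxels) with modality-specific tumor contrast — FLAIR
brightest on WT, T1CE brightest on ET, T2 elevated on TC, T1 mildly
hypointense.  Background is exactly zero; everything is deterministic given
the seed.  It does not model MRI physics (noise correlations, bias fields,
partial voluming) or multifocal lesions, so passing tests certify the
geometry/measure pipeline, not robustness to scanner artifacts.

A probability-cube fixture (1−ε on tumor, ε elsewhere, clipped Gaussian
noise) stands in for a segmentation network's output when exercising the
voting rules; it is synthetic and does not model network error structure.

## Problem sizes and numerical choices

Default study conditions: 64³ phantoms (≈42 000 brain voxels, ≈5 700 mesh
vertices at the standard remeshing ratio), homotopy p = 8 with two inner
assemblies per knot, boundary λ = 0.1, tol 10⁻⁶, ≤100 outer iterations,
cube stage at 24³ cells (the n³ resampling grid — default n = 128, with 96
supported — is decoupled from the cube mesh resolution: the map is
piecewise linear, so sampling resolution and mesh resolution are
independent choices).  The cube-stage map is cached per (resolution, p, λ).
Degenerate inputs: constant grayscale normalizes to ½; empty masks and
non-spherical boundaries raise; two empty label sets compare as equal.

Conversion losses measured on phantoms at these sizes are ≈0: with ~15–60
pulled-back cube centres per brain voxel, the majority rule reproduces the
original label of every covered voxel exactly, and coverage is complete.
Real 240³ cases have ~1.5 centres per voxel at n = 128, which is where the
sub-percent losses of full-scale runs come from; the phantom regime bounds
the loss from below, and the resolution direction (coarser grids lose at
least as much) is still exercised.

## Known limitations

- Zero folded tetrahedra is achieved on the identity-limit ball at the
  standard remeshing ratio; meshing phantoms at full grid resolution
  (ratio ~1) can leave isolated folds (1–2 per map) at crease remnants,
  the same order as full-scale runs of the method report.
- The cube-stage map preserves per-tet volume only approximately near the
  cube's edges and corners (the global distortion D_M stays small, but
  individual corner tets deviate strongly); the composed map's stretch
  statistics are the meaningful quality measure.
- The principal-axes canonicalization assumes a boundary with distinct
  inertia eigenvalues; exactly spherical inputs fall back to an arbitrary
  (deterministic) frame.
- Genus repair is morphological; pathological masks (thin handles at large
  scale) can exhaust the escalation and raise rather than mesh incorrectly.
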