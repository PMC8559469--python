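# Methods

This note documents the models, parameter choices and numerical
conventions behind `geodeface`, and what its phantom-based tests do and
do not demonstrate about real data.

## Coordinate conventions

All geometry — mesh vertices, control points, influence radii — lives in
world millimetres, RAS+ (x: left→right, y: posterior→anterior,
z: inferior→superior). Voxel indices are 0-based; a voxel is the closed
cube centred on its grid point. Input volumes are reoriented to the
closest-canonical RAS layout by axis permutation/flips only; **no
resampling ever happens** — every operation runs on the native grid, and
canonicalization preserves each voxel's world coordinate exactly.
Volumes more oblique than 5° from axis-aligned are processed in world
space with a warning. Written NIfTI headers are regenerated from the
volume's dtype and affine; descriptive fields and extension blocks from
any source file are never propagated, so a defaced output cannot leak
identifying header content. (This is deliberately stricter than leaving
header hygiene to the user.)

## Segmentation model

The head model is a T1-like five-band intensity ordering:
background < skull ≈ CSF-dark < scalp < brain-bright. Segmentation
proceeds in two coupled parts.

**Head/background:** Otsu's threshold `t_bg` splits background from
tissue; a marker-based watershed on the Gaussian gradient-magnitude
image (`grad_sigma_mm = 1.5`) floods from border background seeds and
from all tissue brighter than the CSF|scalp threshold (scalp *and*
brain). Marking the scalp directly matters: if only a bright core is
seeded, a defaced input whose scalp has an opening lets the background
basin tie with the head basin at the skull–scalp ridge and steal the
scalp. The watershed line is then corrected within a ±2-voxel band by
the background threshold itself, which makes the head boundary exact on
noise-free data.

**Tissue bands:** thresholds are midpoints between 1-D k-means centers —
a 3-class fit (CSF, scalp, brain) on above-background intensities and a
2-class fit (background, skull) on the rest, both Lloyd iterations with
fixed quantile initializations, hence deterministic. Each midpoint is
snapped to a coarse scale-free grid (≈ intensity range / 64, rounded to
a power of two). Snapping is a stability device: the defacing fill
redraws shell voxels from the shell's own empirical distribution, so
un-snapped thresholds would jitter by sampling noise between a volume
and its anonymized twin and could flip band-edge voxels; snapped
thresholds make skull-stripping the anonymized volume voxel-identical
to the original, which is what the brain-conservation guarantee needs.

Compartments are then built bottom-up, each step independent of
head-mask topology: brain = filled largest bright component; inner skull
= filled largest component of (CSF band ∪ brain); skull band = dark
voxels within `skull_reach_mm = 8` (Euclidean distance transform) of the
inner-skull mask, with a 1-step morphological closing whose additions
are restricted to sub-scalp intensities (bridges noise gaps without
inflating the band's outer rim); outer skull = filled largest component
of (inner ∪ skull band). The final head mask is the filled largest
component of (watershed head ∪ outer skull) — the union happens *before*
the largest-component reduction because a defaced opening can disconnect
scalp from brain inside the watershed result, and the outer skull is the
bridge between them. Bounding the skull search by distance to the inner
surface is what keeps the (equally dark) background out even when a
defaced input opens a path to it.

This is intentionally *not* a reimplementation of the hybrid
template-deformation watershed used clinically; the self-contained
marker/band construction is calibrated for geometric fidelity on
phantoms, and its parameterization (`SegmentationParams`) is exposed.
A fixed head-interior quantile for the skull band (`skull_quantile`) is
available as an override; the k-means midpoints are the default because
they adapt to compartment volume fractions and they snap.

## Surface extraction

Marching cubes at level 0.5 of the (mildly pre-smoothed,
`presmooth_sd = 0.5` voxel) mask, one-voxel zero padding so surfaces
close at the volume edge, largest component, hole closing, outward
orientation, then Taubin smoothing (`λ = 0.5, ν = −0.53`, 10
iterations — volume-preserving, unlike Laplacian shrinking). Mask voxels
whose pre-smoothed value falls below the level are clamped just above it
so thin protrusions (a nose tip) cannot be washed away. A mesh still
non-watertight after repair is returned flagged rather than raised,
because a distorted reconstruction is an outcome the usability screen is
supposed to measure. On closed-form fixtures the defaults land within
~3% of true volumes and ~1.5% of true areas, and errors shrink with grid
resolution.

## Landmarks and registration

A complete control-point set has ≥ 3 `face` points and ≥ 1 per ear
(`ear_L`, `ear_R`); default influence radii are 25 mm (face) and 20 mm
(ears) — chosen once so the default phantom's nose and ear features are
fully covered by the balls of the corresponding landmarks, and
overridable globally or per point. FCSV files follow the 3D Slicer
markups dialect: positions are interpreted per the file's
`# CoordinateSystem` header (LPS assumed, with a warning, when absent —
Slicer's default) and converted to RAS by negating x and y; per-point
radii ride in the description column (`radius=25`). The JSON schema
declares its coordinate convention explicitly.

Registration (template → subject) is SimpleITK's multi-resolution
(4/2/1 shrink, 2/1/0 smoothing) affine optimization of a correlation
metric, initialized by image moments, with `RegularStepGradientDescent`
and a fixed metric-sampling seed so runs are reproducible; an optional
diffeomorphic-demons pass adds a dense displacement field on the
template grid. The transform maps template-space points to subject
space; transferred points are then projected to the exact nearest point
of the subject's skin mesh. The projection is the robustness mechanism:
the output always satisfies the on-surface invariant, and registration
error can only slide points tangentially. Points that had to travel
more than 15 mm are flagged; more than half flagged aborts the transfer
with a recommendation to place points manually.

Template bundles are directories (`template.nii.gz`, `points.fcsv`,
`manifest.json` with SHA-256 checksums, verified on load). No external
template data is bundled; a phantom-derived template can be built in
seconds with `make-template`.

## Masking and fill

The shell is computed by rasterizing the skin and outer-skull meshes
with an even-odd scanline voxelizer (axis-aligned rays through voxel
centers, fixed sub-voxel jitter against vertex/edge degeneracies):
shell = inside skin ∧ outside outer skull. Voxel centers exactly on the
skin isosurface count as inside, so the skin boundary voxels are
preserved and the surface re-extracts identically in unmasked regions.
The active mask is the shell intersected with the union of Euclidean
balls around the control points — the simplest influence geometry
consistent with point-plus-radius landmarks; geodesic skin patches are a
documented alternative left unimplemented.

The fill distribution is the exact multiset of *all* shell intensities
(one global pool, not local neighborhoods); sampling is i.i.d. draws
with replacement, no spatial correlation. The fill RNG is a Philox
counter-based generator keyed by the user seed, with draws assigned to
active voxels in fixed C order — bitwise reproducible regardless of
platform or iteration strategy. Exterior zeroing is global by default
(`--zero-exterior global|face-only|off`): it removes background
artifacts as well as any residual face silhouette, at zero cost to the
skin boundary. The mask reaches inward only to the *outer* skull
surface; the skull itself is never touched.

## Evaluation battery

*Jaccard* |A∩B|/|A∪B| on the brain masks of a skull-strip run on both
members of a pair, with both members segmented by this package's own
watershed (the two-template external skull-stripper setup it stands in
for is not reproducible here); two empty masks count as identical.
*Hausdorff* distances are computed from dense area-weighted surface
samples (all vertices + 10⁴ face samples by default) against exact
point-to-triangle distances, both directions; vertex-to-vertex shortcuts
systematically underestimate and are not used. The symmetric form is the
max of the directed ones; an optional point filter supports region-split
variants ("Hausdorff outside the masked region"). *Usability* automates
what would otherwise be visual inspection: `failed` = no mesh or
non-watertight after repair; `distorted` = multiple bodies, genus > 0,
enclosed volume off by more than 25% of the subject's own
compartment-derived reference, a violated nesting check, or a crumpled
surface (> 1% of adjacent-face dihedral angles beyond 90°). The fold
criterion is the practical stand-in for exact self-intersection testing,
which no installed collision backend provides and which a pure-Python
exact test would make prohibitively slow; crumpled, self-intersecting
meshes reliably light it up. All thresholds are configurable.
`compare_pair` reports Hausdorff only for surfaces usable in both
members, matching the conditional structure of the evaluation it
automates, and pairs with standard Wilcoxon / Cochran's Q / McNemar /
Holm utilities for batched reports.

## The phantom

Nested ellipsoids (brain ⊂ inner skull ⊂ outer skull ⊂ skin, default
semi-axes 50/64/44 … 70/85/65 mm) with a nose (9×15×11 mm half-ellipsoid
protruding anteriorly) and two lateral ear bumps (12×14×15 mm), on a
128³ grid at 1.5 mm, head center shifted 8 mm posteriorly so the nose
stays in the field of view. Intensities are compartment means
(background 0, skull 30, CSF 60, scalp 90, brain 120, arbitrary units)
plus i.i.d. Gaussian noise (σ = 4); `PhantomSpec` validation enforces ≥ 5σ
separation between means so segmentation on the phantom is well-posed by
construction. The CSF gap between brain and inner skull carries its own
intensity band because without it no intensity-driven method could
recover the inner-skull boundary at all (real pipelines lean on shape
priors there). Ground truth is analytic: marching cubes of the exact
quadric fields gives the four surfaces, landmarks are closed-form points
on those surfaces (nose tip, brow, chin, cheeks, ear apices), and the
label volume partitions the grid. Feature masks record the protruding
(identity-bearing) nose/ear voxels. Generation is bit-reproducible under
the `PhantomSpec` seed.

`degrade_like` produces the two comparison surrogates: `blank-face`
zeroes the face-ball region outside the outer skull (face removal that
leaves cranial content intact), `blur-face` Gaussian-smooths the
unrestricted region (blurring that bleeds across tissue boundaries —
precisely the failure mode that breaks downstream surface extraction).

**What the phantom does not emulate:** partial-volume effects, bias
fields, Rician noise, anatomical asymmetry and texture, real ear pinna
geometry, neck and shoulders. Passing the phantom suite therefore
demonstrates the *mechanics* — conservation, exactness of the fill
rules, metric correctness, robustness of the pipeline's couplings — not
segmentation accuracy on clinical contrast. On real data the watershed
parameterization would need validation per protocol, and the usability
screen's thresholds may classify borderline meshes differently than a
human rater.

## Problem sizes and numerical choices

The study phantom is 128³ at 1.5 mm; unit tests use 96³ at 2 mm. A full
anonymization of the study phantom takes ~3 s, the complete acceptance
run ~1.5 min on one CPU. Hausdorff estimates use 10⁴ samples per mesh
(monotone non-decreasing in sample count; at this density the estimate
is within the mesh discretization error). Watershed ties are resolved by
the flooding implementation's deterministic raster order; k-means ties
cannot occur with distinct initial quantiles. Degenerate inputs fail
loudly with diagnostics: uniform volumes, empty or touching marker sets,
collapsed intensity bands, empty shells, non-nested surfaces.

## Known limitations

- The influence geometry is spherical; a ball large enough to cover a
  long feature also reaches deep. The shell intersection bounds the
  damage (the mask can never reach inside the outer skull), but very
  large radii will refill scalp far from the face.
- One global fill distribution slightly flattens any scalp intensity
  gradient inside the masked region; a local-neighborhood pool is a
  straightforward extension.
- The usability screen's fold criterion is a proxy, not an exact
  self-intersection test.
- Re-anonymizing an already-anonymized volume is supported and keeps the
  brain bitwise intact, but the exterior zeros make the background
  distribution degenerate, so intensity statistics of a twice-processed
  shell are no longer those of the original scalp.
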