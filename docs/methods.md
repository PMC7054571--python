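# Methods

## The delineation model

The pipeline treats HG segmentation as a graph problem on the
white-matter surface mesh.  Its core assumption is the FreeSurfer
curvature convention: on the grey–white boundary surface, vertices with
negative mean curvature are locally convex and lie on gyri, positive
curvature marks sulci.  A transverse temporal gyrus is therefore a
connected set of H < 0 vertices, its crown is the band of strongest
convexity, and the gyrus/sulcus transition is the H = 0 inflection line.
Both thresholds are strict inequalities; vertices exactly at a threshold
are excluded.

Two masks are maintained in parallel.  The *auditory complex*
(gyrus ∪ sulcus ∪ planum temporale ROIs) is where crowns are searched;
the *expansion mask* additionally includes the posterior segment of the
lateral sulcus, because atlas parcellations frequently assign the
medial-most part of HG to that label — growing the crowns inside the
larger mask recovers it.  Both masks are curvature-filtered and then
opened on the vertex graph before use.

### Morphology on the vertex graph

Erosion, dilation and opening are defined in hop-distance layers on the
vertex adjacency graph (two vertices adjacent iff they share a mesh
edge), not in millimetres: at FreeSurfer's ≈1 mm average edge length a
disk-of-radius-two-edge-lengths structuring element corresponds to
removing three vertex layers, and that is the behaviour reproduced here
with the default `opening_depth = 3`.  Erosion removes every member
within hop distance ≤ depth of a non-member; dilation restores every
vertex within depth hops of the eroded core, **intersected with the
original set** (geodesic-reconstruction style).  The intersection is
what keeps thin formations — gyral fingers up to 2·depth = 6 vertices
wide — from reappearing, while the blob interiors are restored exactly.
The operator is anti-extensive, increasing and idempotent; all three
properties are tested, as is equality with a literal brute-force BFS
oracle on randomized sets.

"Volumetric centre" of a candidate gyrus is implemented as the
area-weighted centroid of its white-surface vertex coordinates.  A true
volumetric centre would require voxelised grey matter that the pipeline
never constructs; the area weighting is the closest surface-native
analogue, and only the *anterior ordering* of centroids matters for
selection.  Anterior = larger coordinate on the configured RAS axis
(default +Y).  Ties break to the larger cluster, then to the one
containing the smallest vertex index, making the pipeline fully
deterministic.  The cluster-size check (default minimum 100 vertices)
runs after regrowth, on the connected candidates, before selection.

### Discrete geometry

Mean curvature uses the cotangent mean-curvature-normal operator with
Meyer's mixed Voronoi vertex areas, signed by the vertex normal so that
convex regions are negative (the FreeSurfer convention); on an
icosphere of radius 10 mm it reproduces −0.1 mm⁻¹ to ≈10⁻⁵.  Gaussian
curvature is the angle deficit (π at boundary vertices of open patches)
over the same areas, so the discrete Gauss–Bonnet sum closes to 4π on a
sphere.  The open-boundary ring of a patch has no meaningful curvature
estimate; it is set to 0 there and excluded from ground-truth crest
sets.  Per-vertex areas for integrals and centroids are the barycentric
third of incident triangle areas, which makes area sums exactly
conservative.

### Anatomical quantification

For a label on corresponding white/pial surfaces: surface area is the
sum of white-surface vertex areas; grey-matter volume uses a per-vertex
prism, thickness·(white area + pial area)/2 — this is an internal
approximation, not an attempt at bit parity with any external tool, and
it matches analytic slab and spherical-shell volumes to ≤2%.  Thickness
mean and SD are unweighted over vertices (the reference convention).
Curvature indices are 1/(4π)-normalised area integrals of rectified
curvatures; principal curvatures are recovered from (H, K) as
H ± √max(H²−K, 0).  For the folding index |k₁|(|k₁|−|k₂|) the pair is
ordered by magnitude, not numerically — numerical ordering would make
the rectified integrand negative on convex cortex, and the folding
literature defines it with |k₁| ≥ |k₂|.  The volume sanity bound is
volume ≤ mid-surface area × max thickness (the white-area bound fails
on convex labels where the pial sheet is larger).

## The synthetic test bed

The generator emulates the features of a supratemporal plane that the
pipeline actually consumes; it is the study-conditions definition, not a
tuning knob.  A regular 120×90 grid spans 60×45 mm (≈0.5 mm spacing,
finer than typical cortical meshes so that layer-based morphology and
the 100-vertex cluster floor behave at realistic scale).  The height
field is the pointwise maximum of oblique Gaussian ridges — amplitude
6 mm, transverse σ = 4 mm, 15° obliquity, axes at y = +7 mm (anterior,
"HG") and −7 mm (posterior duplication) — smoothed with a 1 mm Gaussian
to remove crease artifacts of the max.  These values give crest mean
curvature ≈ −0.17 mm⁻¹, comfortably below the −0.1 crown threshold, and
an H < 0 band whose half-width is the effective σ ≈ 4.1 mm, matching the
4–6 mm half-widths of real transverse gyri.

Morphotypes: *single* has one ridge; *fpd* has two fully separated
ridges (14 mm axis separation leaves a positive-curvature valley
between them); *csd* adds a narrow connector ridge running
anteroposteriorly at the centre of the medial (1 − span) stretch of the
gyrus.  The connector creates a saddle whose transverse curvature
dominates, so the two ridges stay connected through H < 0 vertices — a
flat "fill" between the ridges would have H ≈ 0 and break exactly the
connectivity that defines a common stem.  Ground truth marks the ridge
bands at 0.95 of the inflection half-width (conservatively inside the
H < 0 region), the per-gyrus crest rows, and HG = anterior gyrus
(+ posterior gyrus and stem for CSD only).

Vertical jitter (default SD 0.05 mm) is spatially smoothed at 2 mm
before scaling: unsmoothed white noise at 0.5 mm spacing would inject
second-difference curvature noise of order noise_sd/dx² ≈ 0.2 mm⁻¹,
swamping every threshold — a roughness no reconstructed white surface
exhibits.  Thickness is a smooth field around 2.5 ± 0.3 mm, clipped
positive; the pial surface is the white surface offset along vertex
normals by exactly that field.

The parcellation assigns the four Destrieux-style ROIs geometrically
(gyrus bands at 1.5σ, a 4 mm sulcus band, planum temporale posterior,
the lateral-sulcus ROI on the 5 mm medial margin).  Labelling-error
injections operate **only on the parcellation**, never on geometry,
mirroring the fact that the errors being corrected are atlas errors:
`exclude_medial_hg` moves the medial 20% of the HG ROI into the
lateral-sulcus ROI, `spill_into_sulcus` extends the HG ROI into the
adjacent sulcal band, and `split_csd_to_pt` reassigns the CSD's second
gyrus to the planum temporale.  The moved vertex sets are recorded so
tests can score recovery exactly; recovery is measured over moved
vertices that are both ground-truth gyral and off the mesh boundary
(boundary vertices have no curvature estimate on an open patch and can
never enter a label — an artifact of finite patches, not of the method).

What the fixtures do **not** model: whole-hemisphere topology (closed
surfaces), scanner noise and intensity artifacts, reconstruction
failures that distort geometry, third/fourth transverse gyri, and the
anatomical covariation of thickness with curvature.  Passing tests
therefore demonstrate the algorithm's correctness given a
FreeSurfer-convention curvature field and parcellation, not robustness
to reconstruction failure.

## Statistics

The method-comparison statistic is the Meng–Rosenthal–Rubin z test for
two dependent correlations sharing a variable (two automated methods
each correlated with the same manual reference).  A naive
independent-samples Fisher r-to-z comparison would ignore the
dependency and is provided only behind a flag for contrast; it neither
suits the design nor reproduces the published whole-sample z magnitudes,
whereas the Meng form lands within ~2–3% of them when fed the printed
(rounded) correlations — the residual is consistent with input rounding,
so those z values are treated as approximate cross-checks.  One-tailed
p values are in the direction r₁ > r₂.  The test's null calibration
(rejection rate 0.05 ± 0.01 at α = 0.05 over 10,000 simulated triples)
is part of the acceptance suite.  Partial correlations residualise both
variables on the covariates plus intercept by least squares, with
t-based p on n − 2 − k degrees of freedom.

## Numerical and design choices

- Component lists and all vertex-set outputs are ordered by smallest
  member index; nothing in the pipeline is randomised.
- Crowns falling outside the independently refined expansion mask are
  intersected into it with a logged warning rather than an error (the
  grow step is defined only inside the mask).
- An empty-but-named ROI warns and continues — a hemisphere can lack a
  distinct transverse temporal sulcus.
- Degenerate zero-area faces contribute nothing to areas; an
  all-degenerate mesh is an error, as is any non-manifold edge.
- File writes use a fixed creation stamp so outputs are byte-identical
  across runs; all multi-byte on-disk values are big-endian 32-bit.
- Problem sizes in the acceptance script (10 generator seeds per
  morphotype, 10,000 statistic replicates, subdivision-4 icospheres,
  ≤2,000-vertex oracle meshes) keep a full from-scratch run under half
  a minute while leaving Monte-Carlo error well inside the tolerances
  checked.

## Known limitations

- Hop-layer morphology is resolution-dependent by construction: on
  meshes much finer or coarser than ≈0.5–1 mm edge length the default
  depth 3 corresponds to a different metric radius
  (`opening_depth` is configurable for that reason).
- The per-vertex prism volume ignores oblique columns between the
  white and pial sheets; against analytic fixtures the error is ≤2%,
  but it is not the exact grey-matter Jacobian integral.
- Selection assumes the anterior axis of surface RAS is anatomically
  anterior; heavily rotated surface frames would need the
  `anterior_axis` override.
- Boundary vertices of open patches carry H = 0, so labels can never
  reach the outermost vertex ring of a synthetic patch; real (closed)
  surfaces have no such ring.
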