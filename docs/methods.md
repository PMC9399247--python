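# Methods

`toothpair` quantifies how similar a tooth is to the mirror image of its
contralateral partner, and whether that similarity suffices to *identify*
the partner among a population.  This note documents the model, the
numerical choices, and what the synthetic study conditions do and do not
show.

## The pair-matching procedure

For one tooth type (central incisor, lateral incisor or canine) and a
population of individuals with both sides present:

1. **Mirroring.** The left tooth is reflected across the plane that
   contains its long axis — the line through the root apex and the crown
   midpoint.  A reflection plane needs an azimuth as well as an axis; we
   take the plane normal to be the mesiodistal direction (local x)
   orthogonalized against the axis.  This is a modelling choice: mirroring
   "along the long axis" leaves the azimuth free, and any residual azimuth
   error is exactly the degree of freedom the constrained ICP later
   optimizes.

2. **Superimposition.** A closed-form Kabsch least-squares rigid fit on
   three reference points (root apex, left and right prominent
   incisal-edge points) gives the initial alignment.  Reflections are
   excluded by the determinant correction.  Note the incisal landmark
   labels swap when a tooth is mirrored.

3. **Constrained ICP.** A point-to-plane ICP restricted to a 3-parameter
   motion group: rotation θ about the target tooth's long axis and
   translation (u, v) in the plane perpendicular to it.  Rationale: after
   landmark alignment the pair share a long axis, so the remaining
   freedom is spin about that axis and in-plane shift; leaving the other
   three parameters free would let the registration absorb genuine
   asymmetry.  Each iteration samples source points, finds closest target
   points with normals, rejects correspondences beyond a cap (default
   2 mm), and solves the linearized 3×3 normal equations.  The update is
   composed *within* the group (a rotation about the axis followed by an
   in-plane translation stays in the group), so the returned transform
   satisfies the constraints to machine precision rather than
   approximately.  Defaults: 2000 samples, tolerance 1e-6 mm on the RMS
   change, 100 iterations maximum.  The population pipeline uses a
   cheaper setting (300 samples, 1e-4 mm, 40 iterations), which testing
   shows is converged at the 0.01 mm level — far below the HD differences
   being measured.

   Correspondence comes in two modes: nearest target sample point with its
   vertex normal (fast; used in population runs) and exact closest point
   on the target triangles with the face normal (used where 1e-3 mm
   recovery accuracy is asserted).

4. **Element extraction.** Two closed curves partition each tooth
   surface: the gingival margin and its geodesic offset 3 mm apically
   *along the surface*.  The crown is the region coronal to the margin,
   the emergence profile the band between the curves, the root the rest
   (excluded from scoring).  Geodesic distance is computed by Dijkstra on
   a Steiner-refined edge graph (default 3 extra nodes per edge; 2 in the
   population pipeline), accurate to ~2% on smooth meshes — adequate
   because a 2% error on a 3 mm band boundary is 0.06 mm, an order below
   the HD signal.  Faces crossed by a curve are split exactly along the
   interpolated zero set of the signed geodesic field, so the three
   regions partition the surface area exactly (asserted to 1e-6
   relative).  Boundaries are inclusive on the coronal side.  Extraction
   commutes with rigid motion, so it is done once per tooth, not per pair.

   Two robustness details matter for bilateral comparisons.  Both cuts are
   level sets of the *margin's* signed field — the coronal cut at level
   zero, the apical cut at the offset curve's own field level — so the two
   band edges stay mutually consistent; cutting in a second field anchored
   to the extracted offset polyline would compound discretization errors.
   And the field's side assignment near the curve uses a continuous
   geometric test (offset from the nearest curve point along the coronal
   direction) rather than flood-fill majority votes, whose knife-edge
   decisions can differ between two near-mirror-identical meshes by a
   whole face row.

5. **Similarity.** Symmetric Hausdorff distance between the registered
   element surfaces, measured between point sets: element vertices plus an
   area-weighted uniform face sample (20 points/mm² in the population
   pipeline).  Point-set HD is a discretization of surface HD whose error
   scales roughly as density^(−1/2); the density is chosen so that this
   floor (~0.2 mm at 20/mm²) sits below the within-pair asymmetry signal
   being measured, since an HD dominated by sampling gaps would measure
   resolution rather than shape.

6. **Thresholding.** For each tooth type × element, every ordered
   (right of i, mirrored left of j) pair is scored: n symmetric pairs and
   n(n−1) nonsymmetric ones.  The ROC sweeps every distinct observed HD
   as a candidate threshold with "match ⇔ hd ≤ t" (ties positive — tie
   handling is our choice).  The operating point is the **largest
   threshold retaining 100% specificity**, i.e. maximal sensitivity with
   zero false positives on the calibration set; the literal "minimum HD
   at 100% specificity" would be the vacuous threshold 0.  The
   complementary statistic is the smallest threshold giving 100%
   sensitivity (the largest symmetric-pair HD).  Calibration and
   evaluation use the same population, deliberately: the study design
   asks how well thresholds separate the observed pairs, not how they
   generalize.

Supporting statistics: Cohen's kappa with large-sample CI for rater
agreement, and a one-way ANOVA comparing HD values of true-positive,
false-negative and true-negative pairs (degenerate zero-within-variance
input is flagged with p = 0 rather than erroring).

## The synthetic cohort

No scan data are distributed with this package; a seeded generator stands
in for a patient population.  A tooth is a watertight parametric solid in
a local frame (+z long axis, apex at origin, x mesiodistal): a tapered
root blending into a superellipse-section crown with a mid-crown bulge
and incisal taper, the canine additionally carrying a 1.5 mm cusp.  Base
dimensions follow typical maxillary anterior anatomy (e.g. central
incisor: 10.5 mm crown, 13 mm root, 8.4 mm mesiodistal width).  The
gingival margin is a scalloped closed curve at the cervix (amplitude
1.3–1.5 mm, peaks interproximal).

Landmarks are annotated at anatomically corresponding material points —
the apex vertex and the top-ring vertices at the mesial and distal
parametric extremes — so the two sides of an individual carry matched
reference points the way a human annotator would mark the same anatomy
on both teeth (a coordinate-argmax "most prominent point" is unstable
under shape deformation and would corrupt the landmark superimposition).

Shape variation is a smooth low-order radial deformation field — 15
harmonic coefficients (3 angular orders × cos/sin × 3 axial orders),
windowed to vanish at the apex.  Per-individual coefficients are drawn
N(0, σ_pop²) with σ_pop = 0.5 mm; the left tooth is the exact mirror of
the right plus an extra draw with σ_asym = 0.05 mm.  Smooth deformations
were chosen over vertex noise because real bilateral asymmetries are
smooth anatomical differences; HD on white-noise vertices would measure
mesh resolution, not shape.  With these defaults the nonsymmetric HDs and
the calibrated thresholds land in the ~2 mm regime reported for real
anterior teeth, and σ_asym/σ_pop = 0.1 encodes the study's premise that
within-individual asymmetry is small against between-individual
variation.

What the generator does **not** emulate: segmentation and scanning
artifacts, interproximal contact-surface truncation, gingival soft-tissue
variation, correlated shape across tooth types within an individual, and
annotation error in landmarks and margin curves (our landmarks are
exact).  Passing the synthetic study therefore demonstrates correctness
and internal consistency of the measurement pipeline under the stated
asymmetry model — not clinical performance on scans.

## Problem sizes and numerical choices

- The headline synthetic study uses 50 individuals at 32×32 mesh
  resolution (per tooth: ~1 000 vertices), i.e. 50 symmetric + 2 450
  nonsymmetric pairs per tooth type, as the package's standard desk-scale
  configuration; property tests use 24×24 and 3–10 individuals.
- STL reading welds duplicate facet corners at 1e-6 mm.  Grid decimation
  (the "reduce to a 1 mm grid" data-reduction step) is vertex clustering
  with centroid collapse — the displacement bound cell·√3 is asserted.
- Splines through annotated points are periodic cubics with chord-length
  parameterization, then projected to the surface.
- Candidate ICP degeneracies: an empty correspondence set after the cap
  raises; the linearized solve falls back to least squares if the normal
  matrix is singular.
- All randomness (deformation draws, surface sampling, ICP subsampling)
  derives from a single top-level seed via named `SeedSequence`
  substreams; identical configuration + seed reproduces results exactly.

## Known limitations

- Graph geodesics overestimate true geodesic distance (≤ ~2% at the
  default refinement); the offset band is correspondingly biased narrow
  by up to ~0.06 mm.
- The side classification of a curve's two surface regions assigns faces
  the curve touches by neighbour majority; the cut can deviate from the
  annotated polyline by up to one face width (the field's zero set is the
  exact cut that is used).
- Point-set HD underestimates surface HD by up to the sample spacing.
- The constrained ICP solves a nonconvex objective by local linearized
  steps; for motions far outside the constraint set it can in principle
  stop in a local minimum, which the grid-search comparison bounds at the
  5% level in the tested regime.
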