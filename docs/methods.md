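# Methods

## The sorting model

The method rests on one anatomical premise: the femoral head and the
acetabulum of the same hip interlock, so homologous landmarks placed on
the two opposing articular surfaces describe (near-)coincident point sets
in articulated pose. Two bones of one individual therefore share articular
*shape*; bones of different individuals generally do not. Reassociation
reduces to a nearest-neighbour problem in shape space.

Shape is extracted by Procrustes superimposition. For a query acetabulum,
its configuration and all candidate femora are superimposed jointly (one
superimposition per query, repeated for every acetabulum — the per-query
formulation is the default; a single shared superimposition of the whole
assemblage is available as an explicit approximation, `shared_gpa=True`).
Dissimilarity is the Manhattan distance over the 33 Procrustes
coordinates. Manhattan distance is used rather than Euclidean, so that a
single displaced landmark contributes linearly, not quadratically.

### Why scaling is on by default

In raw (unscaled) centred coordinates, two specimens of nearly identical
centroid size are automatically close, whatever their shape — size
dominates the coordinate differences. Scaling both configurations to unit
centroid size removes this confound; the regression test
`test_size_confound_regression` constructs the failure explicitly (a
same-size decoy of clearly different shape outranks the true match
without scaling and loses to it with scaling). The unscaled variant is
retained (`scale=False`) because size can carry signal, but it is not the
default.

### The coordinate frame matters for Manhattan distances

Unlike Euclidean distance, the Manhattan distance is **not** invariant to
a global rotation of the aligned set: rotating all shapes together changes
Σ|Δ| and can even reorder candidates. The superimposition therefore pins
the output frame deterministically: after convergence the whole set is
rotated so the consensus lies on its principal axes. Axis sign is fixed by
requiring the largest-magnitude loading of each of the first two principal
axes to be positive; the third axis is the cross product of the first two,
which keeps the rotation proper (determinant +1) even when the naïve
per-axis sign rule would produce a reflection. With the frame pinned,
distances are reproducible and invariant (to < 1e-8) under any similarity
transform of any raw input.

### Superimposition details

* Iterative GPA: centre, optionally scale to unit centroid size, rotate
  each shape to the running consensus, update the consensus; stop when the
  consensus moves < 1e-10 (root-sum-of-squares) or after 100 sweeps.
  Non-convergence sets a flag instead of raising — repeated digitizations
  of real joint surfaces converge in a handful of sweeps, while clouds of
  mutually unrelated random shapes (which arise only in synthetic stress
  tests) may need a few hundred; `max_iter` is exposed for that case.
* Rotations are restricted to determinant +1 throughout. Chirality is
  handled explicitly upstream: left-side elements are mirrored to the
  right-side convention (x-axis negation) before any comparison, and mixed
  sides in one comparison set raise an error rather than being silently
  absorbed.
* Rim semilandmarks are treated as fixed landmarks. They are digitized
  manually as arc midpoints; no sliding relaxation is modelled.
* For two configurations the GPA fixed point reproduces the ordinary
  (pairwise) Procrustes fit; the suite verifies the residuals agree to
  1e-9, and against a closed-form solution for planar configurations.
  For planar point sets the closed form must include the possibility of
  turning the plane over — a proper 3D rotation acts on in-plane
  coordinates as a 2D reflection — so the optimum is
  √(2 − 2·max(|⟨a, b̄⟩|, |⟨a, b⟩|)) for unit complex vectors a, b.

### Ranking and evaluation conventions

Ties in distance are broken lexicographically by specimen id and logged.
"Accuracy error in individuals" is defined as (rank of the true match − 1),
i.e. the number of false candidates ranked above the true femur; the
blind-test error is the number of queries whose assignment is wrong or
absent. Queries whose true femur is not among the candidates (element
missing from the assemblage) are reported as unmatchable and excluded from
the rates rather than counted as failures of the ranking itself.

The global one-to-one assignment (Hungarian algorithm on the Manhattan
cost matrix from a shared superimposition) is an extension beyond
per-query ranking and is flagged as such in its result. Note that the sum
of per-query first-indication distances is *not* a feasible matching when
two queries share a first indication, so optimality is only guaranteed
against feasible matchings (e.g. greedy assignment without replacement).

## The osteometric filter

`ODA = 4.725 + 1.027·FHD ± 2.54` (all mm) is applied as a symmetric
acceptance band: candidate femur and query acetabulum are compatible when
the observed ODA falls in the closed interval around the point prediction.
Candidates are examined strictly in shape-rank order and the first
compatible one is assigned (not the best-of-compatible); if every top-k
candidate fails, the query is left unassigned — the filter may veto a
correct shape indication, trading recall for protection against confident
wrong matches. Missing measurements yield a tri-state "unknown" that is
treated as compatible with a logged warning, so partially measured
assemblages degrade to shape-only sorting instead of failing.

## Digitization error

Repeatability reports use, per landmark, the mean Euclidean deviation (mm)
of each repeat from the across-repeat mean position, and a percentage
error normalized by the mean centroid size of the repeats; the specimen
figure is the average over the 11 landmarks. Centroid size was chosen as
the normalizer because it is scale-bearing, frame-free, and puts realistic
digitizer noise (a few tenths of a millimetre on a decimetre-scale joint)
in the sub-percent to low-percent range; other published percentage-error
conventions exist, so absolute percentages should not be compared across
normalizers. Repeats from different sessions live in unrelated digitizer
frames and are rigidly superimposed (GPA without scaling, preserving mm)
before deviations are computed; for repeats already recorded in one common
frame, `superimpose=False` computes the direct formula, under which a
single landmark displaced by 1 mm between two repeats yields exactly
0.5 mm deviation at that landmark and zero elsewhere (superimposition
would redistribute part of that offset through the shared centring).

## The synthetic generator

The generator emulates the structure the method assumes, not bone
anatomy. A canonical 11-landmark template (rim points on a 27 mm-radius
circle; fossa/fovea points on a 10 mm inner circle sunk 15 mm along the
pole axis; semilandmarks exactly at arc midpoints) is deformed per
individual by a smooth low-dimensional field — anisotropic axis scaling,
second-order rim ellipticity, rigid fossa-block offset — with coefficients
~ Normal(0, shape_sd). The deformation is applied identically to both
bones of a pair *before* noise, so a pair's Procrustes shape distance is
zero by construction; individuality lives in structured deformation,
noise is the only unstructured term. Size is drawn FHD ~ Normal(44.89,
3.83) mm, the distribution of a typical adult human sample, and both
bones are scaled proportionally; each bone then receives independent iid
per-coordinate Gaussian placement noise (digitization_sd, default 0.5 mm
— the scale of manual digitization error on such surfaces) and an
independent random rigid motion standing in for the digitizer frame.
ODA is generated as 4.725 + 1.027·FHD + Normal(0, oda_residual_sd) with
oda_residual_sd defaulting to 1.27 mm (half the filter's acceptance
half-width), so that ~95.4% of true pairs pass the metric filter and the
rare both-rejected/unassigned outcome can occur in simulation. Optional
switches mark elements as left-sided (coordinates mirrored), drop
elements (per-bone rates available), and add a per-population mean shape
shift (a plain offset, with no claim of anatomical realism).

What the generator does **not** emulate: real articular surface geometry,
cartilage-thickness discrepancies between the bony rims, pathological
lipping, correlated (non-iid) digitization error, and realistic
population-level covariance structure. Passing tests on synthetic data
therefore demonstrate the correctness and internal consistency of the
pipeline — superimposition, distances, ranking, filtering, evaluation —
not the empirical accuracy rates achievable on real skeletal samples,
which depend on how strongly true articular shape is shared within
individuals relative to between-individual variation.

All randomness flows through `numpy.random.default_rng` (PCG64); a fixed
parameter set and seed reproduce an assemblage bit for bit.

## Problem sizes and numerical choices

The test suite and the acceptance script run end-to-end sorting at the
full 97-individual scale for the zero-noise check (seconds on one core)
and use 10-individual assemblages over 20 seeds for noise-degradation and
accuracy summaries — assemblage sizes chosen to mirror small commingled
recovery contexts while keeping Monte-Carlo summaries stable. Degenerate
inputs (coincident or collinear landmark sets) are rejected with explicit
errors before superimposition; validation reports machine-readable issue
codes rather than raising, so defective files can be inspected. Distances
are written with 9 significant digits and rates with one decimal; CSV and
JSON outputs are byte-stable across reruns for fixed inputs.

## Known limitations

* The percentage-error normalizer is a stated convention (centroid size);
  absolute percentages depend on it.
* Per-query joint superimposition costs one GPA per acetabulum (O(n)
  superimpositions of n+1 shapes each); at hundreds of specimens the
  shared-GPA approximation may be preferable and is exposed, but it is an
  approximation, not the default.
* The metric filter assigns the first compatible candidate in shape-rank
  order; with several compatible candidates it never revisits the choice.
* TPS support is read-only (3D LM3 blocks).
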