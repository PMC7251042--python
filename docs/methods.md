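# Methods

`menisize` implements indirect meniscus allograft sizing from 3D surface
models of the ipsilateral tibia plateau, together with the two comparator
methods it is evaluated against (direct 3D meniscus matching and
radiographic Pollard sizing) and a leave-one-out bank-simulation harness.
This note records the models, the numerical choices, and what the
synthetic cohort does and does not emulate.

## The sizing problem

After total meniscectomy no meniscus remains to measure, so an allograft
must be chosen indirectly. The working assumption is that of an imprint:
two knees with very similar tibia plateaus carry very similarly shaped
menisci. A recipient's plateau (from CT) is therefore compared against
the plateaus of every specimen in a tissue bank, and the meniscus
attached to the most similar plateau is the proposed graft. The package
evaluates this selector against (a) the best-available graft — the bank
meniscus with the lowest surface distance to the recipient's own
meniscus, only computable in a simulation where that meniscus is known —
and (b) the radiographic standard, where meniscus width is read off the
AP view and meniscus length is the lateral-view plateau depth scaled by
0.8 (medial) or 0.7 (lateral).

## Similarity score

All 3D matching uses one primitive (`registration.match_score`): the
candidate surface is rigidly superimposed on the query surface by ICP,
then `n` area-uniform sample points on each mesh are projected to the
exact closest point on the other mesh's triangles (point-to-triangle,
never point-to-vertex). The mean of those closest-point distances is the
MeSD and the maximum the MaSD, per direction; the combined MeSD and MaSD
take the direction-wise maximum (the Hausdorff convention), and the
directional values are retained on the result. Selectors rank by
combined MeSD with MaSD as tie-break, then lexicographic id.

ICP details: initialization is centroid alignment composed with each of
a small set of multistart rotations (default: identity and ±30° about
the proximal axis). Each start runs cheap point-to-point iterations
against a cached dense sampling of the target surface (15 000 points);
the best start is then refined with exact point-to-surface
correspondences and linearized point-to-plane pose updates, which remove
the tangential-slide error modes that point-to-point updates leave
behind. Iterations stop when the relative MSE change falls below
`rel_tolerance` (default 1e-8) or the pose increment is numerically
zero; `max_iterations` defaults to 200. With these defaults a synthetic
proximal tibia perturbed by up to 20° and 10 mm is recovered to well
under 0.5° and 0.1 mm.

The nearest-surface query is a compiled exhaustive scan with a
centroid-plus-bounding-radius prune, so it is exact for every input,
including the sliver triangles that plane cuts produce. It is verified
against an independently formulated brute-force closest-point oracle to
1e-9 mm.

Sampling defaults: 5000 points for stand-alone surface-distance calls
(discretization error well under 0.05 mm on structures of a few
centimetres); 800 points inside `IcpParams` for matching. The
leave-one-out drivers in the test-suite and the acceptance script use
300–400 points per mesh — chosen so full bank simulations run on a
single CPU; the planted-twin and transform-recovery checks pass
unchanged at these sizes. Per-pair sampling seeds are derived
deterministically from the specimen ids, so repeated runs are
bit-stable and an independently re-scored candidate reproduces the
selector's number exactly.

Note one asymmetry: registering A onto B and B onto A give almost
identical scores on closed surfaces (<2% observed), but open plateau
cuts can differ by ~10% because the one-directional ICP optimum depends
on which mesh contributes the sample points near the open boundary. The
selectors always register candidate-onto-query, so rankings are
consistent within a bank run.

## Standardized plateau cuts

Every tibia is first superimposed on an average right tibia template
(3.5 cm proximal segment) by ICP; left-sided specimens are mirrored to
right-sided ones at ingestion. The template carries fixed cutting
planes: an axial plane 10 mm distal to the plateau level (the most
proximal point of the template) and sagittal planes perpendicular to it
— one through the plateau center and one through each intercondylar
tubercle. Three configurations are cut from the aligned bone, all open
along the cut (no capping):

* **entire** — everything proximal of the axial plane;
* **half with eminence** — one compartment, split at the central
  sagittal plane (includes its half of the intercondylar area);
* **half without eminence** — one compartment, split at that side's
  tubercle plane (excludes the intercondylar area).

The planes are fixed in the template frame and are *not* adapted to the
individual: a large plateau keeps some intercondylar bone and a small
one loses some peripheral bone. This is deliberate — it is the
standardized, operator-free procedure being evaluated — and it is the
dominant noise source in plateau-based rankings: the per-specimen
alignment offset (typically 0.3–1 mm of residual MeSD against the
template) moves the cut relative to the anatomy.

Because the template is procedural and deterministic, it is rebuilt
bit-identically on demand rather than shipped as a mesh file;
`save_template`/`load_template` serialize it when a file is needed.

## Oriented-bounding-box morphometry

Meniscus width/length/height are box extents. The height axis is the
minimal-extent direction of the model points, computed as the smallest
principal axis of the vertex cloud refined by a 0.5°-step grid search
about the two in-plane principal axes (every step is rigid-equivariant,
so measurements are exactly invariant under rigid motion — an exact
minimum-volume box is unnecessary because the in-plane orientation is
overridden anyway). The box is then rotated about the height axis until
its length axis is parallel to the anterior–posterior root chord
(root landmarks are inputs, not detected), and the three extents are
re-measured so the box encloses every vertex. For a box-shaped mesh the
procedure is exact to 1e-9 mm.

## Leave-one-out validation and statistics

Each specimen in turn is the recipient; the remaining `n−1` form the
bank, giving `n·(n−1)` ordered scoring evaluations per method and
compartment (2450 at the study scale of 50), which the driver asserts.
The selected meniscus is registered back onto the original and compared
by MeSD, MaSD and absolute width/length/height differences (signed
values are stored alongside). A couple is an outlier above >5 mm width,
>5 mm length, >4 mm height or >5 mm MaSD (strict inequalities, counted
once per exceeded category; `total` counts couples exceeding any). The
evaluation reuses the same per-pair seeds as the direct selector, so the
direct 3D meniscus selection is per-query at least as good as any other
method's on this metric, by construction.

Method comparisons: one-way repeated-measures ANOVA with
Greenhouse–Geisser correction (epsilon from the doubly-centered
condition covariance; textbook sums-of-squares implementation,
cross-checked against pingouin to 1e-8), paired t-tests, the classic
mean-centered Levene test (median-centered Brown–Forsythe via the
`center` option), and the variance-ratio F test with two-sided p. Each
result reports `alpha / m_comparisons`; the default six pairwise
comparisons give 0.0083 at the family-wise 0.05 level. The number of
comparisons is explicit configuration. Identical pairings make the
paired t degenerate and are flagged rather than reported as p = 1.

## Synthetic cohort

No patient scans ship with the package; the generator produces cohorts
whose *measured* properties drive every test.

* **Dimensions.** Per-compartment meniscus width/length/height are
  Gaussian with the cohort statistics: medial 31.9 (SD 3.14) / 46.4
  (SD 3.01) / 8.9 (SD 1.51) mm, lateral 32.0 (SD 3.52) / 35.3 (SD 3.01)
  / 9.7 (SD 1.37) mm, truncated at ±3 SD. Within a compartment the
  three dimensions share 80% of their variance through a common size
  factor; across compartments the size factors mix a shared knee factor
  with independent draws via `compartment_independence` (default 0.5 —
  the compartments correlate only moderately).
* **Plateau coupling.** Per dimension, the plateau value is
  `rho·meniscus + (1−rho)·independent draw`; compartment width maps to
  plateau half-width and length to plateau AP depth through the
  0.8/0.7 radiographic factors, so at `rho = 1` with zero measurement
  noise the Pollard conversion recovers the true meniscus dimensions
  exactly. `rho` defaults to 0.8; no measured plateau–meniscus
  correlation exists to calibrate it against, so it is a simulation
  parameter, not an estimate.
* **Geometry.** A meniscus is a wedge cross-section (tall peripheral
  rim, thin inner edge, flat bottom, and a flat top band parallel to
  the bottom so the shape's minimal-extent direction is exactly the
  construction height axis) swept along a C-shaped elliptical arc —
  240° medial, 290° lateral — then rescaled per axis so the construction
  extents equal the drawn dimensions exactly. The tibia is a tapered
  extrusion with two shallow condylar dishes and an intercondylar ridge
  between the tubercle planes, topped by two tubercle spines; the
  eminence's height, extent and tubercle geometry vary independently of
  the compartment sizes (scaled by `eminence_variation`; the eminence
  carries ligament insertions, not meniscus-size information). Meshes
  are watertight before posing: ~2 300 faces per meniscus and ~5 800
  per tibia, which keeps surface-sampling discretization error well
  below the 0.2 mm at which generated dimensions are verified.
* **Nuisance processes.** A smooth low-frequency displacement field
  (`shape_noise_sd`, default 0.2 mm) deforms each specimen coherently;
  radiographic measurements add Gaussian noise (`rx_noise_sd`, default
  1 mm, two-reader averaging scale); each specimen gets a random rigid
  pose (≤25°, ≤20 mm — scan pose variability) and 36% are emitted as
  left knees.

What the generator does **not** emulate: real segmentation artefacts
(slice thickness, wrapping), osteophytes or other pathology, root
geometry beyond two landmark points, and any statistical shape detail
beyond the parametric families above. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the
method's qualitative behaviour (eminence exclusion helps; stronger
plateau–meniscus coupling helps) emerges under controlled conditions —
not that the quantitative accuracy on real patients is reproduced.

## Problem sizes and determinism

Bank-simulation experiments in the test-suite use cohorts of 12–20
specimens with 10 seed replicates, and the acceptance script uses 12
(selection at 300 sample points per mesh, preparation at 400) — sizes
chosen so the complete suites run on one CPU. All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; identical
inputs give byte-identical selections and rankings.

## Known limitations

* Scores between open cut surfaces include the cut-boundary
  contribution symmetrically for all specimens; cuts are not capped.
* The ICP basin of attraction is finite; poses beyond roughly 30–40°
  of the multistart coverage can converge to local optima. The
  ingestion path aligns everything to the template first, so downstream
  registrations start near-aligned.
* The plateau-based ranking inherits alignment-offset noise from the
  fixed template-frame cuts (see above); at realistic cohort sizes this
  compresses the differences between cut configurations relative to
  what larger real cohorts show.
* The radiographic selector compares recipient Pollard dimensions
  against 3D-measured bank dimensions, mirroring the validation design;
  a production bank would list its own graft measurements.
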