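# Methods

This note documents the models, parameter defaults, numerical choices and
limitations of `brainplane`. It is the package's own account of its
procedures; every empirical number quoted here is computed by the test
suite or by `scripts/acceptance.py`.

## Coordinate conventions

* AP coordinates are millimetres from bregma, positive anterior. Stacks are
  assumed acquired anterior first, so AP is strictly decreasing in plane
  index.
* Mask and image pixels are 0-based, row = y (downward), column = x
  (rightward). Physical units are micrometres; `pixel_size_um` converts
  in-plane, `z_step_um` axially.
* Atlas label masks reserve 0 for "outside tissue". Cells landing there,
  out of mask bounds, or farther in AP from every registered plate than the
  cutoff are reported under a synthetic `unassigned` region rather than
  dropped, so counts always conserve.

## AP alignment

The z ↔ AP map is piecewise linear between anchors. Both stack endpoints
must be anchored (manual AP assignment) before interpolation is allowed.

**Choice game.** The initial middle plane is the one whose interpolated AP
— from the *current* map, i.e. all anchors pinned so far, not only the
endpoints — is nearest the reference plate's AP; later anchors can only
improve the initial guess, so the search starts closer. Each cycle presents
(middle − s, middle, middle + s) at the current schedule step s, clamped to
the stack; a collapsed duplicate candidate counts as the middle. A side
choice recentres the middle with the step unchanged; choosing the middle
advances to the next smaller step; the middle at the final step terminates.
The default schedule is (200, 100, 30, 10) planes. The chosen plane is
anchored at exactly the reference AP — matching a plane to a plate *defines*
its AP. A choice that could not be anchored without breaking AP
monotonicity is rejected and the chooser re-prompted; a chooser that
insists raises an error.

With a truthful chooser the game terminates with the middle within half the
finest step of the plane truly nearest the reference AP, hence within the
finest step (10 planes) of the true plane. A bound of
n_planes/s₀ + len(schedule) chooser calls holds at whole-brain scale
(n_planes ≫ s₀, interpolation-based initial guess); on very short stacks
the per-level recentring moves can exceed it, which is why the call-bound
test runs at realistic scale while the landing-accuracy test runs at every
scale.

**Midpoint check.** One pass audits the midpoint of every inter-anchor
interval present at entry; a rejected midpoint triggers a choice game at
its interpolated AP, inserting a new anchor. `refine_alignment` repeats
passes until no anchor is added. The oracle's accept tolerance defaults to
25 μm = finest step × z-step (10 × 2.5 μm), i.e. the resolution the choice
game itself can deliver; a human player is the analogous judge of "looks
aligned".

**Diagnostics.** For the interval between consecutive anchors,
morph ratio = (Δz/|ΔAP|) / (Z_total/|AP_total|), the local planes-per-mm
slope normalised by the endpoint-to-endpoint average. The |ΔAP|-weighted
mean of the ratios is identically 1 (an algebraic identity, verified to
1e-9 over random anchor sets). `linear_prediction_error` reports
(all-anchor interpolation − endpoint-only interpolation) × 1000 μm per
plane; a plane truly more posterior than its linear prediction has negative
error.

## Plate registration

**Warp family.** Thin-plate splines with an affine part, solved from the
standard kernel system (U(r) = r² log r, block matrix [[K + λI, P], [Pᵀ, 0]]).
λ = 0 (the default) interpolates: control residuals are at numerical noise
(the acceptance script measures ~1e-10 px). Increasing λ trades control
fidelity for lower bending energy. The implementation is cross-checked in
the test suite against an independent thin-plate RBF interpolator. Forward
(image→plate) and inverse (plate→image) transforms are fitted independently
by swapping source and target rather than numerically inverting one spline;
round-trip error inside the control hull is a diagnostic, not an identity.
Degenerate control sets (fewer than 4 pairs, collinear or duplicated
points) are rejected before solving.

**Automatic correspondences.** The tissue mask is Otsu's threshold on
log-intensity, holes filled, largest connected component kept. Its boundary
is smoothed with a short circular moving average before equal-arc-length
resampling — the raw marching-squares polyline is a staircase whose arc
length is locally inflated, which would otherwise skew the sampling by a
pixel or two. Both the image contour and the plate outline are oriented
clockwise (as displayed) and start at the *dorsal point*, defined as the
intersection of the upward vertical ray from the contour centroid with the
polygon. This definition is sub-vertex exact and stable under rasterisation,
unlike "minimum-y vertex", which is ambiguous on a locally flat dorsal
boundary and was observed to rotate the pairing by several pixels. The
default of 32 contour points is a compromise between boundary fidelity and
the editing burden on the user.

**Loop.** Plates are registered one at a time: plane selection by inverse
interpolation of the alignment map, automatic seeding, corrector edits
(with single-step undo backed by a history stack), fit, save. Saved plates
are skipped on resume unless overwriting is requested; an aborting
corrector skips the plate; a singular fit re-prompts up to 3 times. Warp
files are plain text (pairs + λ); coefficients are re-solved on load, which
is deterministic, so a reloaded warp transforms identically.

## Segmentation and duplicate cleanup

Per plane: difference-of-Gaussians band-pass (defaults 3 μm / 9 μm),
absolute threshold on the filtered response (default 100, ~20× the filtered
noise level of the default phantom; a quantile mode exists for stacks with
drifting background), 8-connected components, area filter (15–1000 μm²),
intensity-weighted centroid and peak raw intensity per object. A filter
scale below one pixel is rejected rather than silently aliased.

Cleanup links two detections iff in-plane centroid distance ≤ `xy_thresh_um`
**and** axial separation |Δz|·z_step ≤ `z_thresh_um`, then takes connected
components, so a soma smeared across many planes merges even when its
extreme planes exceed the axial threshold (transitive closure — the
documented reading of "erase duplicates across other images"). Each
component becomes one cell at its maximum-peak-intensity member; equal
peaks resolve to the lower plane index for determinism. Defaults
xy = 10 μm, z = 7.5 μm (three 2.5 μm planes) suit nuclear labels ~10 μm
across imaged at 2.5 μm z-step; they are package choices, not reproductions
of published values. Candidate pairs come from a KD-tree on the in-plane
coordinates filtered by the axial rule — never an all-pairs scan — and the
result is verified exactly equal to a brute-force all-pairs oracle on
random instances up to 2,000 detections.

## Mapping and counting

Forward warping uses the single warp of the registered plate nearest in AP
(exact ties, to floating-point tolerance, resolve to the more anterior
plate); blending warps of neighbouring plates is future work. Cells farther
than the AP cutoff (default: half the largest inter-plate gap) are flagged
unmapped. Region assignment reads the label under the warped position at
the nearest pixel.

The count table reports, per ontology node, the direct count, the rolled
count (direct + all descendants), and percent = rolled/total × 100 where
the denominator is **all** cells including unassigned — with that choice
the table always conserves the input count and the unassigned row is
visible; users preferring assigned-only percentages can renormalise from
the same columns. The root's percentage is 100 exactly when every cell is
assigned. The sunburst export stores direct counts as node values, so any
subtree sums to that node's rolled count.

## The phantom

The generator emulates exactly the structural features the pipeline relies
on, at desk scale:

* **Morph**: a linear AP ramp plus a Gaussian bump (amplitude in mm, centre
  and width as stack fractions), ramp-corrected to meet the endpoint APs
  exactly and validated strictly monotone. Random draws reject
  non-monotone parameter combinations.
* **Atlas**: a fixed 7-region ontology (root, two mid-level bands, four
  leaf discs nested inside them) rendered at 5 plates whose band split and
  disc radii drift from plate to plate, inside a constant elliptical
  tissue outline.
* **Cells**: 3D Gaussian blobs (σ_xy = 5 μm, σ_z = 4 μm, amplitude 2000 on
  a tissue background of 200 with noise σ = 20, 16-bit), each visible on
  several adjacent 2.5 μm planes — the duplicate-generation mechanism.
  Placement is uniform within regions eroded by 4 px, at least 25 μm in AP
  from inter-plate bin midlines (so each cell's ground-truth nearest plate
  is well defined), with pairwise separation of ≥ 40 μm in-plane or
  ≥ 30 μm axially so that individual recovery is in principle possible.
  Ground-truth regions are looked up from the nearest plate's mask, not
  assumed from the sampling.
* **Scale**: the default stack is 300 planes of 256×256 px at 2.5 μm
  pixels and 2.5 μm z-step (0.75 mm of AP), so the full suite runs in
  seconds. Alignment-only studies (which need no pixel data) use
  whole-brain-scale morphs: 2560 planes spanning +2.2 to −4.2 mm, where
  the 25 μm recovery bound and bump amplitudes up to 0.3 mm are both
  meaningful; on the short default stack the same bump amplitude would
  violate monotonicity.

What the phantom does **not** model: optical PSF anisotropy and depth
attenuation, staining gradients, intensity variation across planes,
non-elliptical or plate-dependent tissue outlines (so registration is
near-identity by construction), anatomically realistic region geometry,
and imaging artefacts. Passing the end-to-end tests therefore demonstrates
the pipeline's internal consistency — alignment, registration,
segmentation, cleanup, warping and counting compose correctly and recover
known truth — not segmentation or registration robustness on real tissue,
where filter parameters and human corrections carry the load.

## Degenerate inputs and tie-breaks

* Duplicate or non-monotone anchors are rejected at insertion; identical
  re-insertion of an existing anchor is a no-op.
* Equal-distance plate lookups resolve anterior, both in `nearest_plate`
  and in forward warping (the latter with a 1e-9 mm tolerance for
  interpolation round-off).
* Truthful-oracle distance ties resolve to the middle candidate.
* Empty inputs flow through: empty stacks segment to empty tables, empty
  detection sets clean to empty cell sets, empty cell sets count to a
  zero table that still validates.

## Checkpoints and resumability

Every stage writes human-readable checkpoints (CSV tables, YAML config,
plain-text warps) under a fixed seven-directory layout. Loading
distinguishes "never run" from "corrupt file". Segmentation appends
per-plane results as it goes and resumes from the first unfinished plane,
yielding a result identical to an uninterrupted run; registration skips
already-saved plates.
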