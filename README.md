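# brainplane

Semi-manual mapping of coronal image stacks onto a reference brain atlas:
anchor-based anterior–posterior (AP) alignment, correspondence-point plate
registration, 2.5D cell segmentation with duplicate consolidation, forward
warping into atlas space, and hierarchical region counting.

## Who this is for

Light-sheet microscopy of cleared mouse brains produces stacks of thousands
of coronal planes in which immediate-early-gene labelling (e.g. Fos) marks
recently active neurons. Turning such a stack into per-region cell counts
requires registering every plane to a reference atlas. Fully automated
voxel-based registration needs heavy compute and fails on damaged or partial
brains; `brainplane` instead follows the semi-manual philosophy: a human (or
a programmatic oracle, for testing) makes a small number of easy visual
judgements, and the package interpolates, registers, segments and counts
around them. Whole brains, partial brains, and single user-chosen planes all
work the same way.

## The method

**AP alignment (the choice game).** Tissue clearing deforms the brain
nonuniformly along the AP axis, so plane index is not linearly related to
atlas AP coordinate. The first and last planes are assigned AP coordinates
by hand; each internal reference plate (seven bundled defaults spanning
+1.91 mm to −3.96 mm from bregma, each with landmark cues) is then matched
to a plane by a coarse-to-fine ternary search: the current guess is shown
with a further-anterior and a further-posterior candidate at plane offsets
200, 100, 30, 10; picking a side recentres the guess, picking the middle
refines the offset. Anchored planes define a piecewise-linear z ↔ AP map;
a *midpoint check* audits each interval and inserts extra anchors where
interpolation is judged off. Diagnostics report the normalised morph ratio
per interval (local planes-per-mm over the whole-stack average) and the
error a naive two-endpoint linear assignment would make.

**Plate registration.** For each registered plate, correspondence points are
seeded automatically by sampling the image's tissue boundary and the plate
outline at equal arc length from the dorsal point, clockwise; the user may
add/move/delete pairs with single-step undo. A thin-plate-spline pair
(image→plate and plate→image, fitted independently) interpolates the control
points exactly at regularization 0.

**2.5D segmentation and cleanup.** Each plane is segmented independently
(difference-of-Gaussians band-pass, threshold, connected components, area
filter). Because a soma spans several adjacent planes, detections whose
in-plane distance and axial separation both fall below thresholds are linked
transitively; each connected group becomes one cell at its brightest member.

**Mapping and counting.** Each cell gets its AP from the alignment map, is
warped through its nearest registered plate, and receives the region label
under its warped position. Counts aggregate over the region ontology tree:
direct counts, rolled-up counts (including descendants), percentages, and a
d3-style sunburst JSON.

**Phantoms.** `brainplane.phantom` generates synthetic datasets with the
exact structure the pipeline assumes — a monotone nonlinear z→AP morph,
a miniature nested-region atlas, cells rendered as 3D Gaussian blobs that
appear on several adjacent planes, background noise — plus ground truth and
a truthful oracle that plays the choice game, so the whole pipeline is
testable without any external data.

## Worked example

Generate a phantom and run the whole pipeline with the truthful oracle
standing in for the human:

```sh
brainplane phantom --out demo --seed 1
# phantom: 300 planes, 60 cells, 5 plates -> demo/config.yaml
brainplane run --config demo/config.yaml --mode oracle
```

`demo/analysis/tables/region_counts.csv` then holds the hierarchical count
table:

```
 region_id    acronym                      name  direct_count  rolled_count    percent
         1      BRAIN               whole brain             0            60 100.000000
         3        SUB          subcortical band            11            31  51.666667
         2        CTX             cortical band             8            29  48.333333
         6        ACB       accumbens-like disc            11            11  18.333333
         4         PL       prelimbic-like disc            11            11  18.333333
         5         IL     infralimbic-like disc            10            10  16.666667
         7         TH        thalamus-like disc             9             9  15.000000
         0 unassigned outside tissue / unmapped             0             0   0.000000
```

All 60 planted cells are recovered (none double-counted despite each being
segmented on several adjacent planes) and every rolled count equals its
direct count plus its children's rolled counts. The recovered morph profile
(`demo/analysis/alignment/morph_profile.csv`) shows the phantom's simulated
nonuniform deformation — ratios above 1 where tissue is stretched along AP,
below 1 where compressed:

```
 ap_start_mm  ap_end_mm  morph_ratio
       0.400      0.275     1.204013
       0.275      0.150     1.364548
       0.150      0.025     0.862876
       ...
```

For real data, start from `brainplane init --images DIR --out DIR` and run
the `align` and `register` stages with `--mode console`, which saves
side-by-side preview images under `figures/` and prompts on the terminal.
An atlas bundle is a directory of `ontology.csv`, `plates.csv`, one integer
label mask TIFF per plate and outline CSVs — the synthetic bundle written by
`brainplane phantom` is the canonical example of the format.

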