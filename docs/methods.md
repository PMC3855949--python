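# Methods

## The problem and the model

Contrast-enhanced coronary CT angiography shows the vessel lumen as bright
(contrast-filled, typically > 160 HU) but gives no direct delineation of the
vessel wall, where noncalcified plaque (NCP) — the low-attenuation,
lipid-associated, rupture-prone component — actually sits.  This package
models the wall *constructively*: instead of tracing wall borders, it builds
the wall as a stack of one-voxel-thick morphological shells around the
segmented lumen and reads plaque off the attenuation statistics of those
shells.

The pipeline:

1. **Lumen segmentation.** A voxel is lumen if its attenuation is *strictly*
   greater than 160 HU.  The thresholded mask is refined by region growing:
   the connected component of a seed voxel (26-connectivity by default,
   because coronaries run obliquely through axial slices) with enclosed
   cavities filled (6-connectivity on the background complement, the standard
   dual pairing that prevents diagonal leaks).  The default seed is the
   maximum-HU voxel — in contrast CTA the brightest voxel sits in or near the
   aortic root, which is connected to the coronary ostia.  Multiplying the
   binary mask into the original volume gives the coronary tree model (CTM):
   original HU inside the lumen, 0 outside.

2. **Voxel-Map.** Iterated binary dilation/erosion of the lumen mask `A`
   with a structuring element `B` yields one-voxel-thick shells:
   `shell(+k) = dilate^k(A) \ dilate^(k-1)(A)` and
   `shell(-k) = erode^(k-1)(A) \ erode^k(A)`.  With the default face-connected
   (6-neighbour) element, `shell(+k)` is exactly the set of background voxels
   at city-block distance `k` from the lumen (chessboard distance for the
   26-neighbour element) — this equivalence is used as an independent test
   oracle via `scipy.ndimage.distance_transform_cdt`.  Defaults are three
   outward shells and one inward shell, i.e. the layer labels
   {-1, 1, 2, 3}: beyond the third dilation the shells ordinarily cross the
   outer wall border into tissue at or below 0 HU, so larger `n_out` warns.

3. **Wall model (CAWM).** The *original* volume (not the lumen-masked CTM —
   wall voxels are outside the lumen by construction) restricted to the
   shells.  Shell voxels below 0 HU are epicardial fat: clamped to 0 HU and
   flagged; they remain in the model (and in layer means, as 0) but are never
   plaque candidates.  Off-shell voxels are excluded (0).

4. **Severity levels.** Wall attenuation is binned into six contiguous
   levels covering [0, ∞): 0–49, 50–99, 100–199 (NCP severities 1–3) and
   200–299, 300–399, ≥ 400 (calcified-plaque severities 4–6).  Bin edges are
   half-open: 49 → 1, 50 → 2, …, 400 → 6.

5. **Plaque detection.** On a healthy wall the mean attenuation decreases
   outward, layer by layer, and each layer is dominated by one level
   (+1 → level 3, +2 → level 2, +3 → level 1 — the default *baseline*).  An
   NCP candidate is a non-fat wall voxel whose level **exceeds** its layer's
   baseline while staying ≤ 3.  Candidates are grouped into 26-connected
   components; components smaller than `min_voxels` (default 4) are dropped
   as noise.  Levels 4–6 are tallied as calcified plaque in the report but
   never form NCP components.  *This candidate rule is this package's
   operationalization of the qualitative idea of "layer outliers"; one
   consequence is that a detected component can never contain level-1 voxels
   (level 1 exceeds no baseline).*

6. **Volumetry.** Per level: volume = voxel count × (dx·dy·dz); percent =
   level volume / plaque volume × 100, rounded half-up to two decimals, so
   nonzero-level percents sum to 100.00 within 0.01.  Worked check: level
   volumes 0.9834 mm³ and 1.9703 mm³ give 33.29 % and 66.71 %.

7. **Centerline tree.** The lumen is thinned to a one-voxel skeleton
   (3D topological thinning, `skimage.morphology.skeletonize`).  Skeleton
   voxels form a graph under 26-adjacency with Euclidean mm edge weights;
   loops (imaging/thinning artifacts) are broken by dropping the longest
   edge of each cycle — computed as the minimum spanning tree, which is
   exactly that rule (Kruskal's cycle property) — with a warning.  Segments
   split at branch voxels (≥ 3 skeleton neighbours); the root is the segment
   containing the minimum-z point in world coordinates (ties: min y, then
   min x).  Per-point radius is the anisotropy-aware Euclidean distance to
   the nearest background voxel centre.  Anatomical names are **input** (a
   radiologist's knowledge, not inferred): a label map keyed by segment id
   or branch-order path (`root/0/1`), validated against a packaged 17-name
   AHA-style vocabulary; unlabeled descendants inherit the nearest labeled
   ancestor's name + `-sub`.

8. **Localization.** Each plaque voxel votes for the label of its nearest
   (Euclidean, mm) centerline point; the plaque label is the majority, ties
   resolved toward the segment closer to the root.  Vote counts are kept on
   the plaque for audit.  This is a concrete, deterministic form of
   "intersect plaque coordinates with the labeled centerline through the
   lumen segmentation", which is under-specified for wall voxels that by
   construction lie outside the lumen.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `threshold_hu` | 160 (strict >) | HU | lumen/wall attenuation cutoff; boundary value is background |
| grow connectivity | 26 | – | oblique vessels stay connected across slices |
| shell connectivity | 6 | – | shells = city-block distance bands; 26 optional |
| `n_out` / `n_in` | 3 / 1 | shells | the {-1,1,2,3} layering; >3 crosses the outer border (warns) |
| baseline | {+1:3, +2:2, +3:1} | level/layer | healthy outward gradient |
| `min_voxels` | 4 | voxels | suppress single-voxel noise components |
| percent rounding | half-up, 2 decimals | % | reporting precision |

Morphology runs in index space; with anisotropic spacing the physical shell
thickness differs per axis (recorded in volume metadata, never resampled).
Whether to run shells slice-wise 2D vs fully 3D is not dictated by the
method; 3D is the default here and the structuring element is configurable.

## The phantom: what it emulates, what it does not

`voxelmap.phantom` rasterizes a branching tube tree (straight branches,
explicit radii, parent links) on a configurable grid (default 128³ at 0.5 mm
isotropic):

- lumen HU falls linearly with arc length from 450 HU at the root to 250 HU
  at the farthest tip — bright near the aortic end, dimmer distally, always
  safely above threshold (at sd 10 noise the distal margin is 9σ);
- wall shells are stamped at 140 / 75 / 25 HU for layers +1/+2/+3 — each
  layer dominated by its baseline level (3, 2, 1), strictly decreasing
  outward;
- background is epicardial fat at −80 HU;
- plaques are spheres intersected with one wall layer, offset outward
  perpendicular to the branch (away from the parent vessel), stamped at a
  stated HU; the default fixture carries one 120 HU (level 3) insert of 39
  voxels on layer +2 of the RMA branch;
- optional Gaussian noise (one `numpy` generator seeded from the spec,
  rounded to integer HU) is added to the whole volume.

Ground truth (exact lumen mask, per-branch axis polylines, exact plaque
voxel sets and levels) is returned alongside, so tests compare pipeline
output to truth set-for-set.  `label_map_from_truth` builds the anatomical
label map from truth geometry — it stands in for the manual labeling step,
not for automatic anatomical naming.

What the phantom deliberately lacks: cardiac motion, beam hardening,
scanner PSF / partial-volume blur, tortuosity, tapering lumina, and real
plaque texture.  Passing tests therefore demonstrate the *algorithmic*
contracts (shell algebra, recovery, localization, volumetry), not clinical
accuracy on patient scans.

## Numerical and degenerate-case choices

- Erosion treats the grid border as background; the distance-band test
  oracle pads by one zero voxel so both sides agree on border-touching masks.
- `threshold_lumen` may legally return an empty mask; `region_grow` on a
  background seed fails with a hint to pick a lumen voxel (e.g. the
  highest-HU voxel).
- Root-selection ties (equal world z) break by y then x; child segments are
  ordered deterministically by their far endpoint, so branch-order path keys
  are stable across re-runs.
- A 50/50 localization tie goes to the segment nearer the root.
- OBJ surfaces are marching-cubes iso-surfaces at 0.5 on a one-voxel zero
  pad: always watertight, outward-wound (positive enclosed volume).
- All randomness flows through explicit seeds; the pipeline itself is fully
  deterministic (re-running from an emitted resolved config reproduces
  reports byte-for-byte).

## Known limitations

- Under sd-10 noise a mis-segmented single cap voxel can occasionally
  (≈ 0.2 % of slices in a 20-run ensemble) create a one-voxel layer cell
  that inverts the per-slice layer-mean gradient; the ensemble statistics
  are unaffected.  Noisy plaque-volume recovery is an ensemble property:
  mean |error| ≈ 5 % for the 39-voxel default insert, with individual runs
  occasionally reaching ~13 %.
- The detection rule cannot flag level-1 outliers (nothing is below baseline
  level 1), and hypo-attenuating outliers (level *below* baseline) are not
  searched for.
- No sub-voxel wall thickness, no partial-volume correction, no stenosis
  grading, no calcified-plaque analysis beyond tallying.
- Left/right coronary trees need separate seeds (one seeded component per
  run); the aorta is excluded only by seed choice, not modelled.

Problem sizes used in the shipped tests and acceptance script: 128³
noise-free recovery, 72³ × 20 seeds for the noisy ensemble, 16³ × 50 masks
for the shell-oracle equivalence — the full suite runs in well under a
minute on one CPU.
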