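# Methods

This note documents the models, algorithms and numerical choices behind
`golgitrace`, in the spirit of a methods appendix: what is computed, under
which assumptions, which knobs matter, and what the synthetic validation
does and does not establish.

## Image model and conventions

Volumes are slice-major `(z, y, x)` grids with physical voxel spacing
`(dz, dy, dx)` in μm; 8- or 16-bit unsigned intensities; signal assumed
brighter than background (an invert flag covers the opposite polarity).
Physical coordinates are voxel centres, `x = ix·dx` etc., with the origin
at index `(0, 0, 0)`; SWC files store physical μm in the standard
`x y z` column order. All lengths, volumes and radii are physical, which
is what makes the anisotropic fluorescence-tomography case (2.5 μm slice
pitch vs 1 μm in-plane) behave correctly in every metric computation.

16→8-bit conversion is linear with half-up rounding; the default maps the
global min/max onto 0/255 (a constant volume maps to all-zero — a
deterministic signal of "no contrast"), and a fixed-range mode exists for
reproducibility across volumes.

## Extraction

Denoising is a single global threshold *T*. The package deliberately does
not auto-select *T*: the trade-off between background suppression and loss
of faint neurites is a judgement call, so `evaluate_thresholds` reports
objective proxies (foreground fraction, component count, largest component
volume) for a candidate list and leaves the choice to the operator. Two
presets encode working points for the two supported regimes: `fmost`
(T = 220 on 8-bit data) and `microct` (T = 40).

Foreground connectivity is 26 (preserves thin diagonal neurites; background
is implicitly 6-connected — the standard digital-topology pairing).
Components whose physical volume is strictly below 1000 μm³ are removed;
the floor is expressed in μm³ so the same rule covers both voxel sizes
(400 voxels at 2.5 μm³/voxel, 3642 at 0.65³ μm³/voxel). A real soma alone
exceeds this floor, so the target neuron always survives. The soma seed
snaps to the nearest foreground voxel within 5 μm (manual clicks rarely
land on the medial axis; the bound prevents jumping to a different
neuron), ties broken to the smallest `(z, y, x)` index. Eraser markers
(spheres/boxes) remove voxels whose centres fall inside; they can only
shrink the mask.

## Gap repair

Staining discontinuities come in two classes: an interruption inside an
otherwise labelled branch, and a branch whose signal is missing distal to
a point. Both are repaired identically: from a manually marked terminus, a
minimal-cost path is traced to the nearest voxel of the soma-connected
structure and rasterised into the mask as a tube.

* **Cost.** `c(v) = exp(λ(1 − I/I_max)^γ)`, λ = 10, γ = 2 by default:
  bright voxels cost ~1 per μm, pure background `e^10 ≈ 2.2·10⁴` per μm.
  λ sets how strongly the trace prefers signal over shortcuts; γ shapes
  the transition (γ = 2 keeps moderately dim voxels cheap, so faint
  sub-threshold remnants inside a gap still guide the trace — the reason
  tracing runs on the *raw* volume, not the thresholded one).
* **Search.** Dijkstra on the 26-neighbour graph, edge weight = physical
  step length × mean endpoint cost. Equal-cost relaxations prefer the
  smaller lexicographic `(z, y, x)` parent, so paths are deterministic.
  Traces abort when accumulated cost exceeds
  `e^λ · 10 · straight-line distance` (prevents runaway searches across
  background); a failed trace is recorded per terminal and does not void
  the others. The search runs on a crop around the terminal that doubles
  until the target is reachable, which keeps the frontier small without
  changing the result.
* **Start attachment.** The marked terminus snaps to supra-threshold
  signal within 3 μm if any exists, else the trace starts at the marked
  voxel itself (the undetected-branch case, where the trace crosses dark
  tissue along the path the operator indicated).
* **Absorption.** After each trace the tube (per-node radii from the
  largest supra-threshold ball, minimum one voxel so 26-connectivity is
  guaranteed) is stamped into the mask, and the mask is re-labelled
  against the full thresholded foreground: any detached fragment the
  trace touched joins the structure whole. Terminals are processed in
  file order, so fragments reconnected early serve as targets for later
  traces; termini already inside the mask are no-ops. Unrelated bright
  clutter joins only if a trace actually touches it — the known failure
  mode is a vessel hugging a gap corridor, which is exactly what eraser
  markers are for.

## Skeletonization

The voxel mask becomes a centreline tree rooted at the soma voxel:

1. Dijkstra over mask voxels (same edge weights, restricted to the mask)
   gives geodesic distance, parent pointers and physical path length.
2. Candidate tips are local maxima of geodesic distance; they are
   connected back to the accepted tree in decreasing-distance order.
3. **Coverage pruning.** An accepted path stamps a coverage envelope of
   2.5 × the local tube radius (Euclidean distance transform on the
   hole-filled mask — speckle holes would otherwise deflate radii). A
   candidate chain is rejected as a surface burr unless its arc outside
   the envelope exceeds the prune threshold (3 μm default) **and** its
   net Euclidean reach from its attachment point clears the local tube
   diameter (+ prune). Net reach, not chain arc, is compared because
   voxel chains zigzag and inflate arc length. Chains that re-enter the
   envelope are truncated there and re-attached to the nearest tree voxel,
   which eliminates parallel Dijkstra threads running inside one tube.
4. Branch polylines are Laplacian-smoothed (3 iterations, endpoints
   fixed) — raw voxel-centre chains overestimate length by ~8–20% — then
   resampled at ≤ 2 μm arc spacing; radii re-estimated per node; root
   typed soma (1), all else basal dendrite (3) until retyped
   (`retype_subtree`, e.g. to axon for the per-type length readouts; no
   automatic axon classifier is attempted).

A degenerate blob with no acceptable tips yields a single-node tree rather
than an error.

## Morphometry

A **branch** is a maximal path between consecutive critical nodes (root,
bifurcation/multifurcation, tip); this convention is declared in outputs
because branch counts are convention-dependent. Lengths are Euclidean
parent→child edge sums; the soma root contributes no edge; per-type length
assigns each edge its child's type. Conservation (Σ branch lengths =
total = Σ per-type) holds to 1e-6 relative and is tested.

**Sholl profiles** count sphere crossings as sign changes of
`distance − r` along edges resampled at ≤ 1 μm, with the last nonzero sign
carried across nodes (breadth-first from the root) so a node lying exactly
on a sphere counts with its outgoing step only. The polyline approximation
is validated against the exact quadratic segment–sphere oracle on random
trees; it can only miss sub-μm double-crossings of near-tangent spheres,
which the resampling bound makes practically irrelevant. Default radii
step 10 μm from 10 μm to the farthest tip.

**Comparison** reports per-metric percent change rounded half-away-from-
zero to the nearest integer and fold change to one decimal; a zero raw
value yields fold-only (percent undefined).

## The phantom generator

The generator emulates the study conditions: 8-bit volumes, fMOST mode at
spacing (2.5, 1, 1) μm with neurite mean 240, background 120, noise sd 10
(so T = 220 separates the classes), or micro-CT mode at 0.65 μm isotropic
with means 60/20, sd 5 (so T = 40 separates). A single RNG seeded once per
phantom drives topology → geometry → noise → gaps → distractors in that
fixed order; identical specs give bit-identical volumes.

* **Tree.** Random binary topology with exactly `n_bifurcations` splits;
  straight segments of 25–45 μm at branching angles 20–60°, radii
  tapering from 2 μm at the soma (floor 1.2 μm — thin enough to be
  neurite-like, thick enough that a thresholded tube cannot fall apart at
  a single voxel); soma ball 7 μm radius (≈14 μm somata, typical of
  cortical pyramidal cells — and, as in real tissue, large enough to
  survive the 1000 μm³ artefact floor on its own). Centrelines of
  non-adjacent segments keep > 4 μm clearance (z-offsets discounted ×0.6
  for the axial elongation below) so rendered tubes never merge and the
  ground-truth topology stays well defined; generation retries within
  bounds and fails loudly if the tree cannot fit.
* **Rendering.** Tubes are stamped as overlapping balls with an axial
  half-axis of at least 0.8·dz — the axial elongation characteristic of
  anisotropic optical sectioning — and centreline voxels are always set.
  Gaussian noise is added; centreline-core voxels are clamped at
  `neurite_mean − 1.5σ` so the scripted gap model, not noise luck, is the
  only source of signal discontinuity.
* **Corruption.** Gaps are sampled at 1.5 per 100 μm with lengths
  5–15 μm (expected erased fraction 15%); interior intervals create
  mid-branch interruptions, intervals abutting a terminal branch end
  create undetected branch ends; nothing is erased within soma radius
  + 4 μm of the root (the soma is always visible in practice). The
  recorded interval is the arc actually erased. Distractors — vessel-like
  random-walk tubes and glia-like ellipsoids at neurite intensity (they
  must survive thresholding and be removed by connectivity or erasers,
  the real challenge), and 1–3-voxel puncta below the volume floor — are
  placed with ≥ 4 μm clearance from the neurite tube, with bounded
  retries.
* **Markers.** The generator emits the marker file an operator would
  produce: the soma seed, one terminal at each interruption's broken
  fragment end, one at each undetected branch's expected tip, plus any
  ground-truth tip left without soma-connected foreground within 2 μm at
  the regime's working threshold, ordered soma-outward.

**What the phantom does not model:** realistic optics or CT noise physics
(just Gaussian intensity noise), curved segments, dendritic spines,
multi-neuron forests with designed crossings, or intensity falloff with
depth. Passing the phantom recovery tests therefore demonstrates that the
pipeline's logic is correct under the stated contrast/geometry regime, not
that it will reach the same recovery on any particular real dataset.

## Validation and known limitations

The test suite checks every operation against an independent oracle where
one exists: connected components vs brute-force flood fill, trace costs vs
an exhaustive graph-library shortest path, Sholl counts vs the analytic
segment–sphere solution, plus round-trip identities and the conservation
and monotonicity invariants (threshold nesting, filter monotonicity,
repair superset/monotonicity, eraser non-creation).

On default gap-free phantoms the skeleton recovers total length within
±5% and the exact branch count on ~39/40 seeds; the residual failure mode
is a close-angle junction whose two child tubes merge over their first few
μm — genuinely unresolvable at the voxel size — which adds one spurious
bifurcation. Branch-count recovery is therefore assessed as a mean over
several phantoms. On default gapped phantoms (~15% of arc erased), the
raw-stage reconstruction recovers well under 90% of true length (gaps
disconnect whole subtrees, and sub-floor fragments are filtered), while
the repaired reconstruction recovers ≥ 95% and reconnects every marked
terminus into one component. Repair can overshoot truth by absorbing a
vessel that hugs a repair corridor; the criteria bound recovery from
below, and the eraser mechanism is the intended remedy.

Problem sizes used throughout testing — 40 × 144 × 144 voxel phantoms,
~400 μm of cable, 5 bifurcations, ≤ ~12 terminals — were chosen as the
smallest volumes that exercise every failure mode (dense distractors,
multiple gap classes, anisotropy) while keeping the whole suite fast
enough to run on every commit.
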