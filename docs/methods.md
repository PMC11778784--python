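# Methods

This note records the models, conventions, numerical choices and known
limitations of `cardiomorph`. Coordinates throughout are physical
micrometres in `(z, y, x)` component order — the voxel-spacing order of
the image axes — and all geometry downstream of image I/O is computed in
physical units, because lightsheet stacks are strongly anisotropic
(axial steps of 0.5–0.7 µm against ~0.23 µm pixels) and index-space
geometry would be wrong.

## Segmentation model

The two tissue layers are assumed to appear, slice by slice, as closed
contours: an external border, possibly enclosing one or more lumens,
possibly with tissue islands inside lumens. Contours are traced at the
0.5 iso-level of the thresholded binary slice (zero-padded first, so
foreground touching the crop box is closed along the border) and
classified purely by containment parity: even depth → external, odd
depth → internal. Parity extends the depicted two-level case to
arbitrary nesting. Filling assigns each pixel the depth of the deepest
contour covering it; `filled_external` is any coverage,
`filled_internal` is odd deepest depth, and the tissue mask is their
XOR — an identity that holds bit-exactly by construction and is asserted
as such in the tests. Boundary pixels belong to the filled region.

Thresholding defaults to per-slice Otsu with a global fixed-level
alternative; components enclosing fewer than `min_area` pixels
(default 25) are discarded. There is deliberately no interactive step:
the semi-automatic selection of the original workflow is replaced by the
(threshold, min_area) policy plus an explicit per-slice override map of
manual polygons, recorded in the library's provenance field, so a run is
a pure function of its inputs.

## Negative-space compartment

The ECM mask is `A XOR (A AND B)` with A = outer layer's filled
internal mask and B = inner layer's filled external mask — equivalently
A minus B, but computed with the AND/XOR pair so the identity
`ECM ∪ (A ∩ B) = A` is exact. Real segmentations violate strict nesting;
B-voxels outside A are clipped from every compartment and reported as a
leak count instead of producing negative volumes. The same operation
accepts any nested layer pair, so hybrid workflows (e.g. a biosensor
channel standing in for one layer) are configuration, not code.
Compartment shares are percentages of the outer layer's filled external
volume; the four compartments partition it exactly, so shares sum
to 100%.

## Meshes and volumes

Marching cubes at the 0.5 iso-level of the binary field, on a grid
zero-padded by one voxel (so boundary-touching masks still close),
scaled by the spacing and offset by the origin. Smoothing is Taubin's
shrink-free pass (λ = 0.5, ν = 0.53, default 10 iterations), which
conserves enclosed volume within 2%. Mesh volume uses the divergence
theorem on watertight meshes and errors otherwise, naming the number of
open edges. A degenerate but documented case: an isolated foreground
voxel meshes to the octahedron of the 0.5 iso-level, volume exactly
1/6 voxel.

## Centreline

The definition is the path through the lumen whose minimal wall distance
is maximal, anchored at the venous and arterial poles. The continuous
Voronoi/maximal-inscribed-sphere construction is realized discretely:
the Euclidean distance transform (with anisotropic sampling) gives every
lumen voxel its inscribed-sphere radius; the centreline is the
minimum-cost path on the 26-connected voxel graph with edge cost
`step_length / (ε + mean endpoint radius)`, ε = 0.1 × min spacing. The
inverse-radius cost makes wall-hugging shortcuts expensive, so the path
tracks the ridge of the distance transform.

The raw voxel path carries a 26-connectivity staircase that overstates
arc length by several percent. It is removed by an arclength-domain
moving average whose window defaults to the path's median inscribed
radius; on circular-arc phantoms this leaves an arc-length bias of about
−0.5% (the window pulls a bend of radius R inward by order (w/R)²),
versus +4–5% uncorrected. A smoothing-spline alternative was tried and
rejected: at the strengths needed it was numerically unstable, with
non-monotone length error. After smoothing the line is resampled
uniformly (default step = min spacing), endpoints clamped to the poles,
and the inscribed radius interpolated from the distance transform.

Looping ratio = looped (centreline) length / straight pole-to-pole
distance, ≥ 1, equal to 1 for a straight tube; the ratio increases as
the organ loops. Extension beyond the poles (needed for unrolling) is
straight-line prolongation along the least-squares tangent of the
terminal 5% of arclength.

## Partitions and orientation

A cutting disc (centre, unit normal, radius, in µm) placed at the
atrioventricular canal splits masks or meshes by the sign of
`(p − centre)·normal`; points exactly on the plane go to the ventricle
side (deterministic tie-break), each side must be connected and
nonempty, and the disc must cover the cut cross-section — otherwise the
error reports the measured overhang. Left/right splits classify each
voxel by the sign of `(v − foot)·(t × dorsal)` at its nearest centreline
point; ties go right. Chamber axes run from the pole (disc centre) to
the apex (chamber point farthest from the disc centre — an explicit
definition, since "apex" is otherwise informal); angles are signed,
measured against a user-supplied reference vector after projection into
the ventral (⊥ imaging z) or lateral (⊥ left-right x) view plane, with
the inter-chamber angle folded to [0°, 180°].

## Ellipsoid, ballooning, thickness

The chamber ellipsoid is extent-based by design (it mirrors projecting
the chamber onto the faces of a reference cube): semi-axes are half the
mesh extents along the scene triad, not a least-squares fit.
Asphericity is the coefficient of variation of the semi-axes,
`√Σ(sᵢ − s̄)² / s̄` — zero iff the fit is a sphere. `(4/3)πabc` is a
convex-size proxy only.

Ballooning at a vertex is the minimum distance to the centreline
polyline, computed segment-wise, not to its sample points. Thickness at
a carrier vertex is the exact distance to the closest point on the
opposing mesh's triangles (point-to-triangle): candidates are pruned by
a KD-tree upper bound from the nearest vertex, then tested exactly, so
the result is a pure minimum, independent of traversal order. Carrier
defaults to the external mesh for wall thickness; ECM thickness is the
same operation applied to the endocardial-external / myocardial-internal
pair. On capped tube phantoms the cap regions legitimately read larger
thickness (the nearest opposing surface is the far cap rim); lateral
statistics exclude a 10 µm band at each end.

## Unrolling and averaging

Heatmaps are standardized on an (arclength, circumferential angle) grid:
`n_planes` stations (default 100) along the pole-extended centreline
(default extension 5% of length per end), `n_angle_bins` (default 72,
i.e. 5°) covering [−180°, 180°). At each station the mesh is cut by the
plane normal to the local tangent; each intersection segment contributes
its face's mean scalar, weighted by segment length, to the bin of its
midpoint angle. Angle zero is ventral (the projection of −dorsal into
the plane), ±180° dorsal, positive angles on the left (t × dorsal)
side. Segments whose nearest centreline station is not the current one
are discarded — this both assigns geometry to stations and drops loops
from other parts of a looped organ cut by the same plane (a
centreline-proximity rule, chosen over reconstructing loops from
unordered segments).

Cells never intersected stay missing (NaN) and are never imputed —
bent-tube inner curvatures produce genuine gaps, and the tests assert
they survive. Averaging across specimens requires identical axes, is
cell-wise over contributing specimens only, and returns contributor
counts and the sample (n−1) standard deviation. CSV export writes empty
fields for missing cells and round-trips present cells bit-exactly
(re-import uses round-trip float parsing).

## Cell analysis

Nuclei coordinates come from an external spot detector as CSV (x, y, z
in µm); duplicates within 0.1 µm are merged with a warning. Chamber
assignment reuses the cutting-disc sign rule and tie-break. Regions are
90° sectors about the centreline centred on ±dorsal and ±left, with
45°-boundary ties joining the counter-clockwise-next sector; in this
coordinate convention the left/right sectors correspond to the outer and
inner curvature of the chamber. Internuclear distance: every nucleus is
a seed (no seed sampling — deterministic and unbiased; clusters
overlap), IND = mean distance to its k nearest same-chamber neighbours,
k = 4 by default. Chambers with ≤ k nuclei are skipped with a warning.
The per-chamber mean equals the count-weighted mean of region means by
construction.

## Phantoms

The generator is first-class code and the entire test-fixture surface.
A voxel is foreground iff its centre lies inside the analytic solid
(centre sampling), so voxel-count volumes deviate from closed form by at
most about one surface layer — the rasterization bound used by the
tests. Kinds: straight, bent (circular arc with spherical end caps,
poles at the arc ends), nested and bulged tubes, concentric shells, a
two-sphere two-chamber body with a connecting neck, and cubic nuclei
lattices. Defaults mirror the study conditions: wall radii 25–30 µm over
a 17–20 µm inner layer, 100 µm tube length, bend radius 50 µm, 8 µm
lattice spacing, and voxel spacing (0.5, 0.25, 0.25) µm matching
lightsheet anisotropy. Noise (salt-and-pepper, Gaussian) perturbs
intensities only; truth records never change; generation is
seed-deterministic.

Tests and the acceptance script run phantoms at 0.25–1 µm spacing
(grids up to ~8·10⁶ voxels, chosen so the whole suite completes in a
few minutes); accuracy at these sizes bounds, but does not equal,
accuracy on real data. What phantom validation establishes: the mask
algebra is exact, volumes/lengths/thicknesses converge to analytic truth
within stated tolerances, and every pipeline stage is deterministic.
What it does not establish: robustness to real microscopy physics — PSF
blur, attenuation with depth, autofluorescence, motion artefacts — nor
the adequacy of Otsu thresholding on dim or uneven staining; on real
stacks the per-slice override hook exists precisely because automatic
contouring fails on some z-planes.

## Known limitations

- Centrelines are single-branch; poles are user inputs, not detected.
- The chamber partition supports exactly two segments per disc.
- Thickness is unsigned; no inside/outside orientation.
- Heatmap averaging assumes specimens share the standardized grid; no
  warping or registration between developmental stages is attempted, and
  fewer specimens contribute at inner-curvature gaps — the count matrix
  should accompany any interpretation.
- Intensities keep their input dtype through filtering; no bit-depth
  normalization is performed.
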