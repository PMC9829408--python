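# Methods

## Problem setting

Single-cell embeddings (UMAP, tSNE, PCA) and imaging-based spatial plots
mix two point regimes: compact, heavily overplotted clusters and scattered
singletons. Redundant coding with hatch patterns must treat the two
differently — a texture over a region for the former, a per-marker glyph
for the latter — and the boundary between regimes is a visual property of
the *rendered* page, not of the data units. That observation drives most
of the design below: classification and hatch geometry operate in display
coordinates (typographic points), parameterized by the rendered marker
diameter.

## Input model

The sole required input is an ordered table of records
(id, x, y, group). Ids must be unique; coordinates finite; group labels
are compared as exact strings after whitespace trimming, with no case
folding (case-folding could silently merge biologically distinct labels).
Delimiters are inferred from the file extension (`.csv` comma, otherwise
tab) and can be overridden. Duplicate coordinates are permitted — they
simply co-occupy a grid cell. Round-tripping a table through
`write_point_table`/`load_point_table` preserves ids, order, groups and
coordinates to full float64 precision (coordinates are serialized with
`repr` and parsed with Python's correctly-rounded `float`; pandas'
`to_numeric` was measured to drop the last ~2 significant digits, so
parsing avoids it).

## Sparse point detection

Per group, independently:

1. Points are binned into square cells of side
   `bin_size = bin_factor × marker_diameter`, converted from display
   points to data units using the canvas dimensions (half-open cells,
   left/bottom edge inclusive, so every point maps to exactly one cell).
2. An occupied cell *qualifies* when the same-group count over its 3×3
   cell neighborhood is ≥ `density_threshold` k.
3. Qualifying cells form 8-connected components (diagonal chains of
   touching markers read as one cluster); components smaller than
   `min_cluster_cells` are discarded.
4. A point is dense iff its cell belongs to a surviving component.

Defaults: `bin_factor = 1.5`, `k = 4`, `min_cluster_cells = 2`, marker
diameter 3 pt on a 460.8 × 345.6 pt canvas. The cell size means roughly
"markers within ~1.5 diameters would fuse into a blob on screen"; k = 4
demands a genuinely 2-D accumulation rather than a chance pair; the
component-size floor discards single stray qualifying cells. The detector
is linear-time, monotone in k (raising k never converts sparse → dense)
and group-local (other groups' points never change a group's labels).
For headless or data-unit workflows, `bin_size` can be given directly in
data units.

A user-provided sparse list bypasses the detector entirely: listed ids are
sparse, all others dense, and the labels carry an `override` provenance
flag.

## Hatch geometry

**Region hatching.** A dense component's mask is the raw union of its
occupied square cells — no smoothing or alpha-shape. This is deliberately
blocky: robust for concave clusters, cheap, and visually coarse. A line
family at angle θ with perpendicular spacing s and phase s/2 is clipped to
the mask polygon (shapely); each maximal run becomes one segment. When the
spacing exceeds the mask's perpendicular extent (possible only for
extreme spacing), a single line through the middle of the offset range is
emitted instead, so every mask receives at least one line. Spacing
defaults to 4 × line width; line width defaults to 0.15 × marker
diameter, so pattern weight tracks point size.

**Glyphs.** A sparse marker of radius r receives, per line family, chords
at perpendicular offsets m × `glyph_spacing` (default r), centered so one
chord is a full diameter; chord endpoints lie exactly on the marker
circle. With the default spacing each family contributes one diameter
chord — legible at single-marker scale without turning the marker into a
smudge.

Verification uses two independent oracles: an exact per-cell
Liang-Barsky interval sum (cells partition the mask, so summing the line's
clipped parameter intervals over cells gives the exact hatched length) and
a dense sampling walk along each line. The implementation agrees with the
exact oracle to ~1e-13 relative and with the sampling oracle within its
discretization error. A coverage identity (total length × spacing ≈ mask
area, within 10% for convex masks) pins down the spacing semantics as
perpendicular distance.

## Patterns and palette

Seven named patterns (angle sets): horizontal {0°}, vertical {90°},
positiveDiagonal {45°}, negativeDiagonal {135°}, cross {0°, 90°}, checkers
{45°, 135°}, blank {}. The cross/checkers angle-set geometry is this
package's convention for making the six non-blank patterns pairwise
distinct as one- and two-family line sets. Custom patterns are angle
lists in [0, 180]; 180° normalizes to 0° (angles are directions of
undirected lines). Aesthetics per line: width, color, dash type
(solid/dashed/dotted/dotdash/longdash/twodash), alpha (default 1).
Default region-line color is the group fill darkened 40% toward black;
glyph chords switch to white on dark fills (WCAG relative luminance
< 0.45) for contrast against the marker itself.

The default palette embeds 40 pairwise-distinct colorblind-friendly hex
values (an Okabe-Ito-derived family: 8 base hues plus darker/lighter
variants). Assignment is color-major: group n gets color n mod 40 and
pattern ⌊n/40⌋ mod 7, giving 280 distinct combinations; with ≤ 40 groups
this degrades gracefully to "distinct colors, shared first pattern".
Exceeding capacity is an error rather than a silent wrap. Custom palettes
of any size rescale the capacity.

## Rendering

`render_plot` produces a backend-independent figure object with a fixed
layer stack — base markers, region hatching, sparse glyphs, legend — all
geometry precomputed in display points. Group draw order is assignment
order; overlapping groups overdraw (handling overlap more gracefully is a
known limitation). Legend swatches are 12 × 12 pt squares carrying a
2-line-per-family sample of the group's pattern, so the legend transmits
the redundant code too. Rendering is a pure function of its inputs.

SVG output is written by an internal generator: one `<line>` element per
segment, fixed 3-decimal coordinate formatting, no timestamps — output is
byte-identical across runs and trivially countable in tests. PNG and PDF
go through matplotlib (PDF creation date suppressed); only SVG is
guaranteed byte-stable.

## CVD simulation

Anomalous trichromacy is simulated with the standard Machado-family 3×3
transfer matrices applied in linear-light RGB; monochromacy is a Rec. 709
luma projection. Severity σ ∈ [0, 1] interpolates linearly between the
identity and the severity-1 dichromacy matrix — a simplification of the
published per-severity table that preserves the properties relied on here:
σ = 0 is exactly the identity, the map is continuous in σ, and every
matrix's rows sum to 1 so grays are fixed points. Protanomaly is
implemented as the standard red-weak deficiency; tritanomaly (blue-yellow)
is provided separately. Palette separability is the minimum pairwise
CIEDE2000 distance (scikit-image) after simulation. Figure-level
simulation maps only color strings; segment endpoints, counts and widths
are reproduced bit-identically.

## Synthetic fixtures

`make_embedding_fixture` emulates a clustered embedding: per group, an
isotropic Gaussian blob (sd = 1) at a deterministic position on a circle
of radius 1.2 × halo_radius, plus halo points drawn area-uniformly in the
annulus [0.4, 1] × halo_radius (halo_radius = 12, i.e. a 12:1 scale
separation between halo and blob). Defaults: 4 groups × (2400 dense +
100 sparse) = 10,000 points. With these scales the default detector
agrees with the planted labels on ≈ 99.7% of points; the residual
disagreement is halo points that genuinely co-locate into small clusters,
plus a handful of extreme blob-tail points — i.e. places where the planted
label and the visual truth diverge, not detector noise.

`make_spatial_fixture` tiles an n×m grid of unit frames (default 41 × 2 =
82 frames), each frame one group with points uniform in its tile — the
many-small-groups regime where patterns must cycle after the 40 colors are
exhausted.

Both generators are driven by a single explicit seed (no global RNG
state). What they do *not* emulate: real embeddings' curved, anisotropic
cluster shapes, density gradients between touching clusters, and batch
structure. Passing the recovery test therefore shows the detector
implements its definition correctly under well-separated scales, not that
95% recovery is guaranteed on arbitrary real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 10,000-point
embedding fixture, the 82-group spatial fixture, 50 random classifier
configurations (≤ 20×20 cells) against the brute-force oracle, and 20
random masks against the clipping oracle; the complete run takes a few
seconds. Tolerances: hatch length vs. exact oracle 1e-6 relative (the
acceptance comparison allows 1%); angle fidelity 1e-6 degrees; coverage
identity 10%; grid tie-breaks by half-open cells; hatch offset
enumeration uses a 1e-12 guard against floating-point fence-post loss.

## Known limitations

- Overlapping groups overdraw in input order; no blending or interleaving.
- The blocky cell-union mask can look coarse for very small clusters
  (that coarseness is also what keeps it robust).
- Dash patterns do not scale with line width.
- Legend labels are not measured for width; very long group names can
  overflow their column.
- No readers for single-cell container formats (AnnData/Seurat); input is
  delimited text.
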