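# hatchscatter

Colorblind-accessible scatter plots for single-cell and spatial data:
every cell group is encoded **redundantly** with a fill color *and* a hatch
pattern, so group identity survives any loss of the color channel — from
deuteranomaly to full monochromacy, or simply a bad projector.

Scatter plots of UMAP/tSNE embeddings and in-situ spatial data usually
separate cell groups by color alone. That fails the ~8% of male and ~0.5%
of female readers with a color-vision deficiency (CVD), and degrades for
everyone once dozens of groups share one panel. Point-shape coding breaks
down in dense clusters; plain region hatching breaks down for isolated
points. hatchscatter handles the mixture: each group's points are split
into **dense clusters**, overlaid with coarse region hatching, and
**sparse singletons**, each stamped with a miniature glyph of the same
pattern (chords of the marker disk).

## Method

Given a table of points $(x_i, y_i)$ with group labels $g_i$:

1. **Sparse/dense classification** (per group, independently). Points are
   binned into square cells whose side is `bin_factor` (1.5) × the rendered
   marker diameter. A cell *qualifies* if the same-group count over its
   3×3 cell neighborhood is ≥ *k* (default 4); qualifying cells form
   8-connected components, and components with ≥ `min_cluster_cells`
   (default 2) cells are kept. A point is *dense* iff its cell lies in a
   kept component. A user-supplied sparse list bypasses the detector.
2. **Aesthetic assignment.** Group *n* gets fill color *n* mod 40 from a
   40-color CVD-friendly palette and pattern ⌊*n*/40⌋ from 7 named
   patterns (`horizontal`, `vertical`, `positiveDiagonal`,
   `negativeDiagonal`, `cross`, `checkers`, `blank`) — 280 distinct
   (color, pattern) combinations. Custom palettes, custom angle lists
   (`angle=[45, 90, 135]`) and per-line aesthetics (width, color, dash
   type, alpha) extend this further.
3. **Hatch geometry** (in display coordinates, so angles are exact on the
   page). Dense components: parallel lines at each pattern angle with
   perpendicular spacing 4 × line width, clipped to the union of occupied
   cells. Sparse points: chords of the marker circle at the same angles.
4. **CVD audit.** Machado-matrix simulation of deuteranomaly, protanomaly,
   tritanomaly (severity ∈ [0, 1]) and monochromacy over any palette or
   rendered figure, plus minimum pairwise CIEDE2000 separation. Simulation
   changes colors only — segment geometry is bit-identical, which is the
   redundant-coding guarantee.

## Worked example

Render the built-in synthetic embedding (4 Gaussian clusters of 2400
points, each with a 100-point sparse halo):

```sh
$ hatchscatter --demo embedding --seed 1 --output embedding.svg --verbose
points: 10000 in 4 groups
dense: 9607  sparse: 393
region segments: 194  glyph segments: 393  legend entries: 4
wrote embedding.svg
```

The detector finds 393 sparse points (of 400 planted halo points; the
remaining halo points landed close enough together to form small genuine
clusters). The four dense clusters receive 194 clipped hatch lines; every
sparse point gets its own pattern glyph (one chord per line family here —
the first four groups all carry the single-family `horizontal` pattern);
the legend shows each group's color swatch overlaid with its pattern.

The same from Python, plus the accessibility audit:

```python
import hatchscatter as hs

table = hs.make_embedding_fixture(seed=1)
labels = hs.classify_sparse_dense(table)
fig = hs.render_plot(table, labels)
hs.save_figure(fig, "embedding.svg")

hs.palette_separation(hs.default_palette())                  # 1.955
hs.palette_separation(hs.default_palette(), "deuteranomaly") # 0.792
hs.palette_separation(hs.default_palette(), "monochromacy")  # 0.0
```

The minimum pairwise CIEDE2000 distance of the default palette collapses
to 0 under monochromacy — two of the 40 colors become the same gray. That
is precisely why the pattern channel exists: recoloring the figure with
`hs.simulate_figure(fig, "monochromacy")` changes only colors, never a
single segment endpoint.

Your own data goes in as delimited text with two coordinate columns and a
group column:

```sh
hatchscatter --input cells.csv --x UMAP1 --y UMAP2 --group cell_type \
             --output cells.svg
```

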