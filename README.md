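# ecmlines

Design and analysis pipeline for studying **contact guidance** — how the
organization of fibrous extracellular matrix (ECM) steers cell shape,
polarity and migration — on microcontact-printed fibronectin line arrays.

The package is aimed at quantitative cell biologists and biomedical
engineers who (a) need printable, randomized line-array micropatterns with
orthogonal control of three ECM parameters, and (b) need the downstream
image quantification and statistics for experiments on such patterns. It
covers the full loop:

1. **Pattern design** (`pattern_design`): random line-array fields with
   angular dispersion θ (angles uniform on [−θ, +θ] about the pattern
   axis; ±5° ≈ aligned fibers, ±90° ≈ isotropic), line density D (lines
   per field) and line width w. Fields rasterize to masks and export as
   SVG layouts + metadata CSV for photomask production (a 5× projection
   stepper turns 2.5–10 µm mask lines into 0.5–2 µm printed lines).
2. **Synthetic microscopy** (`synthetic`): multi-channel images (pattern,
   cytosol, nucleus, vinculin, MTOC), nucleus time-lapse stacks, and
   donor/acceptor FRET pairs, rendered from analytic shapes with recorded
   ground truth — so every analysis stage is validated by parameter
   recovery with no external data.
3. **Quantification**: per-cell morphometrics (area, ellipse-equivalent
   aspect ratio AR, axial orientation φ relative to the pattern axis;
   `morphometrics`), focal-adhesion size/count and the axial angular
   deviation of adhesion orientations within each cell (`adhesions`),
   nucleus tracking with migration speed S = path length / duration and
   persistence P = net displacement / path length (`tracking`), and MTOC
   polarity, protrusion detection, kymographs and FRET ratio images
   (`polarity`).
4. **Statistics** (`stats`): axial circular statistics by angle doubling
   (mean resultant length R̄, angular deviation √(2(1−R̄))/2), Pearson
   correlation, Levene's test, one-way ANOVA with Bonferroni post hoc
   tests, and a two-response general linear model
   (φ, AR) ~ w + θ + D + interactions with per-term Pillai-trace /
   approximate-F tests and dual-direction stepwise AIC model selection.

See `docs/methods.md` for the models and numerical choices and
`docs/data_dictionary.md` for every output column.

## Worked example

```python
from ecmlines import pattern_design as pat, synthetic as syn
from ecmlines import morphometrics as morph, stats as st

# an aligned condition: ±5°, 100 lines, 1 µm lines on a 700 µm field
field = pat.generate_field(density=100, dispersion_deg=5.0, line_width_um=1.0,
                           field_size=(700.0, 700.0), seed=7)
mask = pat.rasterize_field(field, pixel_size_um=0.8)
frac, saturated = pat.coverage_fraction(mask)
print(f"lines={len(field.lines)}  coverage={frac:.3f}  saturated={saturated}")

# synthetic stained image of 20 cells on that pattern, then measure them back
channels, truth = syn.synth_cell_image(field, syn.cell_params_for_dispersion(5.0),
                                       syn.ImagingParams(), n_cells=20, seed=7)
labels = morph.segment_cells(channels["cytosol"].astype(float),
                             min_area_um2=200.0, pixel_size_um=0.8)
cells = morph.measure_cells_df(labels, pixel_size_um=0.8)
ax = st.circ_axial_stats(cells["orientation_deg"].to_numpy())
print(f"cells={len(cells)}  median AR={cells.aspect_ratio.median():.2f}  "
      f"axial mean={ax.mean_deg:.1f} deg  axial deviation={ax.angular_deviation_deg:.1f} deg")
```

Output:

```
lines=100  coverage=0.133  saturated=False
cells=20  median AR=3.50  axial mean=-1.2 deg  axial deviation=4.8 deg
```

Reading: the ±5° pattern covers 13% of the field with fibronectin; the 20
rendered cells are strongly elongated (median aspect ratio 3.5) and
co-aligned with the pattern axis (axial mean −1.2° with only 4.8° axial
angular deviation, against a ≈40.5° maximum for isotropic orientations) —
and these measured values recover the generating parameters of the
synthetic condition.

## Command line

A stage-oriented CLI drives the same pipeline from one YAML config:

```sh
ecmlines init-config demo.yaml
ecmlines validate demo.yaml
ecmlines all demo.yaml        # design → synth → morph → adhesions → track → polarity → fret
ecmlines stats demo.yaml --table my_cells.csv
```

Each stage writes its tables/images plus a JSON run manifest (config hash,
seeds, input hashes) to the configured output directory; identical config
and seed reproduce byte-identical outputs.

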