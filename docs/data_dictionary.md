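# Data dictionary

All angles in output tables are degrees; all lengths micrometres; times
minutes unless a column name says otherwise. Axial angles lie in
(−90, 90]; folded relative angles in [0, 90].

## layout_fields.csv (design stage)
| column | meaning |
|---|---|
| field_id | `field-<row>-<col>` slot id, matches the SVG group id |
| row, col | grid position in the layout |
| dispersion_deg | angular dispersion θ (half-width of the uniform angle interval) |
| density | number of line elements in the field |
| line_width_um | printed line width |
| seed | per-field RNG seed |

## synthetic_truth.csv (synth stage; one row per generated cell)
| column | meaning |
|---|---|
| cell | cell index |
| x_um, y_um | cell centroid |
| aspect_ratio | sampled moment-equivalent aspect ratio |
| area_um2 | sampled cell area |
| orientation_deg | sampled cell axis angle (axial) |
| n_adhesions | sampled adhesion count |
| adhesion_angles_deg | `;`-joined sampled adhesion orientations |
| leading_edge_deg | sampled leading-edge direction ((−180, 180]) |
| mtoc_class | sampled MTOC placement: front / middle / back |
| mtoc_x_um, mtoc_y_um | MTOC point |
| nucleus_a_um, nucleus_b_um | nucleus semi-axes |

## synthetic_tracks_truth.csv
cell, frame, t_min, x_um, y_um — ground-truth nucleus positions.

## cells.csv (morph stage; one row per segmented cell)
label, area_um2, centroid_x_um, centroid_y_um, aspect_ratio,
orientation_deg (axial), relative_orientation_deg ([0, 90] vs pattern
axis), degenerate (bool; minor axis floored at one pixel).

## adhesion_records.csv / adhesion_summaries.csv
Records: cell_label, area_um2, orientation_deg (axial), centroid_xy_um.
Summaries: cell_label, n_adhesions, mean_area_um2, angular_deviation_deg
(axial circular deviation of adhesion orientations relative to the cell
axis; empty for cells with no adhesions).

## tracks.csv / track_metrics.csv (track stage)
Tracks: track_id, t_min, x_um, y_um, divided, truncated (one row per
point). Metrics (retained tracks only): track_id, speed_um_per_h (path
length / duration), persistence (net displacement / path length, [0, 1]).

## mtoc.csv (polarity stage)
cell, mtoc_orientation_deg ([0, 90] vs pattern axis), aligned
(orientation ≤ 45°), position_class (front / middle / back).

## regression_table.csv / selection_trace.csv (stats stage)
Table: term, coef[<response>] per response, approx_F (Pillai/Rao),
p. Trace: move (start/drop/add), term, aic after the move.

## manifest_<stage>.json
stage, config_sha256, seed, input file hashes, output paths, package and
Python versions.
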