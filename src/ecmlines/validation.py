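"""In-silico validation experiments: parameter-recovery loops that exercise
the full generate → render → measure pipeline.

Each experiment generates synthetic data at known ground truth, runs the
corresponding analysis stage, and reports generating vs recovered values.
These are the package's own evidence that the measurement chain is unbiased
at the scales it claims; they are reused by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import adhesions as adh
from . import morphometrics as morph
from . import pattern_design as pat
from . import polarity as pol
from . import stats as st
from . import synthetic as syn
from . import tracking as trk

__all__ = [
    "expected_axial_deviation_deg",
    "morphology_recovery",
    "adhesion_recovery",
    "mtoc_recovery",
    "tracking_recovery",
    "persistence_vs_dispersion",
    "speed_vs_adhesion_deviation",
    "stepwise_selection_rate",
]


def expected_axial_deviation_deg(sd_deg: float) -> float:
    """Axial angular deviation of a wrapped-normal sample with sd ``sd_deg``.

    Uses ``E[cos 2Δ] = exp(−2σ²)`` for the wrapped normal, then the axial
    deviation closed form ``√(2(1−R))/2``.
    """
    R = math.exp(-2.0 * math.radians(sd_deg) ** 2)
    return math.degrees(math.sqrt(2.0 * (1.0 - R)) / 2.0)


def morphology_recovery(
    dispersion_deg: float,
    n_cells: int = 200,
    seed: int = 0,
    noise: bool = True,
    pixel_size_um: float = 0.8,
    cells_per_field: int = 25,
) -> dict:
    """Render ``n_cells`` cells at condition θ, segment and measure them.

    Returns generating vs measured median aspect ratio and axial
    orientation spread, plus the raw measured orientation sample.
    """
    cp = syn.cell_params_for_dispersion(dispersion_deg)
    im = (
        syn.ImagingParams(pixel_size_um=pixel_size_um)
        if noise
        else syn.ImagingParams.noiseless(pixel_size_um)
    )
    n_fields = math.ceil(n_cells / cells_per_field)
    frames = []
    truths = []
    for b in range(n_fields):
        n_here = min(cells_per_field, n_cells - b * cells_per_field)
        field = pat.generate_field(
            100, dispersion_deg, 1.0, (700.0, 700.0), seed=pat.field_seed(seed, b)
        )
        channels, truth = syn.synth_cell_image(field, cp, im, n_here, seed=seed * 1000 + b)
        labels = morph.segment_cells(
            channels["cytosol"].astype(float),
            min_area_um2=200.0,
            pixel_size_um=pixel_size_um,
        )
        frames.append(morph.measure_cells_df(labels, pixel_size_um))
        truths.append(truth)
    cells = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    meas = st.circ_axial_stats(cells["orientation_deg"].to_numpy())
    gen = st.circ_axial_stats(truth["orientation_deg"].to_numpy())
    return {
        "n_cells_measured": len(cells),
        "median_ar_generating": cp.median_aspect_ratio,
        "median_ar_measured": float(cells["aspect_ratio"].median()),
        "axial_dev_expected_deg": expected_axial_deviation_deg(cp.orientation_sd_deg),
        "axial_dev_generating_sample_deg": gen.angular_deviation_deg,
        "axial_dev_measured_deg": meas.angular_deviation_deg,
        "orientations_deg": cells["orientation_deg"].to_numpy(),
        "relative_orientations_deg": cells["relative_orientation_deg"].to_numpy(),
        "aspect_ratios": cells["aspect_ratio"].to_numpy(),
    }


def adhesion_recovery(
    sigma_fa_deg: float,
    n_fields: int = 6,
    cells_per_field: int = 2,
    seed: int = 0,
    pixel_size_um: float = 0.2,
) -> dict:
    """Render cells with adhesions at dispersion σ_FA; recover the per-cell
    axial angular deviation through the full segmentation pipeline."""
    cp = replace(
        syn.CellModelParams(),
        adhesion_angle_sd_deg=sigma_fa_deg,
        adhesion_mean_count=50,
        median_area_um2=2000.0,
        log_area_sd=0.1,
    )
    im = replace(syn.ImagingParams(), pixel_size_um=pixel_size_um)
    devs = []
    for b in range(n_fields):
        field = pat.generate_field(
            20, 15.0, 1.0, (220.0, 220.0), seed=pat.field_seed(seed, b)
        )
        channels, _ = syn.synth_cell_image(
            field, cp, im, cells_per_field, seed=seed * 977 + b
        )
        labels = morph.segment_cells(
            channels["cytosol"].astype(float), min_area_um2=200.0,
            pixel_size_um=pixel_size_um,
        )
        cells = morph.measure_cells_df(labels, pixel_size_um)
        records = adh.segment_adhesions(
            channels["vinculin"].astype(float) - im.background,
            labels,
            threshold=im.foreground * 0.3,
            pixel_size_um=pixel_size_um,
        )
        for s in adh.summarize_adhesions(records, cells):
            if s.n_adhesions >= 10:
                devs.append(s.angular_deviation_deg)
    return {
        "n_cells": len(devs),
        "sigma_fa_deg": sigma_fa_deg,
        "deviation_expected_deg": expected_axial_deviation_deg(sigma_fa_deg),
        "deviation_measured_deg": float(np.mean(devs)),
    }


def mtoc_recovery(
    probs: tuple[float, float, float] = (0.2, 0.3, 0.5),
    n_cells: int = 200,
    seed: int = 0,
    cells_per_field: int = 25,
) -> dict:
    """Sample MTOC placements and recover class fractions by projection
    classification against the nucleus outline."""
    cp = replace(syn.CellModelParams(), mtoc_probs=probs)
    counts = {"front": 0, "middle": 0, "back": 0}
    n_fields = math.ceil(n_cells / cells_per_field)
    done = 0
    for b in range(n_fields):
        n_here = min(cells_per_field, n_cells - done)
        field = pat.generate_field(
            20, 30.0, 1.0, (700.0, 700.0), seed=pat.field_seed(seed, b)
        )
        _, truth = syn.synth_cell_image(
            field, cp, syn.ImagingParams.noiseless(), n_here, seed=seed * 31 + b
        )
        for _, row in truth.iterrows():
            a = np.linspace(0, 2 * np.pi, 64, endpoint=False)
            th = math.radians(row["orientation_deg"])
            pts = np.column_stack(
                [
                    row["x_um"] + row["nucleus_a_um"] * np.cos(a) * math.cos(th)
                    - row["nucleus_b_um"] * np.sin(a) * math.sin(th),
                    row["y_um"] + row["nucleus_a_um"] * np.cos(a) * math.sin(th)
                    + row["nucleus_b_um"] * np.sin(a) * math.cos(th),
                ]
            )
            cls = pol.mtoc_position_class(
                (row["mtoc_x_um"], row["mtoc_y_um"]), pts, row["leading_edge_deg"]
            )
            counts[cls] += 1
            done += 1
    fractions = {k: counts[k] / done for k in counts}
    return {
        "n_cells": done,
        "generating": dict(zip(("front", "middle", "back"), probs)),
        "recovered": fractions,
        "max_abs_error": max(
            abs(fractions[k] - p)
            for k, p in zip(("front", "middle", "back"), probs)
        ),
    }


def tracking_recovery(
    speed_um_per_h: float,
    noise: bool = False,
    n_tracks: int = 50,
    seed: int = 0,
    frame_interval_min: float = 10.0,
    duration_min: float = 360.0,
) -> dict:
    """Simulate, render, detect, link and measure ``n_tracks`` walks.

    Measured tracks are matched to ground-truth cells by start position;
    speed is compared to the generating parameter, persistence to the
    ground-truth track's own persistence.
    """
    w = syn.WalkParams(
        speed_um_per_min=speed_um_per_h / 60.0,
        persistence=0.7,
        confinement=0.5,
        frame_interval_min=frame_interval_min,
        duration_min=duration_min,
    )
    side = 1400.0 + 10.0 * speed_um_per_h
    im = (
        syn.ImagingParams(pixel_size_um=1.0)
        if noise
        else syn.ImagingParams.noiseless(1.0)
    )
    stack, truth = syn.synth_timelapse(
        w, n_cells=n_tracks, field_size_um=(side, side), imaging=im,
        seed=seed, min_separation_um=130.0,
    )
    dets = [trk.detect_nuclei(fr, im.background + 150.0, 4, 1.0) for fr in stack]
    times = sorted(truth["t_min"].unique())
    tracks = trk.link_tracks(dets, max_disp_um=30.0, frame_times_min=list(times))
    kept = trk.filter_tracks(tracks, trk.FilterRules())

    starts = {
        int(c): g.sort_values("frame").iloc[0][["x_um", "y_um"]].to_numpy()
        for c, g in truth.groupby("cell")
    }
    # cells whose paths come close to another cell's can swap identity at a
    # crossing; the tracker has no merge/split resolution by design, so the
    # recovery comparison excludes those encounters (the analogue of
    # excluding touching or dividing cells in live imaging)
    paths = np.stack(
        [g.sort_values("frame")[["x_um", "y_um"]].to_numpy() for _, g in truth.groupby("cell")]
    )  # (cells, frames, 2)
    d = np.linalg.norm(paths[:, None, :, :] - paths[None, :, :, :], axis=3)
    np.einsum("iij->ij", d)[...] = np.inf
    isolated = set(np.flatnonzero(d.min(axis=(1, 2)) > 25.0).tolist())
    speeds, pers_err = [], []
    for t in kept:
        p0 = np.array([t.x_um[0], t.y_um[0]])
        cell = min(starts, key=lambda c: np.linalg.norm(starts[c] - p0))
        if np.linalg.norm(starts[cell] - p0) > 5.0 or cell not in isolated:
            continue
        g = truth[truth.cell == cell].sort_values("frame")
        # compare over the frames the measured track actually covers
        g = g[(g.t_min >= t.t_min[0]) & (g.t_min <= t.t_min[-1])]
        gt = trk.Track(cell, list(g.t_min), list(g.x_um), list(g.y_um))
        sp_m, pe_m = trk.track_metrics(t)
        sp_g, pe_g = trk.track_metrics(gt)
        speeds.append(sp_m)
        if pe_m is not None and pe_g is not None:
            pers_err.append(abs(pe_m - pe_g))
    return {
        "n_tracks_matched": len(speeds),
        "speed_generating_um_per_h": speed_um_per_h,
        "speed_measured_um_per_h": float(np.mean(speeds)),
        "speed_error_pct": 100.0 * abs(np.mean(speeds) - speed_um_per_h) / speed_um_per_h,
        "persistence_mean_abs_error": float(np.mean(pers_err)),
    }


def persistence_vs_dispersion(
    dispersions_deg=(5.0, 90.0), n_cells: int = 15, seed: int = 0
) -> dict[float, float]:
    """Mean measured persistence per pattern dispersion (noiseless render)."""
    out = {}
    for i, theta in enumerate(dispersions_deg):
        w = syn.walk_params_for_dispersion(theta)
        stack, truth = syn.synth_timelapse(
            w, n_cells=n_cells, field_size_um=(1500.0, 1500.0),
            imaging=syn.ImagingParams.noiseless(1.0), seed=seed * 13 + i,
            min_separation_um=150.0,
        )
        dets = [trk.detect_nuclei(fr, 150.0, 4, 1.0) for fr in stack]
        times = sorted(truth["t_min"].unique())
        tracks = trk.link_tracks(dets, 30.0, list(times))
        kept = trk.filter_tracks(tracks, trk.FilterRules(0.9, 0.0, True))
        pers = [
            p for _, p in (trk.track_metrics(t) for t in kept) if p is not None
        ]
        out[theta] = float(np.mean(pers))
    return out


def speed_vs_adhesion_deviation(
    dispersions_deg=(5.0, 30.0, 60.0, 90.0), seed: int = 0
) -> dict:
    """Condition-level coupling experiment: per dispersion θ the generator
    ties σ_FA (increasing) and migration speed (decreasing) together; the
    measured FA deviation and measured speed across conditions should then
    correlate negatively, as adhesion disorganization tracks slower
    migration."""
    devs, speeds = [], []
    for i, theta in enumerate(dispersions_deg):
        cp = syn.cell_params_for_dispersion(theta)
        rec = adhesion_recovery(
            cp.adhesion_angle_sd_deg, n_fields=2, cells_per_field=2,
            seed=seed * 7 + i,
        )
        devs.append(rec["deviation_measured_deg"])
        w = syn.walk_params_for_dispersion(theta)
        stack, truth = syn.synth_timelapse(
            w, n_cells=8, field_size_um=(1200.0, 1200.0),
            imaging=syn.ImagingParams.noiseless(1.0), seed=seed * 11 + i,
            min_separation_um=150.0,
        )
        dets = [trk.detect_nuclei(fr, 150.0, 4, 1.0) for fr in stack]
        tracks = trk.link_tracks(dets, 30.0, sorted(truth["t_min"].unique()))
        kept = trk.filter_tracks(tracks, trk.FilterRules(0.9, 0.0, True))
        speeds.append(float(np.mean([trk.track_metrics(t)[0] for t in kept])))
    r, r2, p = st.pearson_corr(devs, speeds)
    return {
        "dispersions_deg": list(dispersions_deg),
        "fa_deviation_deg": devs,
        "speed_um_per_h": speeds,
        "pearson_r": r,
        "p": p,
    }


def stepwise_selection_rate(
    n_seeds: int = 100, n: int = 2000, seed0: int = 0
) -> dict:
    """Fraction of simulations where dual-direction AIC selection removes a
    zero-coefficient interaction while keeping all true main effects."""
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 * 100_003 + s)
        df = pd.DataFrame(
            {
                "width": rng.normal(size=n),
                "alignment": rng.normal(size=n),
                "density": rng.normal(size=n),
            }
        )
        df["orientation"] = (
            1.0 + 0.3 * df.width - 0.2 * df.alignment + 0.1 * df.density
            + rng.normal(size=n)
        )
        df["aspect_ratio"] = (
            0.5 - 0.2 * df.width + 0.1 * df.alignment + 0.15 * df.density
            + rng.normal(size=n)
        )
        spec = st.MvRegressionSpec(
            ("orientation", "aspect_ratio"),
            ("intercept", "width", "alignment", "density", "width:alignment"),
            df,
        )
        sel, _ = st.aic_stepwise(spec)
        if "width:alignment" not in sel.terms and all(
            t in sel.terms for t in ("width", "alignment", "density")
        ):
            hits += 1
    return {"n_seeds": n_seeds, "n": n, "success_rate": hits / n_seeds, "hits": hits}
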