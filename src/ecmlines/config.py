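"""Pipeline configuration: YAML schema, validation, and run manifests.

One YAML file drives all stages. Each stage reads only its own block plus
the ``global`` block; unknown keys anywhere are rejected so typos fail
loudly instead of silently using defaults.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import yaml

__all__ = [
    "SCHEMA",
    "default_config",
    "load_config",
    "validate_config",
    "write_manifest",
]

# allowed keys and (type, predicate) per block
_pos = ("number", lambda v: v > 0)
_nonneg = ("number", lambda v: v >= 0)
_any_num = ("number", lambda v: True)
_str = ("str", lambda v: True)
_bool = ("bool", lambda v: True)
_int_pos = ("int", lambda v: v > 0)
_list = ("list", lambda v: True)

SCHEMA: dict[str, dict[str, tuple]] = {
    "global": {
        "seed": ("int", lambda v: 0 <= v < 2**31),
        "pixel_size_um": _pos,
        "output_dir": _str,
        "log_level": ("str", lambda v: v in ("DEBUG", "INFO", "WARNING", "ERROR")),
    },
    "pattern_design": {
        "field_size_um": _list,
        "pitch_um": _pos,
        "saturation_threshold": ("number", lambda v: 0 < v <= 1),
        "dispersions_deg": _list,
        "densities": _list,
        "line_widths_um": _list,
        "raster_pixel_size_um": _pos,
    },
    "synthetic_data": {
        "n_cells": ("int", lambda v: v >= 0),
        "dispersion_deg": _pos,
        "density": ("int", lambda v: v >= 0),
        "line_width_um": _pos,
        "noise": _bool,
        "duration_min": _pos,
        "frame_interval_min": _pos,
    },
    "morphometrics": {
        "threshold": _any_num,
        "min_area_um2": _pos,
        "background_filter": ("str", lambda v: v in ("gaussian", "rolling_ball", "none")),
        "filter_sigma_um": _pos,
    },
    "adhesions": {
        "threshold": _any_num,
        "min_area_um2": _pos,
        "max_area_um2": _pos,
        "footprint_dilation_um": _nonneg,
        "center": ("str", lambda v: v in ("mean", "cell_axis")),
    },
    "tracking": {
        "threshold": _any_num,
        "min_area_px": _int_pos,
        "max_disp_um": _pos,
        "min_duration_fraction": ("number", lambda v: 0 <= v <= 1),
        "non_migratory_path_um": _nonneg,
        "exclude_divided": _bool,
    },
    "polarity": {
        "bins": _int_pos,
        "min_frames": _int_pos,
        "min_gain_px": _nonneg,
        "fret_mask_threshold": _any_num,
        "fret_background": _nonneg,
    },
    "stats": {
        "responses": _list,
        "full_terms": _list,
        "direction": ("str", lambda v: v in ("both", "backward", "forward")),
    },
}

_TYPES = {"number": (int, float), "int": int, "str": str, "bool": bool, "list": list}


def default_config() -> dict:
    """The bundled demo configuration: a small end-to-end synthetic run."""
    return {
        "global": {"seed": 7, "pixel_size_um": 0.8, "output_dir": "ecmlines_out", "log_level": "INFO"},
        "pattern_design": {
            "field_size_um": [700, 700],
            "pitch_um": 750,
            "saturation_threshold": 0.99,
            "dispersions_deg": [5, 90],
            "densities": [100],
            "line_widths_um": [1.0],
            "raster_pixel_size_um": 0.8,
        },
        "synthetic_data": {
            "n_cells": 15,
            "dispersion_deg": 5,
            "density": 100,
            "line_width_um": 1.0,
            "noise": True,
            "duration_min": 360.0,
            "frame_interval_min": 10.0,
        },
        "morphometrics": {
            "min_area_um2": 200.0,
            "background_filter": "gaussian",
            "filter_sigma_um": 25.0,
        },
        "adhesions": {
            "threshold": 300.0,
            "min_area_um2": 0.25,
            "max_area_um2": 15.0,
            "footprint_dilation_um": 2.0,
            "center": "mean",
        },
        "tracking": {
            "threshold": 200.0,
            "min_area_px": 4,
            "max_disp_um": 30.0,
            "min_duration_fraction": 0.9,
            "non_migratory_path_um": 20.0,
            "exclude_divided": True,
        },
        "polarity": {
            "bins": 36,
            "min_frames": 3,
            "min_gain_px": 20.0,
            "fret_mask_threshold": 50.0,
            "fret_background": 100.0,
        },
        "stats": {
            "responses": ["relative_orientation_deg", "aspect_ratio"],
            "full_terms": [
                "intercept",
                "width",
                "alignment",
                "density",
                "width:alignment",
                "alignment:density",
                "width:density",
            ],
            "direction": "both",
        },
    }


def validate_config(cfg_or_path) -> list[str]:
    """Return the list of schema violations (empty = valid). No side effects."""
    if isinstance(cfg_or_path, (str, Path)):
        with open(cfg_or_path) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = cfg_or_path
    problems: list[str] = []
    if not isinstance(cfg, dict):
        return ["config root must be a mapping"]
    for block, entries in cfg.items():
        if block not in SCHEMA:
            problems.append(f"unknown block: {block}")
            continue
        if not isinstance(entries, dict):
            problems.append(f"{block}: must be a mapping")
            continue
        for key, val in entries.items():
            if key not in SCHEMA[block]:
                problems.append(f"{block}.{key}: unknown key")
                continue
            tname, pred = SCHEMA[block][key]
            pytypes = _TYPES[tname]
            if isinstance(val, bool) and tname != "bool":
                problems.append(f"{block}.{key}: expected {tname}, got bool")
            elif not isinstance(val, pytypes):
                problems.append(f"{block}.{key}: expected {tname}, got {type(val).__name__}")
            elif not pred(val):
                problems.append(f"{block}.{key}: invalid value {val!r}")
    return problems


def load_config(path) -> dict:
    """Load and validate a YAML config; defaults fill unspecified keys."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    problems = validate_config(user)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    cfg = default_config()
    for block, entries in user.items():
        cfg.setdefault(block, {}).update(entries)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, stage: str, cfg: dict, inputs: list = (), outputs: list = ()) -> Path:
    """Write a machine-readable run manifest next to the stage outputs."""
    import ecmlines

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.get("global", {}).get("seed"),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "versions": {
            "ecmlines": ecmlines.__version__,
            "python": platform.python_version(),
        },
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
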