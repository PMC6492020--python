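"""Readers and writers for every artifact format.

All schemas are fixed here, in one place. Columns carry their units in
the name (``*_um``, ``*_mm2``, ``*_mpa``, ``*_pct``); files with missing
or unknown columns are rejected with a :class:`~xylemct.errors.SchemaError`
naming the offending columns. Reals survive a write/read round trip at
full precision (pandas and ``json`` serialise shortest round-trip reprs).

Images are written as single-channel 16-bit TIFF or 8-bit PNG from floats
in [0, 1] and read back to floats in [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import NoDataError, SchemaError
from .hydraulics import HydraulicSample
from .anatomy import WallMeasurement
from .segmentation import Conduit, ConduitMap
from .vulnerability import VulnerabilityCurve

__all__ = [
    "read_image", "write_image",
    "read_conduit_map", "write_conduit_map",
    "read_curve_points", "write_curve_points",
    "read_wall_pairs", "write_wall_pairs",
    "read_hydraulic_samples", "write_hydraulic_samples",
    "read_ground_truth_frame", "write_ground_truth_frame",
    "curve_to_dict", "write_curves_json", "thresholds_table",
]

CONDUIT_COLUMNS = ["id", "x_um", "y_um", "area_um2", "d_um", "state", "border_flag"]
CURVE_COLUMNS = ["sample_id", "organ", "method", "psi_mpa", "plc_pct"]
WALL_COLUMNS = ["sample_id", "t_um", "b_um", "pair_mean_d_um"]
HYDRAULIC_COLUMNS = ["sample_id", "psi_mpa", "ki", "ks", "temperature_c"]
TRUTH_COLUMNS = ["id", "x_um", "y_um", "d_um", "threshold_psi_mpa", "state"]


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise NoDataError(f"{path}: no data") from None
    missing = [c for c in columns if c not in df.columns]
    unknown = [c for c in df.columns if c not in columns]
    if missing or unknown:
        raise SchemaError(
            f"{path}: schema mismatch (missing columns {missing}, "
            f"unknown columns {unknown}); expected exactly {columns}")
    if len(df) == 0:
        raise NoDataError(f"{path}: table has a header but no rows")
    return df[columns]


# -- images -----------------------------------------------------------------

def write_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit TIFF (.tif) or 8-bit PNG (.png)."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(img * 65535).astype(np.uint16))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, np.round(img * 255).astype(np.uint8))
    else:
        raise SchemaError(f"{path}: unsupported image format (use .tif or .png)")


def read_image(path) -> np.ndarray:
    """Read a single-channel image to floats in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3:  # collapse accidental RGB
        raw = raw[..., 0]
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0
    return raw.astype(float)


# -- conduit maps -----------------------------------------------------------

def write_conduit_map(path_csv, cmap: ConduitMap) -> None:
    """Write conduits as CSV plus a ``.json`` sidecar with map metadata."""
    path_csv = Path(path_csv)
    df = pd.DataFrame(
        {
            "id": [c.id for c in cmap.conduits],
            "x_um": [c.centroid_um[0] for c in cmap.conduits],
            "y_um": [c.centroid_um[1] for c in cmap.conduits],
            "area_um2": [c.area_um2 for c in cmap.conduits],
            "d_um": [c.equivalent_diameter_um for c in cmap.conduits],
            "state": [c.state for c in cmap.conduits],
            "border_flag": [int(c.border) for c in cmap.conduits],
        }
    )
    df.to_csv(path_csv, index=False)
    sidecar = {
        "pixel_size_um": cmap.pixel_size_um,
        "xylem_area_mm2": cmap.xylem_area_mm2,
        "source_image_id": cmap.source_image_id,
        "settings": cmap.settings,
    }
    path_csv.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_conduit_map(path_csv) -> ConduitMap:
    path_csv = Path(path_csv)
    sidecar_path = path_csv.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"{sidecar_path}: missing conduit-map sidecar")
    meta = json.loads(sidecar_path.read_text())
    try:
        df = pd.read_csv(path_csv, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise NoDataError(f"{path_csv}: no data") from None
    missing = [c for c in CONDUIT_COLUMNS if c not in df.columns]
    unknown = [c for c in df.columns if c not in CONDUIT_COLUMNS]
    if missing or unknown:
        raise SchemaError(
            f"{path_csv}: schema mismatch (missing {missing}, unknown {unknown})")
    conduits = [
        Conduit(
            id=int(row.id),
            centroid_um=(float(row.x_um), float(row.y_um)),
            area_um2=float(row.area_um2),
            equivalent_diameter_um=float(row.d_um),
            state=str(row.state),
            border=bool(row.border_flag),
        )
        for row in df.itertuples()
    ]
    return ConduitMap(
        conduits=conduits,
        xylem_area_mm2=float(meta["xylem_area_mm2"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        source_image_id=str(meta.get("source_image_id", "")),
        settings=meta.get("settings", {}),
    )


# -- tabular formats --------------------------------------------------------

def write_curve_points(path, df: pd.DataFrame) -> None:
    df[CURVE_COLUMNS].to_csv(path, index=False)


def read_curve_points(path) -> pd.DataFrame:
    df = _read_table(path, CURVE_COLUMNS)
    bad = df.index[(df["plc_pct"] < 0) | (df["plc_pct"] > 100)].tolist()
    if bad:
        raise SchemaError(f"{path}: plc_pct outside [0, 100] at rows {bad}")
    bad = df.index[df["psi_mpa"] > 0].tolist()
    if bad:
        raise SchemaError(f"{path}: positive psi_mpa at rows {bad} "
                          f"(psi is recorded as negative MPa)")
    return df


def write_wall_pairs(path, pairs: list[WallMeasurement]) -> None:
    pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in pairs],
            "t_um": [p.t_um for p in pairs],
            "b_um": [p.b_um for p in pairs],
            "pair_mean_d_um": [p.pair_mean_d_um for p in pairs],
        }
    ).to_csv(path, index=False)


def read_wall_pairs(path) -> list[WallMeasurement]:
    df = _read_table(path, WALL_COLUMNS)
    return [
        WallMeasurement(t_um=float(r.t_um), b_um=float(r.b_um),
                        pair_mean_d_um=float(r.pair_mean_d_um),
                        sample_id=str(r.sample_id))
        for r in df.itertuples()
    ]


def write_hydraulic_samples(path, samples: list[HydraulicSample]) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "psi_mpa": [s.psi_mpa for s in samples],
            "ki": [s.ki for s in samples],
            "ks": [s.ks for s in samples],
            "temperature_c": [s.temperature_c for s in samples],
        }
    ).to_csv(path, index=False)


def read_hydraulic_samples(path) -> list[HydraulicSample]:
    df = _read_table(path, HYDRAULIC_COLUMNS)
    return [
        HydraulicSample(psi_mpa=float(r.psi_mpa), ki=float(r.ki), ks=float(r.ks),
                        temperature_c=float(r.temperature_c),
                        sample_id=str(r.sample_id))
        for r in df.itertuples()
    ]


def write_ground_truth_frame(path, truth_df: pd.DataFrame) -> None:
    truth_df[TRUTH_COLUMNS].to_csv(path, index=False)


def read_ground_truth_frame(path) -> pd.DataFrame:
    return _read_table(path, TRUTH_COLUMNS)


# -- fits, thresholds, configs ---------------------------------------------

def curve_to_dict(curve: VulnerabilityCurve) -> dict:
    out = {
        "organ": curve.organ,
        "method": curve.method,
        "n_points": int(len(curve.points)),
    }
    if curve.fit is not None:
        out["fit"] = dataclasses.asdict(curve.fit)
    if curve.thresholds is not None:
        ts = dataclasses.asdict(curve.thresholds)
        ts["ci"] = {k: list(v) for k, v in ts["ci"].items()}
        out["thresholds"] = ts
    return out


def write_curves_json(path, curves: list[VulnerabilityCurve]) -> None:
    payload = [curve_to_dict(c) for c in curves]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def thresholds_table(curves: list[VulnerabilityCurve]) -> pd.DataFrame:
    """Long-format threshold summary, one row per organ/method."""
    rows = []
    for c in curves:
        ts = c.thresholds
        row = {"organ": c.organ, "method": c.method,
               "n": int(len(c.points))}
        for name in ("psi12", "psi50", "psi88"):
            if ts is None:
                row[name] = row[f"{name}_ci_low"] = row[f"{name}_ci_high"] = np.nan
            else:
                row[name] = ts.value(name)
                row[f"{name}_ci_low"], row[f"{name}_ci_high"] = ts.ci[name]
        rows.append(row)
    return pd.DataFrame(rows)


def read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a YAML mapping at top level")
    return data


def write_yaml(path, data: dict) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
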